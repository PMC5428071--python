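"""Readers and writers: multi-frame XYZ, a native trajectory container,
YAML configs, delimited series/event tables.

The native container is a NumPy ``.npz`` archive holding the frame and time
arrays plus a JSON metadata block (config, seed, stride); round-tripping
through it is bit-exact.  XYZ is the interchange format (element field fixed
to "CA"); it is lossy to text precision by nature and is written with 17
significant digits so that a round trip is exact in practice.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .chain import CGChainConfig
from .correlators import AcfResult
from .dihedral_stats import FlipEventLog
from .langevin import Trajectory
from .rism import RismConfig, StatePath

__all__ = [
    "write_xyz",
    "read_xyz",
    "save_trajectory",
    "load_trajectory",
    "save_config",
    "load_config",
    "write_series",
    "read_series",
    "write_events",
    "read_events",
]


def write_xyz(path, frames: np.ndarray, comment: str = "polyfric frame") -> None:
    """Write one conformation (N, 3) or a stack (T, N, 3) as multi-frame XYZ."""
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    with open(path, "w") as fh:
        for t, frame in enumerate(arr):
            fh.write(f"{frame.shape[0]}\n{comment} {t}\n")
            for x, y, z in frame:
                fh.write(f"CA {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path) -> np.ndarray:
    """Read a multi-frame XYZ file; returns (T, N, 3)."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment
            frame = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                frame[i] = [float(v) for v in parts[1:4]]
            frames.append(frame)
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return np.stack(frames)


def save_trajectory(path, traj: Trajectory) -> None:
    """Save a trajectory to the native .npz container (bit-exact round trip)."""
    meta = {
        "config": traj.config.to_dict(),
        "seed": traj.seed,
        "stride": traj.stride,
        "equilibration_steps": traj.equilibration_steps,
    }
    np.savez_compressed(
        path, times=traj.times, frames=traj.frames, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    )


def load_trajectory(path) -> Trajectory:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        return Trajectory(
            times=data["times"],
            frames=data["frames"],
            config=CGChainConfig.from_dict(meta["config"]),
            seed=meta["seed"],
            stride=meta["stride"],
            equilibration_steps=meta["equilibration_steps"],
        )


_UNITS = {
    "N": "beads",
    "sigma": "reduced length (sigma)",
    "k_bond": "kBT/sigma^2",
    "theta0": "rad",
    "k_bend": "kBT/rad^2",
    "eps_dih": "kBT",
    "ev_strength": "kBT",
    "ev_cutoff": "sigma",
    "xi0": "reduced friction (xi0)",
    "kBT": "reduced energy",
    "dt": "tau0 = sigma^2 xi0 / kBT",
}


def save_config(path, config: CGChainConfig) -> None:
    """Write a chain config as YAML with explicit unit declarations."""
    payload = {"units": _UNITS, "parameters": config.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> CGChainConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return CGChainConfig.from_dict(payload["parameters"])


def write_series(path, times: np.ndarray, values: np.ndarray, metadata: dict | None = None) -> None:
    """Two-column delimited text (time, value) with a '#' metadata header."""
    header = json.dumps(metadata or {})
    np.savetxt(path, np.column_stack([times, values]), header=header)


def read_series(path) -> tuple[np.ndarray, np.ndarray, dict]:
    with open(path) as fh:
        first = fh.readline()
    meta = json.loads(first.lstrip("# ").strip() or "{}")
    data = np.loadtxt(path)
    return data[:, 0], data[:, 1], meta


def write_acf(path, result: AcfResult) -> None:
    """Autocorrelation curve as a (lag, C) table; tau and settings in the header."""
    meta = dict(result.method)
    meta.update(tau=result.tau, truncation_lag=result.truncation_lag, converged=result.converged)
    write_series(path, result.lags, result.values, metadata=meta)


def write_state_path(path, sp: StatePath) -> None:
    """Jump events of the RIS chain as delimited text: dihedral, time, new state.

    The header carries the initial state vector, the config and the seed so
    that the path can be reconstructed exactly.
    """
    meta = {
        "initial_states": [int(s) for s in sp.initial_states],
        "config": sp.config.to_dict(),
        "seed": sp.seed,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("dihedral\ttime\tnew_state\n")
        for d in range(sp.n_dihedrals):
            for t, s in zip(sp.times[d], sp.states[d]):
                fh.write(f"{d}\t{t:.17g}\t{s}\n")


def read_state_path(path) -> StatePath:
    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# ").strip())
    rows = np.atleast_2d(np.genfromtxt(path, skip_header=2, dtype=float))
    initial = np.array(meta["initial_states"], dtype=int)
    times, states = [], []
    for d in range(initial.shape[0]):
        sel = rows[:, 0] == d if rows.size else np.zeros(0, dtype=bool)
        times.append(rows[sel, 1] if rows.size else np.empty(0))
        states.append(rows[sel, 2].astype(int) if rows.size else np.empty(0, dtype=int))
    return StatePath(
        initial_states=initial,
        times=times,
        states=states,
        config=RismConfig(**meta["config"]),
        seed=meta["seed"],
    )


def write_events(path, log: FlipEventLog) -> None:
    """Flip events as delimited text: dihedral, time, from_well, to_well."""
    with open(path, "w") as fh:
        fh.write(f"# hysteresis_deg={log.hysteresis_deg}\n")
        fh.write("dihedral\ttime\tfrom_well\tto_well\n")
        for d in range(log.n_dihedrals):
            for t, a, b in zip(log.times[d], log.from_well[d], log.to_well[d]):
                fh.write(f"{d}\t{t:.17g}\t{a}\t{b}\n")


def read_events(path) -> FlipEventLog:
    with open(path) as fh:
        first = fh.readline()
        hyst = float(first.split("=", 1)[1])
    rows = np.genfromtxt(path, skip_header=2, dtype=float)
    rows = np.atleast_2d(rows)
    times, fr, to = [], [], []
    n_dih = int(rows[:, 0].max()) + 1 if rows.size else 0
    for d in range(n_dih):
        sel = rows[:, 0] == d
        times.append(rows[sel, 1])
        fr.append(rows[sel, 2].astype(int))
        to.append(rows[sel, 3].astype(int))
    return FlipEventLog(times=times, from_well=fr, to_well=to, hysteresis_deg=hyst)
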