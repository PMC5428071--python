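"""Overdamped Langevin dynamics of the bead-spring chain.

The equation of motion is free-draining Brownian dynamics,

    dr_i = F_i dt / xi0 + sqrt(2 kBT dt / xi0) eta_i,

integrated with the first-order Euler-Maruyama scheme (no inertia, no
hydrodynamic interactions).  Noise comes from a counter-based Philox
generator keyed on the run seed, drawn in (step, bead, coordinate) order, so
trajectories are bitwise reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .chain import CGChainConfig, EV_MIN_SEPARATION, build_chain, check_conformation, dihedral_angles

__all__ = ["Trajectory", "IntegrationError", "forces", "run_langevin"]

#: steps of pre-generated noise per kernel call; bounds peak memory
_CHUNK_STEPS = 20_000


class IntegrationError(RuntimeError):
    """Raised when the integrator blows up (non-finite coordinates or a bond
    stretched beyond five sigma); usually means the timestep is too large."""


@dataclass
class Trajectory:
    """Uniformly strided frames of bead positions with their provenance.

    ``times[k]`` is the simulation time of ``frames[k]`` measured from the
    start of the production run (after equilibration); frame 0 is the state
    right after equilibration.
    """

    times: np.ndarray
    frames: np.ndarray
    config: CGChainConfig
    seed: int
    stride: int
    equilibration_steps: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("frames must be (n_frames, N, 3) aligned with times")
        if self.times.shape[0] < 2:
            raise ValueError("a trajectory needs at least two frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("times must be strictly increasing and uniform")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_dt(self) -> float:
        return float(self.times[1] - self.times[0])

    # -- observable series ------------------------------------------------
    def end_to_end_vector(self) -> np.ndarray:
        """(T, 3) end-to-end vector R = r_{N-1} - r_0 per frame."""
        return self.frames[:, -1] - self.frames[:, 0]

    def end_to_end_distance(self) -> np.ndarray:
        """(T,) end-to-end distance |R| per frame."""
        return np.linalg.norm(self.end_to_end_vector(), axis=1)

    def segment_distance(self, i: int, j: int) -> np.ndarray:
        """(T,) distance |r_i - r_j| per frame."""
        if i == j:
            raise ValueError("segment distance needs two distinct monomers")
        return np.linalg.norm(self.frames[:, j] - self.frames[:, i], axis=1)

    def centroid(self) -> np.ndarray:
        """(T, 3) mean bead position per frame."""
        return self.frames.mean(axis=1)

    def dihedral_series(self) -> np.ndarray:
        """(T, N-3) torsion angles per frame."""
        return dihedral_angles(self.frames)


def forces(positions: np.ndarray, config: CGChainConfig) -> np.ndarray:
    """Forces -grad V on each bead for a single conformation, shape (N, 3)."""
    pos = check_conformation(positions, config.N)
    F = np.empty_like(pos)
    _kernels.forces_into(
        pos,
        F,
        config.sigma,
        config.k_bond,
        config.theta0,
        config.k_bend,
        config.eps_dih,
        config.ev_strength,
        config.ev_cutoff**2,
        EV_MIN_SEPARATION,
    )
    return F


def _noise_stream(seed: int):
    """Philox generator for the integrator noise, keyed on the run seed."""
    return np.random.Generator(np.random.Philox(key=np.uint64(seed)))


def run_langevin(
    config: CGChainConfig,
    n_steps: int,
    seed: int,
    stride: int = 100,
    initial: np.ndarray | None = None,
    equilibration_steps: int | None = None,
) -> Trajectory:
    """Integrate the chain for ``n_steps`` production steps.

    An equilibration prefix (default 10% of ``n_steps``) is run first and
    discarded; the first stored frame is the conformation at the end of that
    prefix.  Frames are then stored every ``stride`` steps.  The initial
    conformation defaults to :func:`polyfric.chain.build_chain` with the same
    seed.

    Raises :class:`IntegrationError` if any coordinate becomes non-finite or
    a bond stretches beyond five sigma; use a smaller ``dt`` in that case.
    """
    if stride < 1 or n_steps < stride:
        raise ValueError("need n_steps >= stride >= 1")
    if equilibration_steps is None:
        equilibration_steps = n_steps // 10
    if initial is None:
        pos = build_chain(config, seed)
    else:
        pos = check_conformation(initial, config.N).copy()

    rng = _noise_stream(seed)
    amp = np.float32(np.sqrt(2.0 * config.kBT * config.dt / config.xi0))
    mob_dt = config.dt / config.xi0
    N = config.N
    n_frames = n_steps // stride + 1
    frames = np.empty((n_frames, N, 3))
    frames[0] = pos
    n_stored = 1

    # a bond stretched beyond 5 sigma signals a blow-up — but only when bonds
    # are actually held by a spring (free beads diffuse apart legitimately)
    max_bond2 = 25.0 * config.sigma**2 if config.k_bond > 0 else np.inf
    args = (
        config.sigma,
        config.k_bond,
        config.theta0,
        config.k_bend,
        config.eps_dih,
        config.ev_strength,
        config.ev_cutoff**2,
        EV_MIN_SEPARATION,
        max_bond2,
    )

    def _advance(total: int, record: bool, n_stored: int, step0: int) -> int:
        done = 0
        while done < total:
            n = min(_CHUNK_STEPS, total - done)
            # float32 draws: the noise amplitude (~1e-2 sigma) leaves single
            # precision rounding ~1e-9 sigma per step, far below thermal noise
            noise = rng.standard_normal((n, N, 3), dtype=np.float32)
            noise *= amp
            fail, n_stored = _kernels.langevin_chunk(
                pos,
                noise,
                mob_dt,
                *args,
                stride if record else -1,
                done if record else 0,
                frames,
                n_stored,
            )
            if fail >= 0:
                raise IntegrationError(
                    f"integration blew up at step {step0 + done + fail} "
                    f"(dt={config.dt}); reduce dt"
                )
            done += n
        return n_stored

    _advance(equilibration_steps, False, 0, 0)
    frames[0] = pos  # state after equilibration
    n_stored = _advance(n_steps, True, 1, equilibration_steps)
    frames = frames[:n_stored]
    # the in-kernel check trails the update by one step; validate the end state
    if not np.all(np.isfinite(pos)):
        raise IntegrationError(
            f"integration blew up near step {equilibration_steps + n_steps} "
            f"(dt={config.dt}); reduce dt"
        )
    times = config.dt * stride * np.arange(n_stored)
    return Trajectory(
        times=times,
        frames=frames,
        config=config,
        seed=int(seed),
        stride=int(stride),
        equilibration_steps=int(equilibration_steps),
    )
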