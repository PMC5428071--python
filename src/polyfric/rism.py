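"""Rotational isomeric state model: dihedrals as the only degrees of freedom.

Each of the N-3 dihedrals of the chain is an independent continuous-time
Markov chain on the three wells of the hindered-rotation potential, with all
six pairwise jump rates equal to ``k`` (total escape rate 2k per dihedral,
mean dwell time 1/(2k), single-dihedral relaxation time tau_dih = 1/(3k)).
Bond lengths and bending angles are frozen at the same geometry as the
Langevin chain; conformations are rebuilt from the current state vector by
internal-coordinate chain growth, so flipping dihedral i rigidly pivots all
beads beyond it.

The module also carries the memoryless-jump analytic model: if every jump
fully randomises the end-to-end distance, <dR^2(t)> saturates as
(1 - exp(-nu t)) and all higher displacement moments share that single time
dependence — the fingerprint that distinguishes the jump picture from
ordinary diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import _kernels
from .chain import WELL_CENTERS

__all__ = [
    "RismConfig",
    "StatePath",
    "MemorylessModel",
    "run_rism_kmc",
    "states_to_angles",
    "reconstruct_chain",
    "sample_states",
    "rism_end_to_end_series",
    "independent_flip_time",
    "memoryless_msd_theory",
]


@dataclass(frozen=True)
class RismConfig:
    """Parameters of the 3-state kinetic Monte Carlo chain.

    ``k`` is the rate of each of the six well-to-well transitions; the
    derived single-dihedral relaxation time is ``tau_dih = 1/(3k)`` and the
    mean dwell time in a well is ``1/(2k)``.
    """

    N: int = 20
    k: float = 1.0
    sigma: float = 1.0
    theta0: float = np.deg2rad(100.0)
    t_max: float = 1000.0
    record_dt: float = 0.1

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("need N >= 4")
        if self.k <= 0 or self.t_max <= 0 or self.record_dt <= 0:
            raise ValueError("k, t_max and record_dt must be positive")

    @property
    def n_dihedrals(self) -> int:
        return self.N - 3

    @property
    def tau_dih(self) -> float:
        """Single-dihedral relaxation time 1/(3k)."""
        return 1.0 / (3.0 * self.k)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (int(v) if k == "N" else float(v)) for k, v in d.items()}


@dataclass
class StatePath:
    """Event history of all dihedrals: per-dihedral jump times and new states.

    ``times[d]`` is strictly increasing; ``states[d][e]`` is the well index
    (0, 1, 2) entered at ``times[d][e]`` and always differs from the state
    occupied before the event.
    """

    initial_states: np.ndarray
    times: list[np.ndarray]
    states: list[np.ndarray]
    config: RismConfig
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.times) != self.initial_states.shape[0] or len(self.states) != len(self.times):
            raise ValueError("per-dihedral event lists misaligned with initial states")
        for d, (t, s) in enumerate(zip(self.times, self.states)):
            if t.shape != s.shape:
                raise ValueError(f"dihedral {d}: times and states differ in length")
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"dihedral {d}: event times not strictly increasing")
            prev = np.concatenate([[self.initial_states[d]], s[:-1]])
            if np.any(s == prev):
                raise ValueError(f"dihedral {d}: event does not change the state")

    @property
    def n_dihedrals(self) -> int:
        return self.initial_states.shape[0]

    def event_counts(self) -> np.ndarray:
        return np.array([t.shape[0] for t in self.times])


def run_rism_kmc(config: RismConfig, seed: int) -> StatePath:
    """Exact event-driven simulation of the independent-dihedral jump chain.

    Each dihedral draws exponential waiting times with total rate 2k and
    jumps to one of the two other wells with equal probability (all pairwise
    rates equal).  Dihedrals use independent, seed-derived random streams.
    """
    ss = np.random.SeedSequence([int(seed), 0x7269736D])
    children = ss.spawn(config.n_dihedrals + 1)
    init_rng = np.random.default_rng(children[-1])
    initial = init_rng.integers(0, 3, size=config.n_dihedrals)
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    rate = 2.0 * config.k
    mean_events = rate * config.t_max
    for d in range(config.n_dihedrals):
        g = np.random.default_rng(children[d])
        # draw waits in blocks until the horizon is passed
        waits = g.exponential(1.0 / rate, size=max(16, int(mean_events + 6.0 * np.sqrt(mean_events) + 10)))
        t = np.cumsum(waits)
        while t[-1] < config.t_max:
            extra = g.exponential(1.0 / rate, size=waits.shape[0])
            t = np.concatenate([t, t[-1] + np.cumsum(extra)])
        t = t[t < config.t_max]
        hops = g.integers(1, 3, size=t.shape[0])  # +1 or +2 mod 3: the two other wells
        s = (initial[d] + np.cumsum(hops)) % 3
        times.append(t)
        states.append(s)
    return StatePath(initial_states=initial, times=times, states=states, config=config, seed=int(seed))


def states_to_angles(states: np.ndarray) -> np.ndarray:
    """Map well indices to dihedral angles at the well minima."""
    return WELL_CENTERS[np.asarray(states, dtype=int)]


def reconstruct_chain(
    values: np.ndarray,
    sigma: float = 1.0,
    theta0: float = np.deg2rad(100.0),
    as_states: bool = False,
) -> np.ndarray:
    """Build bead positions from N-3 dihedral values (angles or well indices).

    Bond lengths are ``sigma`` and bending angles ``theta0`` everywhere.
    Canonical frame: bead 0 at the origin, bead 1 on +x, bead 2 in the
    xy-plane (positive y).  Changing dihedral i and rebuilding is equivalent
    to rigidly rotating beads i+3 ... N-1 about the central bond (pivot
    semantics); beads 0 ... i+2 are unaffected.
    """
    vals = np.asarray(values)
    if vals.ndim != 1:
        raise ValueError("expected a flat sequence of dihedral values")
    phis = states_to_angles(vals) if as_states else vals.astype(float)
    N = phis.shape[0] + 3
    out = np.empty((N, 3))
    _kernels.reconstruct_positions(np.ascontiguousarray(phis), sigma, theta0, out)
    return out


def sample_states(path: StatePath, grid: np.ndarray) -> np.ndarray:
    """State of every dihedral at each requested time, shape (len(grid), n_dih)."""
    grid = np.asarray(grid, dtype=float)
    out = np.empty((grid.shape[0], path.n_dihedrals), dtype=np.int64)
    for d in range(path.n_dihedrals):
        idx = np.searchsorted(path.times[d], grid, side="right")
        full = np.concatenate([[path.initial_states[d]], path.states[d]])
        out[:, d] = full[idx]
    return out


def rism_end_to_end_series(path: StatePath, config: RismConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """End-to-end distance R(t) sampled every ``record_dt``.

    Returns ``(times, R)``; the chain is rebuilt from the current state
    vector at each sample.
    """
    cfg = config or path.config
    grid = np.arange(0.0, cfg.t_max, cfg.record_dt)
    states = sample_states(path, grid)
    phis = states_to_angles(states)
    r = _kernels.reconstruct_r_series(np.ascontiguousarray(phis), cfg.sigma, cfg.theta0)
    return grid, r


def sample_angle_series(path: StatePath, grid: np.ndarray) -> np.ndarray:
    """Dihedral angles (well-center values) at each requested time."""
    return states_to_angles(sample_states(path, grid))


def independent_flip_time(tau_dih: float, N: int) -> float:
    """Reconfiguration time 3 tau_dih / (2N) of the independent-flip picture.

    If any single flip fully randomises the end-to-end distance, the
    reconfiguration time is the inverse of the total flip frequency 2kN,
    which decreases with chain length — in contrast to the length-independent
    barrier-friction time of concerted rotations.
    """
    if tau_dih <= 0 or N <= 0:
        raise ValueError("tau_dih and N must be positive")
    return 3.0 * tau_dih / (2.0 * N)


@dataclass(frozen=True)
class MemorylessModel:
    """Memoryless-jump model: total jump frequency ``nu``, equilibrium mean
    ``R_mean`` and variance ``R_var`` of the observable."""

    nu: float
    R_mean: float
    R_var: float

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.R_var < 0:
            raise ValueError("R_var must be non-negative")


def memoryless_msd_theory(model: MemorylessModel, t: np.ndarray, orders: tuple[int, ...] = (1, 2)) -> dict:
    """Displacement moments of the memoryless-jump process.

    With probability exp(-nu t) no jump occurred and the displacement is
    zero; otherwise the new value is an independent equilibrium draw, so

        <dR^(2n)(t)> = (1 - exp(-nu t)) * E[(R' - R)^(2n)],

    every moment sharing the single saturation curve (1 - exp(-nu t)).  For
    n = 1 the prefactor is E[(R'-R)^2] = 2 Var(R).  Returns a dict with the
    n=1 moment ``msd``, the shared ``normalized`` curve, and the constant
    moment ratio diagnostic <dR^4>/<dR^2> (time-independent here, unlike
    diffusion where <dR^4>/<dR^2>^2 is the constant).
    """
    t = np.asarray(t, dtype=float)
    saturation = 1.0 - np.exp(-model.nu * t)
    return {
        "normalized": saturation,
        "msd": 2.0 * model.R_var * saturation,
        "orders": {n: saturation for n in orders},
    }
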