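"""Dihedral flip detection, dwell/Poisson statistics, and pair lag-time
correlation analysis.

A flip detector with hysteresis turns noisy dihedral-angle series into
event logs: each well owns a core sector (its 120-degree sector shrunk by
``hysteresis_deg``); a flip is recorded only when the angle enters the core
of a *different* well, so rapid recrossings of a barrier inside the buffer
region are not double-counted.

If every dihedral flips as an independent Poisson process, the lag from a
flip of dihedral i to the next flip of dihedral j is exponential with rate
1/tau_i + 1/tau_j; an excess of short lags signals concerted (crankshaft-
like) rotations of sequence neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chain import WELL_CENTERS
from .correlators import acf_dihedral

__all__ = [
    "FlipEventLog",
    "DwellStats",
    "LagTestResult",
    "InsufficientEventsError",
    "detect_flips",
    "dwell_and_poisson",
    "pair_lag_analysis",
    "dihedral_relaxation_profile",
]


class InsufficientEventsError(RuntimeError):
    """Raised when a statistical test is asked for with too few flip events."""


@dataclass
class FlipEventLog:
    """Per-dihedral well-to-well transition events.

    ``times[d]``, ``from_well[d]`` and ``to_well[d]`` are aligned arrays for
    dihedral ``d``; times are strictly increasing and from != to always.
    """

    times: list[np.ndarray]
    from_well: list[np.ndarray]
    to_well: list[np.ndarray]
    hysteresis_deg: float
    well_centers: np.ndarray = field(default_factory=lambda: WELL_CENTERS.copy())

    @property
    def n_dihedrals(self) -> int:
        return len(self.times)

    def n_events(self, d: int | None = None):
        if d is not None:
            return self.times[d].shape[0]
        return np.array([t.shape[0] for t in self.times])


@dataclass
class DwellStats:
    """Dwell-time statistics of one dihedral plus an exponentiality test."""

    n_events: int
    mean_dwell: float
    dwells: np.ndarray
    ks_statistic: float
    p_value: float

    def poisson_consistent(self, alpha: float = 0.01) -> bool:
        return self.p_value >= alpha


@dataclass
class LagTestResult:
    """Exponential-null test of flip lags between a pair of dihedrals.

    The null rate is 1/tau_i + 1/tau_j (independent Poisson flipping).
    ``excess_short_lags`` is True when the empirical lag distribution puts
    more weight at short times than the null — the signature of positively
    correlated (concerted) flips.
    """

    lags: np.ndarray
    null_rate: float
    ks_statistic: float
    signed_statistic: float
    p_value: float
    excess_short_lags: bool

    def rejected(self, alpha: float = 0.01) -> bool:
        return self.p_value < alpha

    def report(self) -> str:
        """Plain-text summary of the test."""
        verdict = "REJECTED" if self.rejected() else "not rejected"
        direction = "excess of short lags" if self.excess_short_lags else "no short-lag excess"
        return (
            f"pair lag test: n={self.lags.shape[0]} lags, null rate={self.null_rate:.4g}\n"
            f"KS={self.ks_statistic:.4f} (signed {self.signed_statistic:+.4f}), "
            f"p={self.p_value:.3g}\n"
            f"independent-Poisson null {verdict} at alpha=0.01; {direction}\n"
        )


def detect_flips(
    angles: np.ndarray,
    dt: float = 1.0,
    hysteresis_deg: float = 20.0,
    well_centers: np.ndarray | None = None,
) -> FlipEventLog:
    """Detect well-to-well flips in one or more dihedral angle series.

    Parameters
    ----------
    angles : array (T,) or (T, n_dihedrals)
        Uniformly sampled dihedral angles in radians.
    hysteresis_deg : float in [0, 60)
        Buffer width: a well's core is the set of angles within
        (60 - hysteresis_deg) degrees of its center.  A flip event fires at
        the first sample inside the core of a well different from the
        current one.
    """
    if not 0.0 <= hysteresis_deg < 60.0:
        raise ValueError("hysteresis_deg must lie in [0, 60)")
    phi = np.asarray(angles, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    centers = WELL_CENTERS if well_centers is None else np.asarray(well_centers)
    core = np.deg2rad(60.0 - hysteresis_deg)
    # nearest well center and angular distance to it
    delta = np.abs(np.angle(np.exp(1j * (phi[..., None] - centers))))
    nearest = np.argmin(delta, axis=-1)
    in_core = np.take_along_axis(delta, nearest[..., None], axis=-1)[..., 0] <= core
    label = np.where(in_core, nearest, -1)

    times: list[np.ndarray] = []
    from_w: list[np.ndarray] = []
    to_w: list[np.ndarray] = []
    T = phi.shape[0]
    for d in range(phi.shape[1]):
        lab = label[:, d]
        core_idx = np.nonzero(lab >= 0)[0]
        if core_idx.size == 0:
            times.append(np.empty(0))
            from_w.append(np.empty(0, dtype=int))
            to_w.append(np.empty(0, dtype=int))
            continue
        # forward-fill the current well over buffer samples
        filled = lab[core_idx]
        change = np.nonzero(np.diff(filled) != 0)[0] + 1
        ev_idx = core_idx[change]  # first sample inside the new core
        times.append(dt * ev_idx.astype(float))
        from_w.append(filled[change - 1].astype(int))
        to_w.append(filled[change].astype(int))
    return FlipEventLog(times=times, from_well=from_w, to_well=to_w, hysteresis_deg=hysteresis_deg, well_centers=centers.copy())


def dwell_and_poisson(log: FlipEventLog, dihedral: int, min_events: int = 30) -> DwellStats:
    """Dwell-time distribution of one dihedral and a KS exponentiality test.

    Dwells are the waiting times between successive flip events.  The test
    compares them against an exponential with the sample mean; for a Poisson
    flipper with all-pairs rate k the mean dwell is 1/(2k).
    """
    t = log.times[dihedral]
    if t.shape[0] < min_events:
        raise InsufficientEventsError(
            f"dihedral {dihedral} has {t.shape[0]} events; need >= {min_events}"
        )
    dwells = np.diff(t)
    mean = float(dwells.mean())
    ks = stats.kstest(dwells, "expon", args=(0.0, mean))
    return DwellStats(
        n_events=t.shape[0],
        mean_dwell=mean,
        dwells=dwells,
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
    )


def pair_lag_analysis(
    log: FlipEventLog,
    i: int,
    j: int,
    tau_i: float,
    tau_j: float,
    min_events: int = 30,
) -> LagTestResult:
    """Test flip lags of a dihedral pair against the independent-Poisson null.

    For each flip of ``i`` whose next flip within the pair belongs to ``j``
    (no intervening flip of ``i``), the lag is the time to that flip of
    ``j``.  Under independent Poisson flipping with relaxation times tau_i,
    tau_j this competing-risks lag is exponential with rate
    1/tau_i + 1/tau_j.  The result reports the two-sided KS p-value plus
    the signed statistic max(F_emp - F_null) - max(F_null - F_emp); a
    positive sign with rejection means short lags are over-represented
    (concerted flips).
    """
    ti, tj = log.times[i], log.times[j]
    if ti.shape[0] < min_events or tj.shape[0] < min_events:
        raise InsufficientEventsError(
            f"pair ({i}, {j}) has {ti.shape[0]}/{tj.shape[0]} events; need >= {min_events}"
        )
    if tau_i <= 0 or tau_j <= 0:
        raise ValueError("relaxation times must be positive")
    idx = np.searchsorted(tj, ti, side="right")
    ok = idx < tj.shape[0]
    # keep only i-flips not followed by another i-flip before j's next flip
    next_i = np.concatenate([ti[1:], [np.inf]])
    ok &= tj[np.minimum(idx, tj.shape[0] - 1)] < next_i
    lags = tj[idx[ok]] - ti[ok]
    rate = 1.0 / tau_i + 1.0 / tau_j
    cdf = lambda x: stats.expon.cdf(x, scale=1.0 / rate)
    ks = stats.kstest(lags, cdf)
    d_plus = float(stats.kstest(lags, cdf, alternative="greater").statistic)
    d_minus = float(stats.kstest(lags, cdf, alternative="less").statistic)
    return LagTestResult(
        lags=lags,
        null_rate=rate,
        ks_statistic=float(ks.statistic),
        signed_statistic=d_plus - d_minus,
        p_value=float(ks.pvalue),
        excess_short_lags=bool(d_plus > d_minus),
    )


def dihedral_relaxation_profile(
    angles: np.ndarray,
    dt: float = 1.0,
    n_exclude: int = 2,
) -> dict:
    """Per-position dihedral relaxation times and their end-excluded average.

    Parameters
    ----------
    angles : array (T, n_dihedrals)
        Dihedral series of the whole chain.
    n_exclude : int
        Number of outermost dihedrals dropped at *each* end before
        averaging (chain ends relax faster than the middle).

    Returns a dict with ``taus`` (per position), ``tau_mean`` (interior
    average), ``spread`` (max/min over all positions) and ``interior`` (the
    index slice averaged).
    """
    phi = np.asarray(angles, dtype=float)
    if phi.ndim != 2:
        raise ValueError("expected (T, n_dihedrals) angle series")
    n_dih = phi.shape[1]
    if n_dih - 2 * n_exclude < 2:
        raise ValueError(
            f"{n_dih} dihedrals leave fewer than 2 interior positions after "
            f"excluding {n_exclude} per end; need N >= {2 * n_exclude + 5 + 2}"
        )
    taus = np.array([acf_dihedral(phi[:, d], dt=dt).tau for d in range(n_dih)])
    interior = slice(n_exclude, n_dih - n_exclude)
    return {
        "taus": taus,
        "tau_mean": float(taus[interior].mean()),
        "spread": float(taus.max() / taus.min()),
        "interior": interior,
    }
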