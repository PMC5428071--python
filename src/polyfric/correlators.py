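"""Autocorrelation functions, integral relaxation times, MSD moments and
diffusion coefficients.

The relaxation time of a stationary observable X is defined throughout as

    tau = integral_0^T C(t) dt / C(0),      C(t) = <dX(0) dX(t)>,

with dX = X - <X>.  Because the upper limit cannot be infinity on finite,
noisy data, the integral is truncated at the first lag where C(t)/C(0) drops
below ``trunc_level`` (default 0.01) or at the first zero crossing, whichever
comes first, and never beyond one fifth of the series length.  For a dihedral
angle the correlator is C(t) = <cos[phi(t) - phi(0)]> instead, which starts
at exactly 1 and needs no mean subtraction.

Autocovariances use the biased (1/M) normalisation, which keeps the
estimated ACF positive semi-definite and the integral well behaved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcfResult",
    "MsdResult",
    "DegenerateSeriesError",
    "acf_scalar",
    "acf_vector",
    "acf_dihedral",
    "msd_moments",
    "translational_diffusion",
    "default_lag_grid",
]

#: default C(t)/C(0) level below which the tau integral is truncated
TRUNC_LEVEL = 0.01
#: the tau integral never extends beyond this fraction of the series
MAX_LAG_FRACTION = 0.2


class DegenerateSeriesError(ValueError):
    """Raised when an observable carries no fluctuations to correlate."""


@dataclass
class AcfResult:
    """An autocorrelation curve and its integral relaxation time.

    ``tau`` integrates ``values`` up to ``truncation_lag`` (trapezoid rule)
    and divides by ``values[0]``.  ``converged`` is False when the curve
    never decayed below the truncation level (nor crossed zero) within the
    allowed lag range, in which case ``tau`` is a lower bound.
    """

    lags: np.ndarray
    values: np.ndarray
    tau: float
    truncation_lag: float
    converged: bool
    method: dict = field(default_factory=dict)

    def normalized(self) -> np.ndarray:
        return self.values / self.values[0]

    def crossing_time(self, level: float = np.exp(-1.0)) -> float:
        """First lag where C(t)/C(0) drops to ``level`` (default 1/e).

        Characterises the dominant decay alone, unlike the integral ``tau``
        which also weighs slow tails; useful when a fast global decorrelation
        coexists with a small long-lived component.
        """
        norm = self.normalized()
        idx = np.nonzero(norm <= level)[0]
        if idx.size == 0:
            return float(self.lags[-1])
        return float(self.lags[idx[0]])


@dataclass
class MsdResult:
    """Moments <|dX(t)|^(2n)> of displacements over lag time, plus the fitted
    short-time exponent alpha of the n=1 moment (<dR^2> ~ t^alpha)."""

    lags: np.ndarray
    moments: dict[int, np.ndarray]
    alpha: float
    fit_window: tuple[float, float]
    method: dict = field(default_factory=dict)


def _fft_autocov(x: np.ndarray) -> np.ndarray:
    """Biased (1/M) autocovariance of a 1-D array via FFT, all lags."""
    M = x.shape[0]
    nfft = 1 << (2 * M - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:M]
    return acov / M


def _fft_crosssum(x: np.ndarray) -> np.ndarray:
    """Unnormalised lagged product sums sum_s x[s] x[s+lag] via FFT."""
    M = x.shape[0]
    nfft = 1 << (2 * M - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    return np.fft.irfft(f * np.conj(f), nfft)[:M]


def _integrate_tau(lags: np.ndarray, values: np.ndarray, trunc_level: float) -> tuple[float, float, bool]:
    """Truncated trapezoid integral of C(t)/C(0); returns (tau, t_trunc, ok)."""
    c0 = values[0]
    norm = values / c0
    cap = max(2, int(len(values) * MAX_LAG_FRACTION))
    below = np.nonzero(norm[:cap] < trunc_level)[0]
    crossing = np.nonzero(norm[:cap] <= 0.0)[0]
    candidates = [i for i in (below[0] if below.size else None, crossing[0] if crossing.size else None) if i is not None]
    if candidates:
        i_trunc = min(candidates)
        converged = True
    else:
        i_trunc = cap - 1
        converged = False
    i_trunc = max(i_trunc, 1)
    tau = float(np.trapezoid(norm[: i_trunc + 1], lags[: i_trunc + 1]))
    return tau, float(lags[i_trunc]), converged


def acf_scalar(
    series: np.ndarray,
    dt: float = 1.0,
    trunc_level: float = TRUNC_LEVEL,
) -> AcfResult:
    """Autocorrelation and integral relaxation time of a scalar series.

    Parameters
    ----------
    series : array, shape (M,)
        Uniformly sampled stationary observable, at least 100 samples.
    dt : float
        Sample spacing in time units.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("acf_scalar expects a 1-D series")
    if x.shape[0] < 100:
        raise ValueError(f"need at least 100 samples, got {x.shape[0]}")
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise DegenerateSeriesError("series is constant; no fluctuations to correlate")
    acov = _fft_autocov(x)
    lags = dt * np.arange(acov.shape[0])
    tau, t_trunc, ok = _integrate_tau(lags, acov, trunc_level)
    return AcfResult(
        lags=lags,
        values=acov,
        tau=tau,
        truncation_lag=t_trunc,
        converged=ok,
        method={"kind": "scalar", "dt": dt, "trunc_level": trunc_level, "normalization": "biased"},
    )


def acf_vector(
    series: np.ndarray,
    dt: float = 1.0,
    trunc_level: float = TRUNC_LEVEL,
) -> AcfResult:
    """As :func:`acf_scalar` for a vector observable (e.g. the end-to-end
    vector); the lag product is the dot product of mean-subtracted vectors."""
    v = np.asarray(series, dtype=float)
    if v.ndim != 2:
        raise ValueError("acf_vector expects an (M, d) series")
    if v.shape[0] < 100:
        raise ValueError(f"need at least 100 samples, got {v.shape[0]}")
    v = v - v.mean(axis=0)
    if np.allclose(v, 0.0):
        raise DegenerateSeriesError("vector series is frozen; no fluctuations to correlate")
    acov = np.zeros(v.shape[0])
    for d in range(v.shape[1]):
        acov += _fft_autocov(v[:, d])
    lags = dt * np.arange(acov.shape[0])
    tau, t_trunc, ok = _integrate_tau(lags, acov, trunc_level)
    return AcfResult(
        lags=lags,
        values=acov,
        tau=tau,
        truncation_lag=t_trunc,
        converged=ok,
        method={"kind": "vector", "dt": dt, "trunc_level": trunc_level, "normalization": "biased"},
    )


def acf_dihedral(
    angles: np.ndarray,
    dt: float = 1.0,
    trunc_level: float = TRUNC_LEVEL,
) -> AcfResult:
    """Angular correlator C(t) = <cos[phi(t+s) - phi(s)]>_s and its integral
    relaxation time.

    C(0) = 1 by construction.  The estimator expands the cosine of the
    difference into cos/sin lag products, averaged over all time origins
    (per-lag counts, so the zero-lag value is exact).  A frozen angle gives
    C = 1 everywhere; the result is then flagged ``converged=False`` and tau
    equals the capped truncation lag.
    """
    phi = np.asarray(angles, dtype=float)
    if phi.ndim != 1:
        raise ValueError("acf_dihedral expects a single angle series")
    if phi.shape[0] < 100:
        raise ValueError(f"need at least 100 samples, got {phi.shape[0]}")
    M = phi.shape[0]
    c = np.cos(phi)
    s = np.sin(phi)
    sums = _fft_crosssum(c) + _fft_crosssum(s)
    counts = M - np.arange(M)
    values = sums / counts
    lags = dt * np.arange(M)
    tau, t_trunc, ok = _integrate_tau(lags, values, trunc_level)
    return AcfResult(
        lags=lags,
        values=values,
        tau=tau,
        truncation_lag=t_trunc,
        converged=ok,
        method={"kind": "dihedral", "dt": dt, "trunc_level": trunc_level, "normalization": "per-lag"},
    )


def default_lag_grid(n_samples: int, n_lags: int = 80) -> np.ndarray:
    """Log-spaced integer lags from 1 to n_samples // 4 (dense at the start)."""
    max_lag = max(n_samples // 4, 8)
    dense = np.arange(1, min(11, max_lag + 1))
    sparse = np.unique(np.round(np.geomspace(1, max_lag, n_lags)).astype(int))
    return np.unique(np.concatenate([dense, sparse]))


def msd_moments(
    series: np.ndarray,
    orders: tuple[int, ...] = (1, 2),
    dt: float = 1.0,
    lag_grid: np.ndarray | None = None,
    fit_window: tuple[float, float] | None = None,
    plateau_fraction: float = 0.1,
) -> MsdResult:
    """Displacement moments <|X(t+s) - X(s)|^(2n)> over a grid of lag times.

    ``series`` may be a scalar series (M,) or a vector series (M, d); for
    vectors the displacement magnitude is used.  The subdiffusion exponent
    ``alpha`` is a log-log least-squares slope of the n=1 moment over
    ``fit_window`` (in time units).  By default the window covers lags from
    2 samples up to where the n=1 moment first reaches ``plateau_fraction``
    of its plateau, the plateau being twice the series variance (the
    saturation value for a stationary scalar); for non-stationary input pass
    an explicit window.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    M = x.shape[0]
    if lag_grid is None:
        lag_grid = default_lag_grid(M)
    lag_grid = np.asarray(lag_grid, dtype=int)
    if np.any(lag_grid < 1) or np.any(lag_grid >= M):
        raise ValueError("lags must lie in [1, len(series))")
    all_orders = tuple(sorted(set(orders) | {1}))  # n=1 always needed for alpha
    moments: dict[int, np.ndarray] = {n: np.empty(lag_grid.shape[0]) for n in all_orders}
    for k, lag in enumerate(lag_grid):
        d = x[lag:] - x[:-lag]
        d2 = np.einsum("ij,ij->i", d, d)
        for n in all_orders:
            moments[n][k] = np.mean(d2**n)
    lags_t = dt * lag_grid.astype(float)

    msd = moments[1]
    if fit_window is None:
        plateau = 2.0 * float(np.var(np.linalg.norm(x, axis=1) if x.shape[1] > 1 else x[:, 0]))
        if plateau <= 0:
            raise DegenerateSeriesError("constant series has no displacement statistics")
        lo = 2 * dt
        above = np.nonzero(msd >= plateau_fraction * plateau)[0]
        hi = lags_t[above[0]] if above.size else lags_t[-1]
        # keep at least 6 grid points so the slope is always defined, even
        # when the plateau fraction is reached within the first few lags
        hi = max(float(hi), float(lags_t[min(6, lags_t.shape[0] - 1)]))
        fit_window = (lo, hi)
    sel = (lags_t >= fit_window[0]) & (lags_t <= fit_window[1])
    if np.count_nonzero(sel) < 3:
        raise ValueError(
            f"alpha fit window {fit_window} covers {np.count_nonzero(sel)} lag points; need >= 3"
        )
    slope, _ = np.polyfit(np.log(lags_t[sel]), np.log(msd[sel]), 1)
    return MsdResult(
        lags=lags_t,
        moments={n: moments[n] for n in orders},
        alpha=float(slope),
        fit_window=fit_window,
        method={"dt": dt, "plateau_fraction": plateau_fraction},
    )


def translational_diffusion(
    centroid: np.ndarray,
    dt: float = 1.0,
    fit_window: tuple[float, float] | None = None,
    min_r2: float = 0.99,
) -> tuple[float, bool]:
    """Translational diffusion coefficient from the centroid MSD slope.

    Parameters
    ----------
    centroid : array (M, 3)
        Centre-of-friction (mean bead position) per frame.
    fit_window : (t_lo, t_hi), optional
        Lag-time range of the linear fit.  The default covers short lags,
        up to 1/500 of the series duration: the relative sampling error of
        an MSD point grows like sqrt(lag / duration), so short lags carry
        nearly all the statistical weight for a diffusive signal.

    Returns ``(D_tr, reliable)`` with ``D_tr = slope / 6`` and ``reliable``
    False when the MSD-vs-lag fit correlates poorly (non-diffusive input).
    """
    c = np.asarray(centroid, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("centroid series must be (M>=2, d)")
    M = c.shape[0]
    lag_grid = default_lag_grid(M)
    lags_t = dt * lag_grid.astype(float)
    msd = np.empty(lag_grid.shape[0])
    for k, lag in enumerate(lag_grid):
        d = c[lag:] - c[:-lag]
        msd[k] = np.mean(np.einsum("ij,ij->i", d, d))
    if fit_window is None:
        duration = dt * M
        fit_window = (2 * dt, max(duration / 500.0, lags_t[4] if lags_t.size > 4 else lags_t[-1]))
    sel = (lags_t >= fit_window[0]) & (lags_t <= fit_window[1])
    if np.count_nonzero(sel) < 2:
        sel = slice(None)
    t_fit, m_fit = lags_t[sel], msd[sel]
    if np.allclose(m_fit, 0.0):
        return 0.0, True
    # relative-error weighting: the sampling noise of an MSD point grows with
    # the lag, so an unweighted linear fit would be dominated by the noisiest
    # points
    w = 1.0 / np.maximum(m_fit, 1e-12 * m_fit.max())
    slope, intercept = np.polyfit(t_fit, m_fit, 1, w=w)
    pred = slope * t_fit + intercept
    res_w = (m_fit - pred) * w
    tot_w = (m_fit - np.average(m_fit, weights=w**2)) * w
    ss_tot = float(np.sum(tot_w**2))
    r2 = 1.0 - float(np.sum(res_w**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope / 6.0), bool(r2 >= min_r2 and slope >= 0)
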