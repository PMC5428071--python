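"""Synthetic stochastic series with known relaxation times and exponents.

These generators exist to calibrate and test the estimators in
:mod:`polyfric.correlators`: Ornstein-Uhlenbeck series (known correlation
time), free Brownian paths (known diffusion constant), rotational diffusion
of a rigid unit vector (known vector relaxation time 1/(2 D_r)), fractional
Gaussian motion (known MSD exponent 2H), Poisson event trains, and the
memoryless-jump process in which an observable is redrawn from its
equilibrium distribution at Poisson-distributed times.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = [
    "ornstein_uhlenbeck",
    "ou_vector",
    "brownian_path",
    "rotor_vector_series",
    "fractional_brownian_motion",
    "poisson_train",
    "memoryless_jump_series",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 0x73796E74]))


def ornstein_uhlenbeck(
    n: int, dt: float, tau: float, sigma: float = 1.0, mean: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Stationary OU series with ACF sigma^2 exp(-t/tau), exact discretisation."""
    rho = np.exp(-dt / tau)
    g = _rng(seed)
    x = np.empty(n)
    x[0] = g.normal(0.0, sigma)
    innov = g.normal(0.0, sigma * np.sqrt(1.0 - rho * rho), size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return mean + x


def ou_vector(n: int, dt: float, tau: float, sigma: float = 1.0, seed: int = 0, dim: int = 3) -> np.ndarray:
    """Isotropic OU vector series, components independent OU processes."""
    g = _rng(seed)
    rho = np.exp(-dt / tau)
    x = np.empty((n, dim))
    x[0] = g.normal(0.0, sigma, size=dim)
    innov = g.normal(0.0, sigma * np.sqrt(1.0 - rho * rho), size=(n - 1, dim))
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def brownian_path(n: int, dt: float, D: float, seed: int = 0, dim: int = 1) -> np.ndarray:
    """Free Brownian path with MSD = 2 d D t; shape (n,) or (n, dim)."""
    g = _rng(seed)
    steps = g.normal(0.0, np.sqrt(2.0 * D * dt), size=(n - 1, dim))
    path = np.vstack([np.zeros((1, dim)), np.cumsum(steps, axis=0)])
    return path[:, 0] if dim == 1 else path


def rotor_vector_series(n: int, dt: float, D_r: float, seed: int = 0) -> np.ndarray:
    """Fixed-length unit vector under rotational diffusion with coefficient D_r.

    The orientation ACF is exp(-2 D_r t), so the integral vector relaxation
    time is 1 / (2 D_r).  Uses small tangent-space steps; keep D_r * dt small.
    """
    g = _rng(seed)
    v = np.empty((n, 3))
    u = np.array([0.0, 0.0, 1.0])
    amp = np.sqrt(2.0 * D_r * dt)
    kicks = g.normal(0.0, amp, size=(n, 3))
    for i in range(n):
        v[i] = u
        k = kicks[i]
        k = k - (k @ u) * u  # tangent-space projection
        u = u + k
        u /= np.linalg.norm(u)
    return v


def fractional_brownian_motion(n: int, dt: float, hurst: float, seed: int = 0) -> np.ndarray:
    """Fractional Brownian motion with MSD ~ t^(2H), Davies-Harte synthesis.

    The increments are stationary fractional Gaussian noise with unit
    variance per step; H = 0.5 recovers ordinary Brownian motion.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    g = _rng(seed)
    m = n - 1
    k = np.arange(m + 1, dtype=float)
    # fGn autocovariance gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(row).real
    if np.min(eig) < -1e-8:
        raise RuntimeError("Davies-Harte circulant not PSD for this n, H")
    eig = np.clip(eig, 0.0, None)
    L = row.shape[0]
    z = g.normal(size=L) + 1j * g.normal(size=L)
    noise = np.fft.fft(np.sqrt(eig / (2.0 * L)) * z)
    fgn = noise.real[:m]
    return np.concatenate([[0.0], np.cumsum(fgn)])


def poisson_train(rate: float, t_max: float, seed: int = 0) -> np.ndarray:
    """Sorted event times of a homogeneous Poisson process on [0, t_max)."""
    g = _rng(seed)
    n = g.poisson(rate * t_max)
    return np.sort(g.uniform(0.0, t_max, size=n))


def memoryless_jump_series(
    n: int,
    dt: float,
    nu: float,
    draw: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Series that is completely redrawn at Poisson(nu) jump times.

    Between jumps the value is frozen; at each jump a fresh value is drawn
    from the equilibrium distribution (default: the radial part of a 3-D
    standard Gaussian, i.e. a Maxwell-distributed end-to-end-like distance).
    This is the jump picture in which a single event erases all memory of
    the observable.
    """
    g = _rng(seed)
    if draw is None:
        draw = lambda rng, size: np.linalg.norm(rng.normal(size=(size, 3)), axis=1)
    t_max = n * dt
    jumps = poisson_train(nu, t_max, seed=seed + 1)
    values = draw(g, jumps.shape[0] + 1)
    grid = dt * np.arange(n)
    idx = np.searchsorted(jumps, grid, side="right")
    return values[idx]
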