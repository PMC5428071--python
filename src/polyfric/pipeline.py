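"""Experiment orchestration: Rouse references, (N, eps) regime sweeps, the
additive interpolation fit tau_EE = a tau_R + b tau_dih, segment
reconfiguration times and Kuhn-length calibration.

A regime sweep simulates the coarse-grained chain over a grid of lengths N
and dihedral barriers eps, measures per condition the end-to-end distance
relaxation time tau_EE, the end-to-end vector time tau_V, the (end-excluded)
average dihedral time tau_dih, the short-time subdiffusion exponent alpha
and the centroid diffusion coefficient, and the fit resolves the
solvent-friction (Rouse) and barrier-friction contributions: a single
(a, b) pair describing all lengths and barriers — with b independent of N —
is the signature that internal friction is a single, chain-length-free
timescale proportional to the dihedral hopping time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chain import CGChainConfig
from .correlators import acf_scalar, acf_vector, msd_moments, translational_diffusion
from .dihedral_stats import dihedral_relaxation_profile
from .langevin import Trajectory, run_langevin

__all__ = [
    "ROUSE_C",
    "RouseReference",
    "RunPolicy",
    "RegimeRecord",
    "InterpolationFit",
    "KuhnEstimate",
    "rouse_slowest_mode_time",
    "rouse_time",
    "analyze_trajectory",
    "run_regime_grid",
    "records_to_dataframe",
    "fit_interpolation",
    "segment_relaxation_time",
    "kuhn_length_estimate",
    "DEFAULT_GRID",
    "FAST_GRID",
]

#: numerical factor c of the slowest Rouse mode: tau_R = c <R^2> / D_tr
ROUSE_C = 1.0 / (3.0 * np.pi**2)

#: full study grid (lengths, barriers in kBT)
DEFAULT_GRID = ((10, 20, 33, 66), (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0))
#: reduced grid for desk-scale runs
FAST_GRID = ((10, 20, 33), (0.0, 2.0, 4.0, 5.0))


class DegenerateFitError(RuntimeError):
    """Raised when the interpolation design matrix cannot separate a and b."""


@dataclass(frozen=True)
class RouseReference:
    """Rouse-model reference timescale tau_R = c <R^2> / D_tr."""

    tau_R: float
    c: float
    D_tr: float
    R2_mean: float

    def __post_init__(self) -> None:
        if self.tau_R <= 0 or self.c <= 0:
            raise ValueError("tau_R and c must be positive")


def rouse_slowest_mode_time(N: int, b2: float, xi0: float = 1.0, kBT: float = 1.0) -> float:
    """Slowest normal-mode time of the free-draining Gaussian chain,
    tau_1 = xi0 N^2 b^2 / (3 pi^2 kBT), with b^2 the mean-square bond (or
    Kuhn-scaled segment) length."""
    return xi0 * N**2 * b2 / (3.0 * np.pi**2 * kBT)


def rouse_time(
    config: CGChainConfig,
    R2_mean: float,
    D_tr: float | None = None,
    c: float = ROUSE_C,
) -> RouseReference:
    """Rouse reference time c <R^2> / D_tr for a chain configuration.

    ``D_tr`` defaults to the free-draining value kBT / (N xi0); pass a
    measured coefficient to override.  ``c`` defaults to pi^-2/3, the
    slowest-mode factor; it may be overridden by a measured ratio.
    """
    if R2_mean <= 0:
        raise ValueError("R2_mean must be positive")
    if D_tr is None:
        D_tr = config.kBT / (config.N * config.xi0)
    if D_tr <= 0 or c <= 0:
        raise ValueError("D_tr and c must be positive")
    return RouseReference(tau_R=c * R2_mean / D_tr, c=c, D_tr=D_tr, R2_mean=R2_mean)


@dataclass(frozen=True)
class RunPolicy:
    """Run-length policy for regime sweeps.

    A pilot run of ``pilot_steps`` estimates tau_EE; the production run
    length is max(``target_taus`` * tau_EE / dt, ``min_steps``), capped at
    ``max_steps`` (a capped, still-unconverged ACF flags the record).  The
    reported values per condition average ``n_seeds`` independent runs, the
    quoted error being the seed-to-seed standard error.
    """

    pilot_steps: int = 1_000_000
    target_taus: float = 100.0
    min_steps: int = 10_000_000
    max_steps: int = 50_000_000
    stride: int = 100
    n_seeds: int = 4
    msd_orders: tuple[int, ...] = (1, 2)

    def production_steps(self, tau_ee_pilot: float, dt: float) -> int:
        need = int(self.target_taus * tau_ee_pilot / dt)
        return int(np.clip(need, self.min_steps, self.max_steps))


@dataclass
class RegimeRecord:
    """Measured timescales of one (N, eps) condition."""

    N: int
    eps_dih: float
    tau_EE: float
    tau_EE_err: float
    tau_V: float
    tau_dih: float
    tau_R: float
    alpha: float
    D_tr: float
    R2_mean: float
    tau_dih_spread: float
    n_steps: int
    seeds: tuple[int, ...]
    converged: bool

    def as_dict(self) -> dict:
        return {
            "N": self.N,
            "eps_dih": self.eps_dih,
            "tau_EE": self.tau_EE,
            "tau_EE_err": self.tau_EE_err,
            "tau_V": self.tau_V,
            "tau_dih": self.tau_dih,
            "tau_R": self.tau_R,
            "alpha": self.alpha,
            "D_tr": self.D_tr,
            "R2_mean": self.R2_mean,
            "tau_dih_spread": self.tau_dih_spread,
            "n_steps": self.n_steps,
            "converged": self.converged,
        }


def analyze_trajectory(traj: Trajectory) -> dict:
    """Observable layer applied to one trajectory.

    Returns tau_EE, tau_V, the end-excluded average tau_dih and its
    max/min spread, the subdiffusion exponent alpha of the end-to-end
    distance, the centroid diffusion coefficient, <R^2>, and convergence
    flags of the ACF integrals.
    """
    dt_frame = traj.frame_dt
    r = traj.end_to_end_distance()
    rvec = traj.end_to_end_vector()
    ee = acf_scalar(r, dt=dt_frame)
    vv = acf_vector(rvec, dt=dt_frame)
    prof = dihedral_relaxation_profile(traj.dihedral_series(), dt=dt_frame)
    ms = msd_moments(r, orders=(1, 2), dt=dt_frame)
    d_tr, d_ok = translational_diffusion(traj.centroid(), dt=dt_frame)
    return {
        "tau_EE": ee.tau,
        "tau_V": vv.tau,
        "tau_dih": prof["tau_mean"],
        "tau_dih_spread": prof["spread"],
        "tau_dih_profile": prof["taus"],
        "alpha": ms.alpha,
        "D_tr": d_tr,
        "D_tr_reliable": d_ok,
        "R2_mean": float(np.mean(r**2)),
        # the interpolation fit consumes tau_EE, so its convergence is what
        # gates a record; tau_V convergence is reported separately
        "converged": bool(ee.converged),
        "converged_V": bool(vv.converged),
    }


def _measure_condition(
    config: CGChainConfig, policy: RunPolicy, seeds: tuple[int, ...]
) -> RegimeRecord:
    pilot = run_langevin(config, policy.pilot_steps, seed=seeds[0], stride=policy.stride)
    tau_pilot = acf_scalar(pilot.end_to_end_distance(), dt=pilot.frame_dt).tau
    n_steps = policy.production_steps(tau_pilot, config.dt)
    results = []
    for s in seeds:
        traj = run_langevin(config, n_steps, seed=s, stride=policy.stride)
        results.append(analyze_trajectory(traj))
        del traj
    taus = np.array([r["tau_EE"] for r in results])
    err = float(taus.std(ddof=1) / np.sqrt(len(taus))) if len(taus) > 1 else float("nan")
    mean = lambda key: float(np.mean([r[key] for r in results]))
    r2 = mean("R2_mean")
    ref = rouse_time(config, r2)
    return RegimeRecord(
        N=config.N,
        eps_dih=config.eps_dih,
        tau_EE=float(taus.mean()),
        tau_EE_err=err,
        tau_V=mean("tau_V"),
        tau_dih=mean("tau_dih"),
        tau_R=ref.tau_R,
        alpha=mean("alpha"),
        D_tr=mean("D_tr"),
        R2_mean=r2,
        tau_dih_spread=mean("tau_dih_spread"),
        n_steps=n_steps,
        seeds=tuple(int(s) for s in seeds),
        converged=all(r["converged"] for r in results),
    )


def run_regime_grid(
    lengths: tuple[int, ...],
    barriers: tuple[float, ...],
    policy: RunPolicy | None = None,
    seed: int = 0,
    base_config: CGChainConfig | None = None,
) -> list[RegimeRecord]:
    """Simulate and analyse every (N, eps) condition of the grid.

    Conditions whose end-to-end ACF never converged within the step budget
    are flagged (``converged=False``) so that fits can exclude them.
    """
    policy = policy or RunPolicy()
    base = base_config or CGChainConfig()
    records = []
    ss = np.random.SeedSequence([int(seed), 0x67726964])
    seed_pool = iter(ss.generate_state(len(lengths) * len(barriers) * policy.n_seeds) >> 1)
    for N in lengths:
        for eps in barriers:
            config = replace(base, N=int(N), eps_dih=float(eps))
            seeds = tuple(int(next(seed_pool)) for _ in range(policy.n_seeds))
            records.append(_measure_condition(config, policy, seeds))
    return records


def records_to_dataframe(records: list[RegimeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


@dataclass
class InterpolationFit:
    """Global least-squares fit of tau_EE = a tau_R + b tau_dih."""

    a: float
    b: float
    a_err: float
    b_err: float
    covariance: np.ndarray
    residuals: np.ndarray
    tau_i_per_record: np.ndarray
    n_records: int
    b_poorly_determined: bool = False

    def predict(self, tau_R: np.ndarray, tau_dih: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(tau_R) + self.b * np.asarray(tau_dih)


def fit_interpolation(
    records: list[RegimeRecord],
    require_span: bool = True,
) -> InterpolationFit:
    """Fit (a, b) of tau_EE = a tau_R + b tau_dih across all records.

    Linear least squares without intercept, each record weighted by the
    inverse of its tau_EE standard error (relative-error weighting falls
    back to 3% of tau_EE when no seed-to-seed error is available).
    Unconverged records are excluded.  Requires records spanning at least
    two chain lengths and three barriers unless ``require_span=False``.
    """
    recs = [r for r in records if r.converged]
    if len(recs) < 4:
        raise DegenerateFitError(f"need >= 4 converged records, got {len(recs)}")
    if require_span:
        if len({r.N for r in recs}) < 2 or len({r.eps_dih for r in recs}) < 3:
            raise DegenerateFitError("records must span >= 2 lengths and >= 3 barriers")
    tau_ee = np.array([r.tau_EE for r in recs])
    tau_r = np.array([r.tau_R for r in recs])
    tau_d = np.array([r.tau_dih for r in recs])
    err = np.array([r.tau_EE_err for r in recs])
    fallback = 0.03 * tau_ee
    w = 1.0 / np.where(np.isfinite(err) & (err > 0), err, fallback)
    X = np.column_stack([tau_r, tau_d]) * w[:, None]
    y = tau_ee * w
    # conditioning check: all records in one regime make the design rank-1
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise DegenerateFitError("design matrix is rank deficient; records span a single regime")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(recs) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    a, b = float(coef[0]), float(coef[1])
    a_err, b_err = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return InterpolationFit(
        a=a,
        b=b,
        a_err=a_err,
        b_err=b_err,
        covariance=cov,
        residuals=(tau_ee - a * tau_r - b * tau_d),
        tau_i_per_record=b * tau_d,
        n_records=len(recs),
        b_poorly_determined=bool(b_err > 0.5 * abs(b) if b != 0 else True),
    )


def segment_relaxation_time(traj: Trajectory, i: int, j: int):
    """Integral relaxation time of the inter-monomer distance |r_i - r_j|.

    ``segment_relaxation_time(traj, 0, N-1)`` is the standard tau_EE.  At
    low dihedral barriers shorter segments relax faster than the whole chain
    (Rouse mode structure); in the barrier-friction limit the times converge
    to a single, segment-length-independent value.
    """
    if not 0 <= i < j < traj.frames.shape[1]:
        raise ValueError("need 0 <= i < j < N")
    return acf_scalar(traj.segment_distance(i, j), dt=traj.frame_dt)


@dataclass(frozen=True)
class KuhnEstimate:
    """Kuhn length l_k = <R^2> / L and derived segment counts."""

    l_k: float
    L: float
    n_k: float
    rho: float

    def __post_init__(self) -> None:
        if self.l_k <= 0 or self.n_k <= 0:
            raise ValueError("l_k and n_k must be positive")


def kuhn_length_estimate(R2_mean: float, config: CGChainConfig) -> KuhnEstimate:
    """Kuhn segment statistics from the measured mean-square end-to-end
    distance: l_k = <R^2> / L with contour length L = (N - 1) sigma.

    The default bending angle (100 degrees) is calibrated so that the full
    default model — bending stiffness plus excluded-volume swelling — gives
    l_k / sigma of about 3 at desk-scale chain lengths, the stiffness of
    real polypeptides.
    """
    if R2_mean <= 0:
        raise ValueError("R2_mean must be positive")
    L = (config.N - 1) * config.sigma
    l_k = R2_mean / L
    return KuhnEstimate(l_k=l_k, L=L, n_k=L / l_k, rho=float(np.sqrt(R2_mean)))
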