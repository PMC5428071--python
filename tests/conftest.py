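"""Shared fixtures.

The expensive session fixtures (regime grid, high-barrier runs) live here so
that the acceptance-level tests and the per-module tests reuse the same
simulations instead of re-running them.
"""

from __future__ import annotations

import numpy as np
import pytest

import polyfric as pf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_traj():
    """Short N=10, eps=2 trajectory shared by plumbing tests."""
    cfg = pf.CGChainConfig(N=10, eps_dih=2.0)
    return pf.run_langevin(cfg, 400_000, seed=42, stride=40)


def _ratio_measurement(cfg, seeds, n_steps=8_000_000, stride=50):
    """Seed-averaged tau_EE, tau_V, tau_R (single-seed estimates of these
    integral times carry ~10-15% noise, so the headline ratios average)."""
    ee, vv, r2 = [], [], []
    for seed in seeds:
        traj = pf.run_langevin(cfg, n_steps, seed=seed, stride=stride)
        r = traj.end_to_end_distance()
        ee.append(pf.acf_scalar(r, dt=traj.frame_dt).tau)
        vv.append(pf.acf_vector(traj.end_to_end_vector(), dt=traj.frame_dt).tau)
        r2.append(float(np.mean(r**2)))
        del traj
    tau_r = pf.rouse_time(cfg, float(np.mean(r2))).tau_R
    return {"tau_EE": float(np.mean(ee)), "tau_V": float(np.mean(vv)), "tau_R": tau_r}


@pytest.fixture(scope="session")
def gaussian_ratios_n33():
    """Averaged relaxation-time ratios of the Gaussian phantom chain."""
    return _ratio_measurement(pf.CGChainConfig(N=33).gaussian(), (111, 112, 113))


@pytest.fixture(scope="session")
def full_chain_ratios_n33(ev_traj_n33_eps0):
    """Averaged ratios of the full (EV-on) chain at zero barrier; reuses the
    shared trajectory for one of the seeds."""
    traj = ev_traj_n33_eps0
    r = traj.end_to_end_distance()
    base = {
        "tau_EE": [pf.acf_scalar(r, dt=traj.frame_dt).tau],
        "tau_V": [pf.acf_vector(traj.end_to_end_vector(), dt=traj.frame_dt).tau],
    }
    extra = _ratio_measurement(traj.config, (121, 122))
    return {
        "tau_EE": float(np.mean(base["tau_EE"] + [extra["tau_EE"]])),
        "tau_V": float(np.mean(base["tau_V"] + [extra["tau_V"]])),
    }


@pytest.fixture(scope="session")
def ev_traj_n33_eps0():
    """Full chain (EV on) at zero barrier, N=33: the Rouse-regime condition."""
    cfg = pf.CGChainConfig(N=33, eps_dih=0.0)
    return pf.run_langevin(cfg, 12_000_000, seed=102, stride=50)


@pytest.fixture(scope="session")
def barrier_traj_n20_eps5():
    """High-barrier condition N=20, eps=5 kBT: the barrier-friction regime."""
    cfg = pf.CGChainConfig(N=20, eps_dih=5.0)
    return pf.run_langevin(cfg, 16_000_000, seed=103, stride=100)


@pytest.fixture(scope="session")
def grid_records():
    """Reduced (N, eps) sweep reused by the regime and interpolation tests."""
    lengths, barriers = pf.pipeline.FAST_GRID
    policy = pf.RunPolicy(
        pilot_steps=600_000,
        target_taus=100.0,
        min_steps=3_000_000,
        max_steps=16_000_000,
        stride=100,
        n_seeds=2,
    )
    return pf.run_regime_grid(lengths, barriers, policy=policy, seed=7)
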