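"""Flip detection, dwell statistics and pair lag-time correlation tests."""

import numpy as np
import pytest
from scipy import integrate

import polyfric as pf
from polyfric import synthetic as syn
from polyfric.chain import WELL_CENTERS
from polyfric.dihedral_stats import detect_flips, dwell_and_poisson, pair_lag_analysis


def log_from_trains(trains):
    """Build a FlipEventLog from bare event-time arrays (wells alternate)."""
    times, fr, to = [], [], []
    for t in trains:
        n = t.shape[0]
        w = np.arange(n) % 2
        times.append(np.asarray(t, dtype=float))
        fr.append(w)
        to.append((w + 1) % 2)
    return pf.FlipEventLog(times=times, from_well=fr, to_well=to, hysteresis_deg=0.0)


class TestDetectFlips:
    def test_square_wave_one_event_per_edge(self):
        ang = np.tile(np.concatenate([np.full(50, WELL_CENTERS[0]), np.full(50, WELL_CENTERS[1])]), 20)
        log = detect_flips(ang, dt=1.0)
        assert log.n_events(0) == 39  # one per edge after the initial segment
        assert np.all(log.from_well[0] != log.to_well[0])

    def test_kmc_path_recovered_exactly(self):
        # no intra-well noise: detected events equal the KMC event list for
        # every dihedral whose events are resolved by the sampling grid (two
        # jumps inside one sample bin are indistinguishable by construction)
        cfg = pf.RismConfig(N=6, k=1.0, t_max=100.0, record_dt=1e-4)
        path = pf.run_rism_kmc(cfg, seed=1)
        grid = np.arange(0.0, cfg.t_max, cfg.record_dt)
        from polyfric.rism import sample_angle_series

        ang = sample_angle_series(path, grid)
        log = detect_flips(ang, dt=cfg.record_dt, hysteresis_deg=20.0)
        checked = 0
        for d in range(cfg.n_dihedrals):
            kmc_t = path.times[d]
            if kmc_t.size < 2 or np.min(np.diff(kmc_t)) <= 2 * cfg.record_dt:
                continue
            checked += 1
            assert log.n_events(d) == kmc_t.shape[0]
            assert np.all(np.abs(log.times[d] - kmc_t) <= cfg.record_dt)
            assert np.array_equal(log.to_well[d], path.states[d])
        assert checked >= 1

    def test_buffer_suppresses_rapid_recrossing(self):
        # dither across the well edge (+/- 62 deg) never reaches a new core
        edge = np.deg2rad(62.0)
        ang = np.where(np.arange(2000) % 2 == 0, edge, -edge) * 0.0 + np.where(
            np.arange(2000) % 2 == 0, np.deg2rad(55.0), np.deg2rad(65.0)
        )
        log = detect_flips(ang, dt=1.0, hysteresis_deg=20.0)
        assert log.n_events(0) == 0

    def test_time_reversal_gives_equal_counts(self):
        rng = np.random.default_rng(2)
        ang = np.cumsum(rng.normal(0, 0.3, size=5000))  # angular random walk
        fwd = detect_flips(np.angle(np.exp(1j * ang)), dt=1.0)
        rev = detect_flips(np.angle(np.exp(1j * ang[::-1])), dt=1.0)
        assert fwd.n_events(0) == rev.n_events(0)

    def test_hysteresis_monotonicity(self):
        rng = np.random.default_rng(3)
        ang = np.angle(np.exp(1j * np.cumsum(rng.normal(0, 0.25, size=20000))))
        counts = [detect_flips(ang, hysteresis_deg=h).n_events(0) for h in (0.0, 10.0, 20.0, 40.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_langevin_flip_rate_matches_smoluchowski_mfpt(self, barrier_mfpt_traj):
        """Mean flip rate of a high-barrier Langevin dihedral agrees within
        30% with 2x the Kramers rate from a 1D mean-first-passage quadrature
        on V_dih, using the angular diffusion coefficient measured at short
        lags."""
        traj, eps = barrier_mfpt_traj
        phi = traj.dihedral_series()
        dt = traj.frame_dt
        # measured flip rate (interior dihedrals)
        log = detect_flips(phi, dt=dt)
        interior = range(1, phi.shape[1] - 1)
        t_total = traj.times[-1]
        rate_sim = np.mean([log.n_events(d) / t_total for d in interior])
        # angular short-time diffusion coefficient (2-frame displacement)
        dphi = np.angle(np.exp(1j * (phi[1:] - phi[:-1])))
        D_phi = float(np.mean(dphi[:, list(interior)] ** 2)) / (2 * dt)
        # MFPT from the well minimum to the adjacent minimum, reflecting wall
        # behind: tau = (1/D) int_0^L dy e^{V(y)} int_{-pi/3}^{y} e^{-V(x)} dx
        V = lambda x: 0.5 * eps * (1 - np.cos(3 * x))
        y = np.linspace(0.0, 2 * np.pi / 3, 2001)
        inner = np.array(
            [integrate.quad(lambda x: np.exp(-V(x)), -np.pi / 3, yy)[0] for yy in y[:: 40]]
        )
        inner = np.interp(y, y[::40], inner)
        tau_mfpt = integrate.trapezoid(np.exp([V(v) for v in y]) * inner, y) / D_phi
        rate_pred = 2.0 / tau_mfpt
        assert rate_sim == pytest.approx(rate_pred, rel=0.30)


@pytest.fixture(scope="session")
def barrier_mfpt_traj():
    eps = 6.0
    cfg = pf.CGChainConfig(N=8, eps_dih=eps, dt=5e-4)
    return pf.run_langevin(cfg, 12_000_000, seed=31, stride=10), eps


class TestDwellStats:
    def test_rism_dwells_exponential(self):
        cfg = pf.RismConfig(N=4, k=2.0, t_max=2_000.0, record_dt=0.002)
        path = pf.run_rism_kmc(cfg, seed=4)
        grid = np.arange(0.0, cfg.t_max, cfg.record_dt)
        from polyfric.rism import sample_angle_series

        log = detect_flips(sample_angle_series(path, grid), dt=cfg.record_dt)
        st = dwell_and_poisson(log, 0)
        assert st.mean_dwell == pytest.approx(1.0 / (2 * cfg.k), rel=0.05)
        assert st.poisson_consistent(alpha=0.01)

    def test_periodic_flipping_rejected(self):
        trains = [np.arange(1.0, 200.0, 1.0)]
        st = dwell_and_poisson(log_from_trains(trains), 0)
        assert not st.poisson_consistent(alpha=0.01)

    def test_superposed_poisson_trains_still_poisson(self):
        a = syn.poisson_train(1.0, 2000.0, seed=5)
        b = syn.poisson_train(2.0, 2000.0, seed=6)
        merged = np.sort(np.concatenate([a, b]))
        st = dwell_and_poisson(log_from_trains([merged]), 0)
        assert st.poisson_consistent(alpha=0.01)
        assert st.mean_dwell == pytest.approx(1.0 / 3.0, rel=0.1)

    def test_too_few_events_raises(self):
        with pytest.raises(pf.InsufficientEventsError, match="5 events"):
            dwell_and_poisson(log_from_trains([np.arange(5.0)]), 0)


class TestPairLag:
    def test_independent_trains_pass_null_in_95_percent_of_seeds(self):
        passed = 0
        for seed in range(100):
            a = syn.poisson_train(1.0, 600.0, seed=1000 + seed)
            b = syn.poisson_train(1.0, 600.0, seed=5000 + seed)
            log = log_from_trains([a, b])
            res = pair_lag_analysis(log, 0, 1, tau_i=1.0, tau_j=1.0)
            if not res.rejected(alpha=0.01):
                passed += 1
        assert passed >= 95

    def test_injected_coincidences_rejected_with_excess_short_lags(self):
        rng = np.random.default_rng(7)
        a = syn.poisson_train(1.0, 3000.0, seed=8)
        b = syn.poisson_train(1.0, 3000.0, seed=9)
        dup = a[rng.random(a.shape[0]) < 0.15] + rng.exponential(0.02, size=None)
        b = np.sort(np.concatenate([b, dup]))
        res = pair_lag_analysis(log_from_trains([a, b]), 0, 1, tau_i=1.0, tau_j=1.0)
        assert res.rejected(alpha=0.01)
        assert res.excess_short_lags

    def test_adjacent_pair_more_correlated_than_distant(self, barrier_traj_n20_eps5):
        """Concerted rotations: the lag-test deviation statistic decays with
        sequence separation on a high-barrier Langevin chain."""
        traj = barrier_traj_n20_eps5
        phi = traj.dihedral_series()
        dt = traj.frame_dt
        log = detect_flips(phi, dt=dt)
        taus = [pf.acf_dihedral(phi[:, d], dt=dt).tau for d in range(phi.shape[1])]
        mid = phi.shape[1] // 2
        near = pair_lag_analysis(log, mid, mid + 1, taus[mid], taus[mid + 1])
        far = pair_lag_analysis(log, 2, phi.shape[1] - 3, taus[2], taus[-3])
        assert near.signed_statistic > far.signed_statistic


class TestRelaxationProfile:
    def test_rism_profile_flat(self):
        cfg = pf.RismConfig(N=14, k=1.0, t_max=4_000.0, record_dt=0.05)
        path = pf.run_rism_kmc(cfg, seed=10)
        grid = np.arange(0.0, cfg.t_max, cfg.record_dt)
        from polyfric.rism import sample_angle_series

        prof = pf.dihedral_relaxation_profile(sample_angle_series(path, grid), dt=cfg.record_dt)
        assert prof["spread"] < 1.3
        assert prof["tau_mean"] == pytest.approx(1 / 3, rel=0.1)

    def test_langevin_ends_relax_faster_than_middle(self, barrier_traj_n20_eps5):
        traj = barrier_traj_n20_eps5
        prof = pf.dihedral_relaxation_profile(traj.dihedral_series(), dt=traj.frame_dt)
        taus = prof["taus"]
        edge = np.mean([taus[0], taus[1], taus[-2], taus[-1]])
        assert edge < prof["tau_mean"]
        assert prof["spread"] > 1.0  # reported as max/min over positions

    def test_too_short_chain_raises(self):
        with pytest.raises(ValueError, match="interior"):
            pf.dihedral_relaxation_profile(np.zeros((100, 5)))


class TestBarrierScaling:
    def test_tau_dih_grows_exponentially_with_eps(self):
        """log tau_dih vs eps is linear with positive slope (R^2 >= 0.98)."""
        taus = []
        barriers = (2.0, 3.0, 4.0, 5.0, 6.0)
        # run lengths sized to >= 150 dihedral relaxation times per seed
        steps = {2.0: 2_000_000, 3.0: 3_000_000, 4.0: 5_000_000, 5.0: 8_000_000, 6.0: 14_000_000}
        for eps in barriers:
            cfg = pf.CGChainConfig(N=10, eps_dih=eps)
            vals = []
            for seed in (77, 78):
                traj = pf.run_langevin(cfg, steps[eps], seed=seed, stride=100)
                prof = pf.dihedral_relaxation_profile(traj.dihedral_series(), dt=traj.frame_dt)
                vals.append(prof["tau_mean"])
                del traj
            taus.append(np.mean(vals))
        y = np.log(taus)
        slope, intercept = np.polyfit(barriers, y, 1)
        pred = slope * np.array(barriers) + intercept
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert slope > 0
        assert r2 >= 0.98
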