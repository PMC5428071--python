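"""Geometry, energy and construction invariants of the coarse-grained chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import polyfric as pf
from polyfric.chain import EV_MIN_SEPARATION, WELL_CENTERS


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def brute_force_energy(pos, cfg):
    """Term-by-term loop re-implementation, independent of the package path."""
    e_bond = sum(
        0.5 * cfg.k_bond * (np.linalg.norm(pos[i + 1] - pos[i]) - cfg.sigma) ** 2
        for i in range(cfg.N - 1)
    )
    e_bend = 0.0
    for j in range(1, cfg.N - 1):
        u, v = pos[j - 1] - pos[j], pos[j + 1] - pos[j]
        th = np.arccos(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v))
        e_bend += 0.5 * cfg.k_bend * (th - cfg.theta0) ** 2
    e_dih = 0.0
    for i in range(cfg.N - 3):
        phi = pf.dihedral_angles(pos[i : i + 4])[0]
        e_dih += 0.5 * cfg.eps_dih * (1 - np.cos(3 * phi))
    e_ev = 0.0
    for i in range(cfg.N):
        for j in range(i + EV_MIN_SEPARATION, cfg.N):
            r = np.linalg.norm(pos[j] - pos[i])
            if r < cfg.ev_cutoff:
                e_ev += cfg.ev_strength * ((cfg.sigma / r) ** 12 - (cfg.sigma / cfg.ev_cutoff) ** 12)
    return e_bond, e_bend, e_dih, e_ev


class TestBuildChain:
    def test_exact_geometry_small(self):
        cfg = pf.CGChainConfig(N=4)
        pos = pf.build_chain(cfg, seed=0)
        assert np.allclose(pf.bond_lengths(pos), 1.0)
        assert np.allclose(pf.bend_angles(pos), cfg.theta0)
        phi = pf.dihedral_angles(pos)
        assert phi.shape == (1,)
        assert np.min(np.abs(np.angle(np.exp(1j * (phi[0] - WELL_CENTERS))))) < 1e-9

    def test_deterministic(self):
        cfg = pf.CGChainConfig(N=66)
        a = pf.build_chain(cfg, seed=9)
        b = pf.build_chain(cfg, seed=9)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, pf.build_chain(cfg, seed=10))

    @pytest.mark.parametrize("N", [4, 7, 10, 33, 66, 100])
    def test_geometry_invariants_many_seeds(self, N):
        cfg = pf.CGChainConfig(N=N)
        cut2 = cfg.ev_cutoff**2
        for seed in range(50):
            pos = pf.build_chain(cfg, seed)
            assert np.allclose(pf.bond_lengths(pos), cfg.sigma, atol=1e-9)
            assert np.allclose(pf.bend_angles(pos), cfg.theta0, atol=1e-9)
            i, j = np.triu_indices(N, k=EV_MIN_SEPARATION)
            if i.size:
                r2 = np.sum((pos[i] - pos[j]) ** 2, axis=1)
                assert np.all(r2 >= cut2 - 1e-12)

    def test_mean_square_end_to_end_matches_rejection_oracle(self):
        """<R^2> of the 3-well builder equals a freely-rotating-chain MC
        sampler with the same geometry and clash rule: with equal well
        populations the first-order orientation correlations coincide."""
        cfg = pf.CGChainConfig(N=20)
        r2_build = np.array(
            [np.sum((p[-1] - p[0]) ** 2) for p in (pf.build_chain(cfg, s) for s in range(400))]
        )
        # independent oracle: continuous uniform dihedrals + same rejection
        rng = np.random.default_rng(999)
        from polyfric.rism import reconstruct_chain

        r2_frc = []
        while len(r2_frc) < 400:
            phis = rng.uniform(-np.pi, np.pi, size=cfg.N - 3)
            pos = reconstruct_chain(phis, cfg.sigma, cfg.theta0)
            i, j = np.triu_indices(cfg.N, k=EV_MIN_SEPARATION)
            if np.all(np.sum((pos[i] - pos[j]) ** 2, axis=1) >= cfg.ev_cutoff**2):
                r2_frc.append(np.sum((pos[-1] - pos[0]) ** 2))
        r2_frc = np.array(r2_frc)
        se = np.sqrt(r2_build.var() / r2_build.size + r2_frc.var() / r2_frc.size)
        assert abs(r2_build.mean() - r2_frc.mean()) < 3 * se

    def test_construction_error_reports_index(self):
        # an absurdly large clash radius makes placement impossible
        cfg = pf.CGChainConfig(N=10, ev_cutoff=5.0)
        with pytest.raises(pf.ChainConstructionError, match=r"bead \d+"):
            pf.build_chain(cfg, seed=0, max_restarts=5)


class TestDihedralAngles:
    def test_planar_trans_zigzag_is_pi(self):
        from polyfric.rism import reconstruct_chain

        pos = reconstruct_chain(np.full(5, np.pi), 1.0, 2 * np.pi / 3)
        assert np.allclose(np.abs(pf.dihedral_angles(pos)), np.pi)
        assert np.allclose(pos[:, 2], 0.0)  # planar

    def test_right_handed_quarter_twist_is_positive(self):
        # independent vector-algebra oracle: place the far bond a quarter turn
        # clockwise when sighting along the central bond
        pos = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 0.0, 1.0]])
        assert pf.dihedral_angles(pos)[0] == pytest.approx(np.pi / 2, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pos = pf.build_chain(pf.CGChainConfig(N=8), seed % 50) + 0.05 * rng.normal(size=(8, 3))
        R = random_rotation(seed)
        moved = pos @ R.T + rng.normal(size=3)
        assert np.allclose(pf.dihedral_angles(moved), pf.dihedral_angles(pos), atol=1e-12)

    def test_matches_mdtraj_convention(self):
        # independent reference implementation of the torsion convention
        import mdtraj as md

        rng = np.random.default_rng(7)
        pos = rng.normal(size=(8, 3))
        top = md.Topology()
        chain = top.add_chain()
        prev = None
        for _ in range(8):
            res = top.add_residue("ALA", chain)
            atom = top.add_atom("CA", md.element.carbon, res)
            if prev is not None:
                top.add_bond(prev, atom)
            prev = atom
        t = md.Trajectory(pos[None].astype(np.float32), top)
        quads = np.array([[i, i + 1, i + 2, i + 3] for i in range(5)])
        ref = md.compute_dihedrals(t, quads)[0]
        mine = pf.dihedral_angles(pos)
        assert np.allclose(np.angle(np.exp(1j * (mine - ref))), 0.0, atol=1e-5)

    def test_collinear_raises(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1, 0]])
        with pytest.raises(ValueError, match="collinear"):
            pf.dihedral_angles(pos)


class TestPotentialEnergy:
    def test_dihedral_term_zero_at_minima_and_eps_at_barrier(self):
        from polyfric.rism import reconstruct_chain

        cfg = pf.CGChainConfig(N=6, eps_dih=3.0)
        at_minima = reconstruct_chain(WELL_CENTERS[[0, 1, 2]], 1.0, cfg.theta0)
        assert pf.potential_energy(at_minima, cfg).dihedral == pytest.approx(0.0, abs=1e-9)
        one_barrier = reconstruct_chain(np.array([np.pi / 3, 0.0, 0.0]), 1.0, cfg.theta0)
        assert pf.potential_energy(one_barrier, cfg).dihedral == pytest.approx(cfg.eps_dih, abs=1e-9)

    def test_matches_brute_force_reimplementation(self):
        rng = np.random.default_rng(5)
        cfg = pf.CGChainConfig(N=10, eps_dih=2.5)
        pos = pf.build_chain(cfg, 3) + 0.08 * rng.normal(size=(10, 3))
        e = pf.potential_energy(pos, cfg)
        eb, et, ed, ev = brute_force_energy(pos, cfg)
        assert e.bond == pytest.approx(eb, abs=1e-10)
        assert e.bend == pytest.approx(et, abs=1e-10)
        assert e.dihedral == pytest.approx(ed, abs=1e-10)
        assert e.excluded_volume == pytest.approx(ev, abs=1e-10)
        assert e.total == pytest.approx(eb + et + ed + ev, abs=1e-10)

    def test_ev_term_active_for_compressed_pair(self):
        cfg = pf.CGChainConfig(N=8)
        pos = pf.build_chain(cfg, 1)
        pos[7] = pos[0] + np.array([1.2, 0.0, 0.0])  # force a 0-7 contact
        e = pf.potential_energy(pos, cfg)
        expected = cfg.ev_strength * ((1.0 / 1.2) ** 12 - 0.5**12)
        assert e.excluded_volume >= expected - 1e-9

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        cfg = pf.CGChainConfig(N=9, eps_dih=1.5)
        pos = pf.build_chain(cfg, seed % 50) + 0.05 * rng.normal(size=(9, 3))
        R = random_rotation(seed + 1)
        moved = pos @ R.T + rng.normal(size=3)
        assert pf.potential_energy(moved, cfg).total == pytest.approx(
            pf.potential_energy(pos, cfg).total, abs=1e-9
        )

    def test_dihedral_potential_scan_has_three_wells_of_depth_eps(self):
        eps = 2.0
        phi = np.linspace(-np.pi, np.pi, 4001)
        V = 0.5 * eps * (1 - np.cos(3 * phi))
        # count strict local minima/maxima on the periodic grid
        Vp = np.roll(V[:-1], 1)
        Vn = np.roll(V[:-1], -1)
        minima = np.sum((V[:-1] < Vp) & (V[:-1] < Vn))
        maxima = np.sum((V[:-1] > Vp) & (V[:-1] > Vn))
        assert minima == 3 and maxima == 3
        assert np.max(V) - np.min(V) == pytest.approx(eps, abs=1e-9)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        pf.CGChainConfig(N=3)
    with pytest.raises(ValueError):
        pf.CGChainConfig(dt=0.0)
    with pytest.raises(ValueError):
        pf.CGChainConfig(eps_dih=-1.0)


def test_well_assignment_partitions_circle():
    phi = np.linspace(-np.pi, np.pi, 3601, endpoint=True)
    w = pf.well_of(phi)
    assert set(np.unique(w)) == {0, 1, 2}
    # each well covers a 120-degree sector around its center
    for k, c in enumerate(WELL_CENTERS):
        sector = np.abs(np.angle(np.exp(1j * (phi - c)))) < np.deg2rad(59.9)
        assert np.all(w[sector] == k)
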