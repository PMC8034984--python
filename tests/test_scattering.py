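"""Coherent ISF components against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy.special import spherical_jn

import rigidnse as rn
from rigidnse.scattering import isf_com, isf_from_beads, isf_rot, isf_total, isf_trans_weighted, make_lag_grid
from rigidnse.trajectory import Trajectory


def identity_quats(n):
    q = np.zeros((n, 4))
    q[:, 0] = 1.0
    return q


def com_only_traj(com, dt=1.0):
    com = np.asarray(com, dtype=float)
    return Trajectory(times=np.arange(len(com)) * dt, com_positions=com,
                      orientations=identity_quats(len(com)))


class TestNormalization:
    def test_lag_zero_is_exactly_one(self, small_mab, mab_tensor):
        traj = rn.run_bd(small_mab, mab_tensor, dt=0.25, n_steps=200, seed=1)
        Q = np.array([0.02, 0.1, 0.2])
        lags = np.array([0.0, 1.0, 5.0])
        for fn in (isf_total, isf_rot, isf_trans_weighted):
            c = fn(traj, small_mab, Q, lags, origin_stride=5)
            assert np.all(c.values[:, c.lag_grid == 0.0] == 1.0)
        c = isf_com(traj, Q, lags, origin_stride=5)
        assert np.all(c.values[:, c.lag_grid == 0.0] == 1.0)

    def test_single_bead_total_equals_com(self, mab_tensor):
        bead = rn.RigidBodyModel(np.zeros((1, 3)))
        traj = rn.run_bd(bead, mab_tensor, dt=0.25, n_steps=2000, seed=2)
        Q = np.array([0.05, 0.1, 0.2])
        lags = make_lag_grid(0.25, 20.0, 8)
        tot = isf_total(traj, bead, Q, lags, origin_stride=10)
        com = isf_com(traj, Q, lags, origin_stride=10)
        assert np.allclose(tot.values, com.values, atol=1e-10)


class TestTotalAgainstOrientationalOracle:
    def test_small_system_matches_random_qhat_average(self):
        # 5 beads, 20 frames of arbitrary rigid motion; single time origin.
        # Oracle: Monte-Carlo average of e^{iQ.(r_m(0)-r_n(t))} over random
        # wavevector directions, the definition the sinc double sum solves.
        rng = np.random.default_rng(42)
        model = rn.RigidBodyModel(rng.uniform(-15, 15, (5, 3)))
        from scipy.spatial.transform import Rotation

        n_frames = 20
        quats_xyzw = Rotation.random(n_frames, random_state=3).as_quat()
        quats = np.column_stack([quats_xyzw[:, 3], quats_xyzw[:, :3]])
        com = np.cumsum(rng.normal(0, 2.0, (n_frames, 3)), axis=0)
        traj = Trajectory(times=np.arange(n_frames, dtype=float),
                          com_positions=com, orientations=quats)
        Q = np.array([0.05, 0.15])
        lag_frames = np.array([0, 3, 11, 19])
        curve = isf_total(traj, model, Q, lag_frames.astype(float),
                          origin_stride=1)
        # with max lag = n-1 only origin 0 is usable -> directly comparable
        assert curve.n_origins.max() == 1

        beads = np.array([traj.bead_positions(model, k) for k in range(n_frames)])
        dirs = rng.standard_normal((20_000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        # exact lag-0 normalizer (closed-form Debye sum, validated separately)
        s0 = rn.form_factor(model, Q) * model.n_beads**2
        for iq, q in enumerate(Q):
            phase0 = np.exp(1j * q * dirs @ beads[0].T)  # (ndir, N)
            A0 = phase0.sum(axis=1)
            for il, l in enumerate(lag_frames):
                phaset = np.exp(1j * q * dirs @ beads[l].T)
                samples = (A0 * phaset.sum(axis=1).conj()).real / s0[iq]
                ratio = samples.mean()
                se = samples.std(ddof=1) / np.sqrt(len(dirs))
                assert abs(curve.values[iq, il] - ratio) < 3 * se + 1e-12

    def test_rigid_reconstruction_matches_explicit_bead_path(self, small_mab,
                                                             mab_tensor):
        traj = rn.run_bd(small_mab, mab_tensor, dt=0.5, n_steps=60, seed=9)
        beads = np.array([traj.bead_positions(small_mab, k)
                          for k in range(traj.n_frames)])
        Q = np.array([0.05, 0.18])
        lagf = np.array([0, 5, 20])
        a = isf_total(traj, small_mab, Q, lagf * 0.5, origin_stride=7)
        b = isf_from_beads(beads, Q, lagf, origin_stride=7, dt=0.5)
        assert np.allclose(a.values, b.values, atol=1e-9)


class TestCom:
    def test_static_trajectory_stays_at_one(self):
        traj = com_only_traj(np.zeros((30, 3)))
        c = isf_com(traj, [0.05, 0.2], [0, 5, 20], origin_stride=1)
        assert np.allclose(c.values, 1.0)

    def test_uniform_drift_gives_sinc(self):
        v = np.array([0.3, 0.0, 0.0])
        t = np.arange(50, dtype=float)
        traj = com_only_traj(t[:, None] * v)
        Q = np.array([0.1, 0.4])
        lags = np.array([0.0, 4.0, 13.0])
        c = isf_com(traj, Q, lags, origin_stride=1)
        speed = np.linalg.norm(v)
        for iq, q in enumerate(Q):
            for il, lag in enumerate(c.lag_grid):
                x = q * speed * lag
                expect = 1.0 if x == 0 else np.sin(x) / x
                assert c.values[iq, il] == pytest.approx(expect, abs=1e-12)

    def test_free_diffusion_log_slope(self, iso_bd_traj):
        # ln Icom decays at rate D0 Q^2 for free isotropic diffusion
        traj, D = iso_bd_traj
        Q = np.array([0.05, 0.1])
        lags = make_lag_grid(0.5, 60.0, 10)
        c = isf_com(traj, Q, lags, origin_stride=20)
        deff = rn.extract_deff(c, (0.5, 60.0), D0_guess=4.0)
        assert np.allclose(deff.values, 4.0, rtol=0.05)


class TestRot:
    def test_dense_shell_is_static(self):
        # spherically symmetric scatterer: coherent rotational ISF ~ 1
        shell = rn.make_spherical_shell(n_beads=1000, radius=45.0)
        D = rn.DiffusionTensor.isotropic(0.0, Dr=3e-3)
        traj = rn.run_bd(shell, D, dt=1.0, n_steps=1500, seed=4)
        Q = np.array([0.02, 0.05, 0.09])  # Q * diameter <= ~8
        lags = make_lag_grid(1.0, 300.0, 6)
        c = isf_rot(traj, shell, Q, lags, origin_stride=30)
        assert np.all(np.abs(c.values - 1.0) < 0.01)

    def test_rigid_rod_matches_bessel_expansion(self):
        # 2-bead rod under pure rotational diffusion: coherent ISF is
        # sum over even l of 4(2l+1) j_l(QL/2)^2 exp(-l(l+1) Dr t)
        L, Dr = 40.0, 2.0e-3
        rod = rn.RigidBodyModel([[0, 0, -L / 2], [0, 0, L / 2]])
        D = rn.DiffusionTensor.isotropic(0.0, Dr=Dr)
        traj = rn.run_bd(rod, D, dt=0.5, n_steps=120_000, seed=5)
        Q = np.array([0.08, 0.2])
        lags = np.array([0.0, 20.0, 60.0, 150.0])
        # origin spacing (200) beyond the slowest retained mode keeps the
        # origin-scatter standard error honest
        c = isf_rot(traj, rod, Q, lags, origin_stride=400)

        ls = np.arange(0, 40, 2)
        for iq, q in enumerate(Q):
            jl2 = spherical_jn(ls, q * L / 2) ** 2
            w = 4 * (2 * ls + 1) * jl2
            for il, lag in enumerate(c.lag_grid):
                expect = (w * np.exp(-ls * (ls + 1) * Dr * lag)).sum() / w.sum()
                tol = max(3 * c.stderr[iq, il], 2e-3)
                assert abs(c.values[iq, il] - expect) < tol

    def test_lag_beyond_length_dropped_with_warning(self, small_mab, mab_tensor):
        traj = rn.run_bd(small_mab, mab_tensor, dt=0.25, n_steps=50, seed=6)
        with pytest.warns(UserWarning, match="dropping lags"):
            c = isf_rot(traj, small_mab, [0.1], [0.25, 1000.0], origin_stride=2)
        assert c.lag_grid.max() <= traj.times[-1]


class TestTransWeighted:
    def test_spherical_model_equals_com(self, iso_bd_traj, shell):
        traj, D = iso_bd_traj
        Q = np.array([0.02, 0.1, 0.2])
        lags = make_lag_grid(0.5, 40.0, 6)
        tw = isf_trans_weighted(traj, shell, Q, lags, origin_stride=40)
        cm = isf_com(traj, Q, lags, origin_stride=40)
        assert np.allclose(tw.values, cm.values, atol=5e-3)

    def test_smallest_q_approaches_com(self, small_mab, mab_tensor):
        traj = rn.run_bd(small_mab, mab_tensor, dt=0.25, n_steps=6000, seed=7)
        Q = np.array([0.01])
        lags = make_lag_grid(0.25, 30.0, 6)
        tw = isf_trans_weighted(traj, small_mab, Q, lags, origin_stride=20)
        cm = isf_com(traj, Q, lags, origin_stride=20)
        assert np.allclose(tw.values, cm.values, atol=1e-4)


class TestInvariants:
    def test_sphere_product_consistency_and_master_curve(self, iso_bd_traj, shell):
        # total = com x rot and all curves collapse on exp(-D0 Q^2 t)
        traj, D = iso_bd_traj
        Q = np.array([0.05, 0.1, 0.15, 0.2])
        lags = make_lag_grid(0.5, 30.0, 6)
        tot = isf_total(traj, shell, Q, lags, origin_stride=40)
        cm = isf_com(traj, Q, lags, origin_stride=40)
        rot = isf_rot(traj, shell, Q, lags, origin_stride=40)
        assert np.abs(tot.values - cm.values * rot.values).max() < 0.01
        # master curve: restrict to Q*diameter <= 10, where the 200-bead
        # shell is effectively spherically symmetric
        sel = Q * shell.diameter() <= 10.0
        reduced = 4.0 * Q[sel, None] ** 2 * tot.lag_grid[None, :]
        dev = np.abs(tot.values[sel] - np.exp(-reduced))
        assert dev.max() < 0.02 + 3 * np.nan_to_num(tot.stderr[sel]).max()

    def test_max_lag_leaves_single_origin(self, small_mab, mab_tensor):
        traj = rn.run_bd(small_mab, mab_tensor, dt=0.25, n_steps=10, seed=8)
        c = isf_total(traj, small_mab, [0.1], [0.25 * 10], origin_stride=1000)
        assert c.n_origins.max() == 1
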