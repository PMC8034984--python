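"""Model construction, form factor and bead-model hydrodynamics."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import rigidnse as rn
from rigidnse.rigid_model import DEFAULT_BEAD_RADIUS, DEFAULT_VISCOSITY


class TestCoarseGrainPDB:
    def test_single_residue_recentred_to_origin(self, pdb_one_residue):
        m = rn.coarse_grain_pdb(pdb_one_residue)
        assert m.n_beads == 1
        assert np.allclose(m.positions, 0.0, atol=1e-9)

    def test_collinear_residues_centred(self, pdb_collinear):
        m = rn.coarse_grain_pdb(pdb_collinear)
        assert m.n_beads == 3
        assert np.allclose(sorted(m.positions[:, 0]), [-1.0, 0.0, 1.0], atol=1e-6)
        assert np.allclose(m.positions[:, 1:], 0.0, atol=1e-6)

    def test_one_bead_per_residue_against_text_scan(self, pdb_mixed):
        # independent oracle: count unique (chain, resid) among amino resnames
        amino = {"ALA", "GLY", "SER", "LEU"}
        seen = set()
        for ln in pdb_mixed.splitlines():
            if ln.startswith("ATOM") and ln[17:20].strip() in amino:
                seen.add((ln[21], int(ln[22:26])))
        m = rn.coarse_grain_pdb(pdb_mixed)
        assert m.n_beads == len(seen) == 7

    def test_scattering_lengths_are_unity(self, pdb_mixed):
        m = rn.coarse_grain_pdb(pdb_mixed)
        assert np.all(m.scattering_lengths == 1.0)
        assert np.all(m.masses == m.masses[0])  # evenly distributed mass

    def test_ca_scheme_matches_centroid_for_ca_only_input(self, pdb_collinear):
        a = rn.coarse_grain_pdb(pdb_collinear, scheme="CA")
        b = rn.coarse_grain_pdb(pdb_collinear, scheme="centroid")
        assert np.allclose(np.sort(a.positions, axis=0), np.sort(b.positions, axis=0))

    def test_ligand_only_input_raises(self):
        from conftest import atom_line

        text = atom_line(1, "O", "HOH", "W", 1, 0, 0, 0, "O") + "\nEND\n"
        with pytest.raises(ValueError, match="no amino-acid residues"):
            rn.coarse_grain_pdb(text)

    def test_missing_ca_names_residue(self, pdb_one_residue):
        text = "\n".join(ln for ln in pdb_one_residue.splitlines()
                         if " CA " not in ln) + "\n"
        with pytest.raises(ValueError, match="no CA"):
            rn.coarse_grain_pdb(text, scheme="CA")

    def test_recentring_is_idempotent(self, pdb_mixed):
        m = rn.coarse_grain_pdb(pdb_mixed)
        again = rn.RigidBodyModel(m.positions.copy(), label="again")
        assert np.array_equal(m.positions, again.positions)


class TestSyntheticMab:
    def test_bead_count(self):
        m = rn.make_synthetic_mab(beads_per_lobe=100, seed=0)
        assert m.n_beads == 300

    def test_deterministic_for_fixed_seed(self):
        a = rn.make_synthetic_mab(seed=5)
        b = rn.make_synthetic_mab(seed=5)
        assert np.array_equal(a.positions, b.positions)
        c = rn.make_synthetic_mab(seed=6)
        assert not np.array_equal(a.positions, c.positions)

    def test_symmetric_y_has_degenerate_gyration_pair(self):
        # 120 deg hinge with equal lobes: threefold symmetry in the plane
        m = rn.make_synthetic_mab(hinge_angle=120.0, fc_scale=1.0,
                                  beads_per_lobe=400, seed=2)
        eig = np.sort(np.linalg.eigvalsh(m.gyration_tensor()))
        assert abs(eig[2] - eig[1]) / eig[2] < 0.05

    def test_target_diameter_rescaling(self):
        m = rn.make_synthetic_mab(seed=1, target_diameter=100.0)
        assert abs(m.diameter() - 100.0) < 1e-6

    def test_default_size_is_antibody_like(self):
        m = rn.make_synthetic_mab(seed=1)
        assert 70.0 < m.diameter() < 130.0

    @pytest.mark.parametrize("kwargs", [
        {"beads_per_lobe": 5},
        {"arm_length": -1.0},
        {"lobe_radii": (10.0, -1.0, 5.0)},
    ])
    def test_invalid_geometry_raises(self, kwargs):
        with pytest.raises(ValueError):
            rn.make_synthetic_mab(**kwargs)

    def test_com_at_origin(self, small_mab):
        assert np.linalg.norm(small_mab.center_of_mass()) < 1e-9


class TestFormFactor:
    def test_single_bead_is_flat(self):
        m = rn.RigidBodyModel(np.zeros((1, 3)))
        assert np.allclose(rn.form_factor(m, [0.0, 0.1, 1.0, 10.0]), 1.0)

    def test_two_bead_closed_form(self):
        d = 7.0
        m = rn.RigidBodyModel([[0, 0, 0], [0, 0, d]])
        Q = np.array([0.01, 0.1, 0.5, 1.3])
        expected = 0.5 * (1.0 + np.sin(Q * d) / (Q * d))
        assert np.allclose(rn.form_factor(m, Q), expected, rtol=1e-12)

    def test_normalized_at_zero(self, small_mab):
        assert rn.form_factor(small_mab, [0.0])[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-20, 20, (20, 3))
        b = rng.uniform(0.5, 2.0, 20)
        m = rn.RigidBodyModel(pos, scattering_lengths=b)
        Q = np.array([0.02, 0.1, 0.3])
        # O(N^2) reference loop
        x = m.positions
        ref = np.zeros_like(Q)
        for i, q in enumerate(Q):
            s = 0.0
            for a in range(20):
                for c in range(20):
                    r = np.linalg.norm(x[a] - x[c])
                    s += b[a] * b[c] * (1.0 if q * r < 1e-300 else np.sin(q * r) / (q * r))
            ref[i] = s / b.sum() ** 2
        assert np.allclose(rn.form_factor(m, Q), ref, rtol=1e-12)

    def test_negative_q_rejected(self, small_mab):
        with pytest.raises(ValueError):
            rn.form_factor(small_mab, [-0.1])


class TestDiffusionTensor:
    @pytest.mark.parametrize("method", ["rpy", "kirkwood"])
    def test_single_bead_stokes_einstein(self, method):
        a, eta = 4.5, DEFAULT_VISCOSITY
        m = rn.RigidBodyModel(np.zeros((1, 3)))
        D = rn.estimate_diffusion_tensor(m, bead_radius=a, viscosity=eta,
                                         method=method)
        D0 = 1.0 / (6.0 * np.pi * eta * a)
        assert np.allclose(D.tt, D0 * np.eye(3), rtol=1e-10)

    @pytest.mark.parametrize("method", ["rpy", "kirkwood"])
    def test_dimer_diffuses_faster_along_its_axis(self, method):
        m = rn.RigidBodyModel([[0, 0, -6.0], [0, 0, 6.0]])
        D = rn.estimate_diffusion_tensor(m, method=method)
        # brute-force Kirkwood sum for the dimer: mu_par - mu_perp > 0
        assert D.tt[2, 2] > D.tt[0, 0]
        assert np.isclose(D.tt[0, 0], D.tt[1, 1], rtol=1e-8)

    def test_dimer_matches_kirkwood_double_sum(self):
        # closed-form Kirkwood for 2 beads at separation r: D_par gets the
        # (I + rhat rhat) Oseen term twice, D_perp once
        r, a, eta = 12.0, 4.5, DEFAULT_VISCOSITY
        m = rn.RigidBodyModel([[0, 0, -r / 2], [0, 0, r / 2]])
        D = rn.estimate_diffusion_tensor(m, bead_radius=a, viscosity=eta,
                                         method="kirkwood")
        mu0 = 1.0 / (6 * np.pi * eta * a)
        oseen = 1.0 / (8 * np.pi * eta * r)
        assert D.tt[2, 2] == pytest.approx(mu0 / 2 + oseen, rel=1e-10)
        assert D.tt[0, 0] == pytest.approx(mu0 / 2 + oseen / 2, rel=1e-10)

    @pytest.mark.parametrize("method", ["rpy", "kirkwood"])
    def test_six_by_six_symmetric_psd(self, small_mab, method):
        D = rn.estimate_diffusion_tensor(small_mab, method=method)
        M = D.as_matrix()
        assert np.allclose(M, M.T, rtol=1e-10)
        assert np.linalg.eigvalsh(M).min() > 0

    def test_spherical_shell_is_isotropic(self, shell):
        D = rn.estimate_diffusion_tensor(shell)
        off = D.tt - np.trace(D.tt) / 3 * np.eye(3)
        assert np.abs(off).max() / D.D0 < 0.01

    def test_coincident_beads_raise(self):
        m = rn.RigidBodyModel([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="singular|coincident"):
            rn.estimate_diffusion_tensor(m)

    def test_non_psd_tensor_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            rn.DiffusionTensor(tt=-np.eye(3), rr=np.zeros((3, 3)))

    def test_json_roundtrip(self, mab_tensor):
        back = rn.DiffusionTensor.from_json(mab_tensor.to_json())
        assert np.allclose(back.as_matrix(), mab_tensor.as_matrix())


class TestModelIO:
    def test_xyz_json_roundtrip(self, small_mab, tmp_path):
        p = tmp_path / "model.xyz"
        rn.save_model(small_mab, p)
        back = rn.load_model(p)
        assert np.allclose(back.positions, small_mab.positions, atol=1e-5)
        assert np.array_equal(back.masses, small_mab.masses)
        assert back.label == small_mab.label

    def test_gyration_radius_consistent_with_extent(self, small_mab):
        # Rg of a compact body is well below but commensurate with D/2
        rg = small_mab.gyration_radius()
        assert 0.3 * small_mab.diameter() / 2 < rg < small_mab.diameter() / 2


class TestPlotting:
    def test_deff_and_isf_plots_render(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from rigidnse.plotting import plot_deff_curves, plot_isf_reduced_time
        from rigidnse.scattering import ISFCurve

        Q = np.array([0.05, 0.1])
        curves = {"com": rn.DeffCurve("com", Q, np.array([3.0, 3.1]))}
        ax = plot_deff_curves(curves, D0=3.0)
        lags = np.linspace(0, 5, 6)
        isf = ISFCurve("total", Q, lags,
                       np.exp(-3.0 * np.outer(Q**2, lags)), np.full(6, 10))
        ax2 = plot_isf_reduced_time(isf, D0=3.0)
        assert ax is not None and ax2 is not None


def test_target_rg_scaling():
    m = rn.make_synthetic_mab(seed=2, target_rg=35.0)
    assert m.gyration_radius() == pytest.approx(35.0, rel=1e-9)
    with pytest.raises(ValueError):
        rn.make_synthetic_mab(seed=2, target_rg=35.0, target_diameter=90.0)
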