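import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ribomech.enm import (
    ConnectivityError,
    ENMError,
    GeometryError,
    bfactor_agreement,
    build_hessian,
    compute_modes,
    cross_correlation,
    square_fluctuations,
)

from conftest import cg, helix_coords
from oracles import brute_hessian


class TestBuildHessian:
    def test_two_nodes_closed_form(self):
        s = cg(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        m = build_hessian(s, cutoff=15.0, gamma=1.0)
        np.testing.assert_allclose(
            m.hessian[0:3, 3:6], -np.diag([1.0, 0.0, 0.0]), atol=1e-14
        )
        lam = np.linalg.eigvalsh(m.hessian)
        np.testing.assert_allclose(sorted(lam)[:5], np.zeros(5), atol=1e-12)
        assert sorted(lam)[5] == pytest.approx(2.0)

    def test_beyond_cutoff_disconnected(self):
        s = cg(np.array([[0.0, 0, 0], [16.0, 0, 0]]))
        m = build_hessian(s, cutoff=15.0)
        assert np.count_nonzero(m.hessian) == 0

    def test_matches_bruteforce_loop(self, helix20):
        m = build_hessian(helix20, cutoff=15.0, gamma=1.0)
        np.testing.assert_allclose(
            m.hessian, brute_hessian(helix20.coords, 15.0, 1.0), atol=1e-12
        )

    def test_symmetry_row_sum_and_translation_null_space(self, state_pair):
        unbound, _, _ = state_pair
        h = build_hessian(unbound).hessian
        np.testing.assert_allclose(h, h.T, atol=1e-10)
        n = len(unbound)
        super_rows = h.reshape(n, 3, n, 3).sum(axis=2)
        np.testing.assert_allclose(super_rows, 0.0, atol=1e-10)
        t = np.tile([1.0, -2.0, 0.5], n)
        assert np.linalg.norm(h @ t) < 1e-8 * np.linalg.norm(t)

    def test_coincident_nodes_rejected(self):
        s = cg(np.array([[0.0, 0, 0], [0.0, 0, 0], [5.0, 0, 0]]))
        with pytest.raises(GeometryError):
            build_hessian(s)

    def test_sparse_dense_agreement(self, helix30):
        hd = build_hessian(helix30, sparse=False).hessian
        hs = build_hessian(helix30, sparse=True).hessian.toarray()
        np.testing.assert_allclose(hd, hs, atol=1e-12)


class TestComputeModes:
    def test_six_zero_modes_on_connected_3d_structure(self, enm_helix30):
        # eigenvalues stored are the nonzero ones: 3N − 6 of them
        assert enm_helix30.eigenvalues.size == 3 * 30 - 6
        assert enm_helix30.eigenvalues.min() > 0

    def test_variance_fraction_one_selects_all(self, helix30):
        m = compute_modes(build_hessian(helix30), variance_fraction=1.0)
        assert m.selected_modes.size == m.eigenvalues.size

    def test_selected_prefix_is_minimal(self, state_pair):
        unbound, _, _ = state_pair
        m = compute_modes(build_hessian(unbound), variance_fraction=0.8)
        inv = 1.0 / m.eigenvalues
        share = np.cumsum(inv) / inv.sum()
        k = m.selected_modes.size
        assert share[k - 1] >= 0.8
        assert k == 1 or share[k - 2] < 0.8

    def test_sparse_partial_solver_matches_dense_fluctuations(self, state_pair):
        """The shift-invert partial eigensolver used for large models selects
        the same modes and reproduces dense fluctuations within 1e-6."""
        unbound, _, _ = state_pair
        md = compute_modes(build_hessian(unbound, sparse=False))
        ms = compute_modes(build_hessian(unbound, sparse=True))
        assert md.selected_modes.size == ms.selected_modes.size
        fd = square_fluctuations(md).msf
        fs = square_fluctuations(ms).msf
        np.testing.assert_allclose(fs, fd, rtol=1e-6)

    def test_disconnected_graph_reports_components(self):
        coords = np.vstack([helix_coords(10), helix_coords(10) + 100.0])
        s = cg(coords)
        with pytest.raises(ConnectivityError, match="components"):
            compute_modes(build_hessian(s))


class TestFluctuations:
    def test_symmetric_three_node_chain(self):
        s = cg(np.array([[-5.0, 0, 0], [0.0, 0.5, 0], [5.0, 0, 0]]))
        m = compute_modes(build_hessian(s), variance_fraction=1.0)
        prof = square_fluctuations(m)
        assert prof.msf[0] == pytest.approx(prof.msf[2], rel=1e-8)

    def test_zscore_standardised_and_threshold_rule(self, enm_helix30):
        prof = square_fluctuations(enm_helix30)
        assert prof.zscore.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.zscore.std() == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_array_equal(
            prof.flexible, np.flatnonzero(np.abs(prof.zscore) > 2.0)
        )

    def test_msf_equals_pseudoinverse_block_traces(self):
        rng = np.random.default_rng(4)
        s = cg(rng.uniform(-12, 12, size=(25, 3)))
        m = compute_modes(build_hessian(s), variance_fraction=0.8)
        prof = square_fluctuations(m)
        hinv = m.pseudo_inverse()  # truncated to selected modes
        traces = np.array([np.trace(hinv[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                           for i in range(25)])
        np.testing.assert_allclose(prof.msf, traces, atol=1e-10)

    def test_msf_invariant_under_rigid_rotation(self, helix30):
        m1 = compute_modes(build_hessian(helix30))
        r = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        s2 = helix30.with_coords(helix30.coords @ r.T + np.array([3.0, -8, 2]))
        m2 = compute_modes(build_hessian(s2))
        np.testing.assert_allclose(
            square_fluctuations(m1).msf, square_fluctuations(m2).msf, rtol=1e-6
        )


class TestCrossValidation:
    def test_fluctuations_match_bio3d_reference(self, tmp_path):
        """Square fluctuations agree with an independent ANM implementation
        (bio3d's nma with the anm force field) up to a global scale."""
        import shutil
        import subprocess

        from ribomech.structures import write_structure
        from ribomech.synthetic import _globule

        rng = np.random.default_rng(3)
        s = cg(_globule(40, rng), name="xval")
        pdb = tmp_path / "xval.pdb"
        pdb.write_text(write_structure(s))
        m = compute_modes(build_hessian(s, cutoff=15.0), variance_fraction=1.0)
        msf = square_fluctuations(m).msf
        script = tmp_path / "nma.R"
        out = tmp_path / "fluct.txt"
        script.write_text(
            "suppressMessages(library(bio3d))\n"
            f'pdb <- read.pdb("{pdb}")\n'
            'modes <- nma(pdb, ff="anm", cutoff=15.0, mass=FALSE)\n'
            f'write.table(modes$fluctuations, "{out}", '
            "row.names=FALSE, col.names=FALSE)\n"
        )
        res = subprocess.run([shutil.which("Rscript") or "Rscript", str(script)],
                             capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = np.loadtxt(out)
        assert np.corrcoef(msf, ref)[0, 1] > 0.999
        ratio = msf / ref
        assert np.std(ratio) / np.mean(ratio) < 1e-3  # pure global scale

    def test_fine_grained_model_gives_same_residue_profile(self):
        """A finer-grained model (three sites per residue) reproduces the
        one-site-per-residue flexibility profile after per-residue averaging."""
        from ribomech.synthetic import _globule

        rng = np.random.default_rng(11)
        coarse_coords = _globule(30, rng)
        s_coarse = cg(coarse_coords)
        m_coarse = compute_modes(build_hessian(s_coarse, cutoff=15.0),
                                 variance_fraction=1.0)
        msf_coarse = square_fluctuations(m_coarse).msf
        # satellites 1 Å around each site emulate side-chain atoms
        fine = []
        for x in coarse_coords:
            offsets = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
            fine.append(x + offsets)
        s_fine = cg(np.vstack(fine))
        m_fine = compute_modes(build_hessian(s_fine, cutoff=15.0),
                               variance_fraction=1.0)
        msf_fine = square_fluctuations(m_fine).msf.reshape(30, 3).mean(axis=1)
        r = np.corrcoef(msf_coarse, msf_fine)[0, 1]
        assert r > 0.8


class TestCrossCorrelation:
    def test_diagonal_symmetry_and_range(self, enm_helix30):
        c = cross_correlation(enm_helix30)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
        np.testing.assert_allclose(c, c.T, atol=1e-10)
        assert c.min() >= -1.0 - 1e-10 and c.max() <= 1.0 + 1e-10

    def test_two_node_single_mode_antiphase(self):
        s = cg(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        m = compute_modes(build_hessian(s), variance_fraction=1.0)
        c = cross_correlation(m)
        assert c[0, 1] == pytest.approx(-1.0)


class TestBfactorAgreement:
    def test_identity_and_anti_identity(self, enm_helix30, helix30):
        prof = square_fluctuations(enm_helix30)
        s_pos = cg(helix30.coords, bfactors=prof.msf)
        assert bfactor_agreement(prof, s_pos) == pytest.approx(1.0)
        s_neg = cg(helix30.coords, bfactors=-prof.msf)
        assert bfactor_agreement(prof, s_neg) == pytest.approx(-1.0)

    def test_planted_linear_relation(self, state_pair):
        unbound, _, _ = state_pair
        m = compute_modes(build_hessian(unbound))
        prof = square_fluctuations(m)
        rng = np.random.default_rng(9)
        b = 5.0 * prof.msf + rng.normal(0, 0.02 * prof.msf.std(), prof.msf.size)
        s = unbound.with_coords(unbound.coords)
        s = cg(unbound.coords, bfactors=b)
        assert bfactor_agreement(prof, s) > 0.9

    def test_constant_vector_rejected(self, enm_helix30, helix30):
        prof = square_fluctuations(enm_helix30)
        s = cg(helix30.coords, bfactors=np.full(30, 7.0))
        with pytest.raises(ENMError):
            bfactor_agreement(prof, s)
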