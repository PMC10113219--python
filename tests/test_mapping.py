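"""Connectopic-mapping stages: shapes, oracles, and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.linalg import eigh
from scipy.stats import spearmanr

import conngrad as cg
from conngrad.mapping import ConnectivityMode, _rescale01


def _eta_squared_naive(C):
    """Literal per-pair evaluation of the eta-squared formula (test oracle)."""
    n = len(C)
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            a, b = C[i], C[j]
            m = (a + b) / 2.0
            M = m.mean()
            within = np.sum((a - m) ** 2 + (b - m) ** 2)
            total = np.sum((a - M) ** 2 + (b - M) ** 2)
            S[i, j] = 1.0 if total == 0 else 1.0 - within / total
    return S


class TestExtractTimeseries:
    def test_shapes_follow_mask_sizes(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((4, 4, 4, 5))
        roi = np.zeros((4, 4, 4), bool)
        roi[0, 0, :3] = True
        brain = np.zeros((4, 4, 4), bool)
        brain[3, 3, :] = True
        ds = cg.extract_timeseries(img, roi, brain)
        assert ds.A.shape == (5, 3)
        assert ds.B.shape == (5, 4)
        assert ds.roi_coords.shape == (3, 3)

    def test_mask_shape_mismatch_is_an_error(self):
        img = np.zeros((4, 4, 4, 5))
        with pytest.raises(ValueError, match="bounds"):
            cg.extract_timeseries(img, np.ones((5, 4, 4)), np.ones((4, 4, 4)))

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((4, 4, 4, 6))
        roi = np.zeros((4, 4, 4), bool)
        roi[1, 1, :3] = True
        img[1, 1, 2, :] = 7.0  # constant ROI voxel
        brain = np.zeros((4, 4, 4), bool)
        brain[3, :, 0] = True
        with pytest.warns(UserWarning, match="constant"):
            ds = cg.extract_timeseries(img, roi, brain)
        assert ds.A.shape[1] == 2

    def test_affine_maps_voxels_to_millimeters(self):
        img = np.random.default_rng(2).standard_normal((3, 3, 3, 4))
        roi = np.zeros((3, 3, 3), bool)
        roi[1, 2, 0] = True
        roi[0, 0, 0] = True
        brain = ~roi
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = [-1.0, 0.0, 5.0]
        ds = cg.extract_timeseries(img, roi, brain, affine=aff)
        np.testing.assert_allclose(ds.roi_coords[0], [-1.0, 0.0, 5.0])
        np.testing.assert_allclose(ds.roi_coords[1], [1.0, 4.0, 5.0])


class TestSvdReduce:
    def test_rank_bound_and_orthogonality(self):
        rng = np.random.default_rng(3)
        B = rng.standard_normal((50, 500))
        red = cg.svd_reduce(B)
        assert red.n_components <= 50
        gram = red.timeseries.T @ red.timeseries
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_lossless_reconstruction(self):
        rng = np.random.default_rng(4)
        B = rng.standard_normal((20, 7)) @ rng.standard_normal((7, 60))
        red = cg.svd_reduce(B)
        Bc = B - B.mean(axis=0)
        np.testing.assert_allclose(
            red.timeseries @ red.right_basis, Bc, atol=1e-8
        )

    def test_rank_zero_is_an_error(self):
        with pytest.raises(ValueError, match="rank 0"):
            cg.svd_reduce(np.ones((10, 4)))


class TestFingerprints:
    def test_exact_match_and_negation(self):
        rng = np.random.default_rng(5)
        comp = rng.standard_normal((30, 3))
        A = np.column_stack([comp[:, 1], -comp[:, 2], rng.standard_normal(30)])
        C = cg.compute_fingerprints(A, comp)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[1, 2] == pytest.approx(-1.0)
        assert np.all(np.abs(C) <= 1.0)

    def test_identical_voxels_get_identical_rows(self):
        rng = np.random.default_rng(6)
        comp = rng.standard_normal((30, 4))
        v = rng.standard_normal(30)
        C = cg.compute_fingerprints(np.column_stack([v, v]), comp)
        np.testing.assert_allclose(C[0], C[1])

    def test_constant_column_is_an_error(self):
        comp = np.random.default_rng(7).standard_normal((10, 2))
        with pytest.raises(ValueError, match="constant"):
            cg.compute_fingerprints(np.ones((10, 1)), comp)


class TestEtaSquared:
    def test_hand_computed_examples(self):
        S = cg.eta_squared_matrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert S[0, 1] == pytest.approx(0.2, abs=1e-12)
        S = cg.eta_squared_matrix(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert S[0, 1] == pytest.approx(0.0, abs=1e-12)
        S = cg.eta_squared_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert S[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_oracle(self):
        C = np.random.default_rng(8).uniform(-1, 1, size=(12, 9))
        np.testing.assert_allclose(
            cg.eta_squared_matrix(C), _eta_squared_naive(C), atol=1e-12
        )

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 8), st.integers(2, 6)),
            elements=st.floats(-1, 1, width=32),
        )
    )
    def test_invariants_on_arbitrary_fingerprints(self, C):
        S = cg.eta_squared_matrix(C)
        assert np.all(S >= 0.0) and np.all(S <= 1.0)
        np.testing.assert_allclose(S, S.T)
        np.testing.assert_allclose(np.diag(S), 1.0)


class TestLaplacianEigenmaps:
    def test_path_graph_first_mode_is_monotone(self):
        n = 5
        S = np.eye(n)
        for i in range(n - 1):
            S[i, i + 1] = S[i + 1, i] = 1.0
        modes = cg.laplacian_eigenmaps(S, n_modes=2)
        diffs = np.diff(modes[0].values)
        assert np.all(diffs > 0) or np.all(diffs < 0)
        assert modes[0].eigenvalue < modes[1].eigenvalue

    def test_matches_dense_generalized_eigendecomposition(self):
        """Oracle: eigh(L, D) on the same graph, independent formulation."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = rng.integers(10, 50)
            X = rng.standard_normal((n, 4))
            S = cg.eta_squared_matrix(X)
            modes = cg.laplacian_eigenmaps(S, n_modes=2)

            W = S - S.min()
            np.fill_diagonal(W, 0.0)
            D = np.diag(W.sum(axis=1))
            L = D - W
            vals, vecs = eigh(L, D)
            order = np.argsort(vals)
            for k, mode in enumerate(modes, start=1):
                v = vecs[:, order[k]]
                r = np.corrcoef(mode.raw, v)[0, 1]
                assert abs(r) > 0.999
                assert mode.eigenvalue == pytest.approx(vals[order[k]], abs=1e-8)

    def test_modes_are_d_orthogonal_to_constant(self):
        rng = np.random.default_rng(10)
        S = cg.eta_squared_matrix(rng.standard_normal((30, 5)))
        modes = cg.laplacian_eigenmaps(S, n_modes=3)
        W = S - S.min()
        np.fill_diagonal(W, 0.0)
        d = W.sum(axis=1)
        for m in modes:
            raw = m.raw / np.linalg.norm(m.raw)
            assert abs(np.sum(d * raw)) / d.sum() ** 0.5 < 1e-6
            assert m.eigenvalue > 0
            assert m.values.min() == 0.0 and m.values.max() == 1.0

    def test_disconnected_graph_is_an_error(self):
        S = np.zeros((6, 6))
        S[:3, :3] = 0.9
        S[3:, 3:] = 0.9
        np.fill_diagonal(S, 1.0)
        with pytest.raises(ValueError, match="not connected"):
            cg.laplacian_eigenmaps(S, n_modes=1)

    def test_too_many_modes_is_an_error(self):
        S = cg.eta_squared_matrix(np.random.default_rng(11).standard_normal((5, 3)))
        with pytest.raises(ValueError, match="n_modes"):
            cg.laplacian_eigenmaps(S, n_modes=5)

    def test_knn_sparsification_stays_connected(self):
        rng = np.random.default_rng(12)
        S = cg.eta_squared_matrix(rng.standard_normal((25, 4)))
        dense = cg.laplacian_eigenmaps(S, n_modes=1)[0]
        sparse = cg.laplacian_eigenmaps(S, n_modes=1, n_neighbors=10)[0]
        assert abs(np.corrcoef(dense.values, sparse.values)[0, 1]) > 0.8


class TestAlignmentAndQC:
    def _mode(self, values):
        return ConnectivityMode(
            values=_rescale01(values), raw=values, mode_index=1, eigenvalue=0.1
        )

    def test_negative_correlation_flips_polarity(self):
        rng = np.random.default_rng(13)
        ref = rng.standard_normal(40)
        noisy = -(ref + 0.5 * rng.standard_normal(40))
        mode = self._mode(noisy)
        aligned = cg.align_sign(mode, ref)
        assert aligned.qc_spatial_r > 0
        assert np.corrcoef(aligned.raw, ref)[0, 1] > 0

    def test_positive_correlation_left_unchanged(self):
        rng = np.random.default_rng(14)
        ref = rng.standard_normal(40)
        mode = self._mode(ref + rng.standard_normal(40))
        aligned = cg.align_sign(mode, ref)
        np.testing.assert_array_equal(aligned.values, mode.values)
        assert aligned.sign_aligned

    def test_zero_correlation_warns_and_keeps(self):
        mode = self._mode(np.array([1.0, -1.0, 1.0, -1.0]))
        ref = np.array([1.0, 1.0, -1.0, -1.0])
        with pytest.warns(UserWarning, match="uncorrelated"):
            aligned = cg.align_sign(mode, ref)
        np.testing.assert_array_equal(aligned.values, mode.values)

    def test_zero_variance_reference_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            cg.align_sign(self._mode(np.arange(4.0)), np.ones(4))

    def test_group_reference_of_identical_maps(self):
        m = _rescale01(np.random.default_rng(15).standard_normal(30))
        ref = cg.group_reference([m, m, m])
        np.testing.assert_allclose(ref, m, atol=1e-12)

    def test_group_reference_resolves_polarity(self):
        m = _rescale01(np.random.default_rng(16).standard_normal(30))
        ref = cg.group_reference([m, 1.0 - m])
        np.testing.assert_allclose(ref, m, atol=1e-12)

    @pytest.mark.parametrize(
        "r,keep", [(0.49, False), (0.50, True), (0.90, True)]
    )
    def test_spatial_corr_threshold_is_strict(self, r, keep):
        mode = ConnectivityMode(
            values=np.zeros(3), raw=np.zeros(3), mode_index=1,
            eigenvalue=0.1, sign_aligned=True, qc_spatial_r=r,
        )
        assert cg.qc_spatial_corr(mode) is keep


class TestCombineSubregions:
    def test_concatenation_preserves_order(self):
        rng = np.random.default_rng(17)
        va, vb = rng.random(120), rng.random(80)
        ca = np.c_[np.arange(120), np.zeros(120), np.zeros(120)]
        cb = np.c_[np.arange(80), np.ones(80), np.zeros(80)]
        combined = cg.combine_subregions(va, ca, vb, cb)
        assert len(combined.values) == 200
        np.testing.assert_array_equal(combined.values[:120], va)
        np.testing.assert_array_equal(combined.coords[120:], cb)
        assert list(np.unique(combined.subregion)) == ["A", "B"]

    def test_overlap_is_an_error(self):
        v = np.random.default_rng(18).random(10)
        c = np.c_[np.arange(10), np.zeros(10), np.zeros(10)]
        with pytest.raises(ValueError, match="overlap"):
            cg.combine_subregions(v, c, v, c)


class TestRecoveryAndDeterminism:
    def test_noise_free_mode_recovers_planted_gradient(self, noise_free_cohort):
        from conngrad.pipeline import map_subject

        co = noise_free_cohort
        for i in range(co.n_subjects):
            modes, _ = map_subject(
                co.images[i], co.roi_mask, co.brain_mask, co.affine
            )
            rho = spearmanr(modes[0].values, co.planted_gradients[i]).statistic
            assert abs(rho) >= 0.95

    def test_identical_image_gives_bit_identical_modes(self, small_cohort):
        from conngrad.pipeline import map_subject

        co = small_cohort
        a, _ = map_subject(co.images[0], co.roi_mask, co.brain_mask, co.affine)
        b, _ = map_subject(co.images[0], co.roi_mask, co.brain_mask, co.affine)
        np.testing.assert_array_equal(a[0].values, b[0].values)

    def test_group_reference_recovers_planted_gradient(self, noise_free_cohort):
        from conngrad.pipeline import map_subject

        co = noise_free_cohort
        maps = [
            map_subject(img, co.roi_mask, co.brain_mask, co.affine)[0][0].values
            for img in co.images
        ]
        ref = cg.group_reference(maps)
        r = np.corrcoef(ref, co.planted_gradients[0])[0, 1]
        assert abs(r) >= 0.95
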