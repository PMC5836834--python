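import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circaphase import (
    QuantileNormalizer,
    compute_reference,
    normalize_matrix,
    quantile_normalize,
    smooth_reference,
    zscore_profiles,
)
from conftest import zscore_rows


class TestComputeReference:
    def test_mean_of_order_statistics(self):
        m = np.array([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]])
        np.testing.assert_array_equal(compute_reference(m), [2.0, 3.0, 4.0])

    def test_identical_samples_are_a_fixed_point(self, rng):
        col = rng.normal(size=50)
        m = np.tile(col[:, None], (1, 6))
        np.testing.assert_allclose(compute_reference(m), np.sort(col))

    def test_single_sample(self, rng):
        col = rng.normal(size=20)
        np.testing.assert_array_equal(compute_reference(col[:, None]), np.sort(col))


class TestSmoothReference:
    def test_linear_input_unchanged(self):
        ref = np.linspace(0.0, 10.0, 40)
        np.testing.assert_allclose(smooth_reference(ref), ref, atol=1e-10)

    def test_spike_amplitude_reduced(self):
        # spike small enough to keep the reference sorted (grid spacing 0.25)
        ref = np.linspace(0.0, 10.0, 41)
        trend = ref.copy()
        ref[20] += 0.2
        smoothed = smooth_reference(ref)
        assert np.max(np.abs(smoothed - trend)) < np.max(np.abs(ref - trend))

    def test_short_input_falls_back_to_identity(self, caplog):
        ref = np.arange(6.0)
        with caplog.at_level(logging.WARNING):
            out = smooth_reference(ref, window=7)
        np.testing.assert_array_equal(out, ref)
        assert any("unsmoothed" in r.message for r in caplog.records)

    def test_output_always_non_decreasing(self, rng):
        ref = np.sort(rng.normal(size=100) ** 3)
        out = smooth_reference(ref)
        assert np.all(np.diff(out) >= 0)


class TestQuantileNormalize:
    def test_rank_substitution(self):
        sample = np.array([[5.0], [1.0], [3.0]])
        ref = np.array([10.0, 20.0, 30.0])
        np.testing.assert_array_equal(quantile_normalize(sample, ref).ravel(), [30.0, 10.0, 20.0])

    def test_permuted_samples_share_a_multiset(self, rng):
        col = rng.normal(size=30)
        m = np.column_stack([col, rng.permutation(col)])
        out = quantile_normalize(m, compute_reference(m))
        np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(out[:, 1]))

    def test_fixed_point_when_columns_equal_reference(self, rng):
        ref = np.sort(rng.normal(size=25))
        m = np.tile(ref[:, None], (1, 4))
        np.testing.assert_allclose(quantile_normalize(m, ref), m)

    def test_kolmogorov_distance_zero_across_samples(self, rng):
        m = rng.lognormal(size=(200, 6))
        out = quantile_normalize(m, compute_reference(m))
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 6):
            np.testing.assert_array_equal(sorted_cols[:, 0], sorted_cols[:, j])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_monotone_transforms(self, seed):
        """The map depends on per-sample ranks only."""
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(30, 3))
        ref = np.sort(rng.normal(size=30))
        transformed = m.copy()
        transformed[:, 0] = np.exp(m[:, 0])
        transformed[:, 1] = m[:, 1] ** 3
        transformed[:, 2] = 2 * m[:, 2] + 1
        np.testing.assert_allclose(
            quantile_normalize(m, ref), quantile_normalize(transformed, ref)
        )

    def test_ties_get_averaged_reference_values(self):
        sample = np.array([[2.0], [2.0], [1.0]])
        ref = np.array([10.0, 20.0, 30.0])
        out = quantile_normalize(sample, ref).ravel()
        np.testing.assert_array_equal(out, [25.0, 25.0, 10.0])


class TestZScore:
    def test_three_point_row(self):
        z, keep = zscore_profiles(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z, [[-1.0, 0.0, 1.0]])
        assert keep.all()

    def test_postcondition_mean_zero_sd_one(self, rng):
        z, _ = zscore_profiles(rng.normal(size=(40, 12)))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_excluded_and_logged(self, caplog):
        m = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with caplog.at_level(logging.INFO):
            z, keep = zscore_profiles(m)
        assert keep.tolist() == [True, False]
        assert z.shape == (1, 3)
        assert any("constant" in r.message for r in caplog.records)


class TestNormalizationPipeline:
    def test_estimator_roundtrip_and_params(self, rng):
        qn = QuantileNormalizer(smooth=True, window=7, polyorder=2)
        assert qn.get_params()["window"] == 7
        X = rng.normal(size=(100, 12))
        out = qn.fit_transform(X)
        for j in range(12):
            np.testing.assert_array_equal(np.sort(out[:, j]), qn.reference_)

    def test_transform_requires_fitted_row_count(self, rng):
        qn = QuantileNormalizer().fit(rng.normal(size=(50, 4)))
        with pytest.raises(ValueError, match="rows"):
            qn.transform(rng.normal(size=(49, 4)))

    def test_quantile_stage_is_idempotent(self, rng):
        """Re-normalizing an already quantile-normalized matrix is the identity.

        All columns of the output share the reference distribution, so a
        second pass (reference recomputed, no re-smoothing) maps every value
        to itself.  A second z-score pass is likewise the identity.  The two
        stages do not commute, so the pipeline as a whole is only idempotent
        stage by stage.
        """
        X = rng.lognormal(size=(80, 12))
        once = QuantileNormalizer(smooth=True).fit_transform(X)
        twice = QuantileNormalizer(smooth=False).fit_transform(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)
        z, _ = zscore_profiles(once)
        z2, _ = zscore_profiles(z)
        np.testing.assert_allclose(z2, z, atol=1e-12)

    def test_rows_are_zscored_profiles(self, small_matrix):
        matrix, _ = small_matrix
        out, keep = normalize_matrix(matrix)
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0, atol=1e-12)
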