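import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circaphase import (
    CosinePhaseClassifier,
    PhaseAssignment,
    TimeDesign,
    assign_phase,
    assign_phases,
    build_templates,
    phase_confidence,
    select_confident,
)
from conftest import zscore_rows


class TestTemplateBank:
    @pytest.mark.parametrize("interval, expected", [(4.0, 6), (3.0, 8)])
    def test_phase_counts(self, interval, expected):
        bank = build_templates(TimeDesign(24.0, interval, 2))
        assert bank.n_phases == expected
        assert bank.templates.shape == (expected, bank.design.n_samples)

    def test_template_peaks_at_own_phase_time(self, design4):
        bank = build_templates(design4)
        t = design4.sample_times
        for p in range(bank.n_phases):
            peak_cols = np.isclose(np.mod(t, 24.0), p * 4.0)
            np.testing.assert_allclose(bank.templates[p, peak_cols], 1.0)

    def test_templates_zero_mean_over_full_cycles(self, design3):
        bank = build_templates(design3)
        np.testing.assert_allclose(bank.templates.mean(axis=1), 0.0, atol=1e-12)

    def test_cross_template_correlation_closed_form(self, design4):
        """corr(template_p, template_q) = cos(2*pi*(p-q)/n_phases)."""
        bank = build_templates(design4)
        T = zscore_rows(bank.templates)
        corr = T @ T.T / (design4.n_samples - 1)
        for p in range(6):
            for q in range(6):
                expected = np.cos(2 * np.pi * (p - q) / 6)
                assert corr[p, q] == pytest.approx(expected, abs=1e-12)

    def test_confidence_interval_geometry(self):
        bank3 = build_templates(TimeDesign(24.0, 3.0, 2))
        assert bank3.confidence_interval(0) == (21.0, 3.0)
        assert bank3.confidence_interval(1) == (0.0, 6.0)
        bank4 = build_templates(TimeDesign(24.0, 4.0, 2))
        lo, hi = bank4.confidence_interval(2)
        assert (hi - lo) % 24.0 == pytest.approx(8.0)


class TestAssignPhase:
    def test_template_assigned_to_itself_with_unit_correlation(self, design4):
        bank = build_templates(design4)
        for p in range(6):
            idx, corr = assign_phase(bank.templates[p], bank)
            assert idx == p
            assert corr == pytest.approx(1.0)

    def test_negated_template_lands_in_antiphase(self, design4):
        bank = build_templates(design4)
        idx, corr = assign_phase(-bank.templates[0], bank)
        assert idx == 3
        assert corr == pytest.approx(1.0)

    def test_off_grid_peak_matches_brute_force(self, design4):
        """A ZT2 peak on a 4-h grid goes to whichever of ZT0/ZT4 wins brute force."""
        prof = np.cos(2 * np.pi * (design4.sample_times - 2.0) / 24.0)
        bank = build_templates(design4)
        brute = np.array([np.corrcoef(prof, tmpl)[0, 1] for tmpl in bank.templates])
        # ZT2 ties ZT0 and ZT4 exactly; ties break toward the smaller index
        brute_idx = int(np.argmax(brute >= brute.max() - 1e-9))
        idx, corr = assign_phase(prof, bank)
        assert idx == brute_idx == 0
        assert corr == pytest.approx(brute.max())

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_and_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        design = TimeDesign(24.0, 4.0, 2)
        bank = build_templates(design)
        x = rng.normal(size=12)
        a = rng.uniform(0.1, 10.0)
        b = rng.normal()
        i1, c1 = assign_phase(x, bank)
        i2, c2 = assign_phase(a * x + b, bank)
        assert i1 == i2
        assert c1 == pytest.approx(c2)

    def test_antiphase_symmetry_of_negation(self, design4, rng):
        bank = build_templates(design4)
        X = rng.normal(size=(50, 12))
        idx, _ = assign_phases(X, bank)
        neg_idx, _ = assign_phases(-X, bank)
        np.testing.assert_array_equal(neg_idx, (idx + 3) % 6)

    def test_zero_variance_profile_rejected(self, design4):
        bank = build_templates(design4)
        with pytest.raises(ValueError, match="zero-variance"):
            assign_phase(np.full(12, 1.0), bank)


class TestPhaseConfidence:
    def test_noise_free_cosine_is_maximally_stable(self, design4):
        bank = build_templates(design4)
        prof = 4.0 * bank.templates[2]
        p = phase_confidence(prof, bank, n_replicates=199, rng=0)
        assert p == pytest.approx(1 / 200)

    def test_formula_floor(self, design4):
        bank = build_templates(design4)
        p = phase_confidence(bank.templates[0], bank, n_replicates=99, rng=1)
        assert p == pytest.approx(1 / 100)

    def test_window_criterion_tolerates_adjacent_phase(self, design4, rng):
        """Strict criterion counts adjacent-phase replicates outside, window does not."""
        bank = build_templates(design4)
        for _ in range(10):
            prof = rng.normal(size=12)
            pw = phase_confidence(prof, bank, 99, rng=7, criterion="window")
            ps = phase_confidence(prof, bank, 99, rng=7, criterion="strict")
            assert pw <= ps

    def test_deterministic_given_rng_seed(self, design4, rng):
        bank = build_templates(design4)
        prof = rng.normal(size=12)
        assert phase_confidence(prof, bank, 99, rng=5) == phase_confidence(prof, bank, 99, rng=5)


class TestSelectConfident:
    def make(self, gene, phase, p):
        return PhaseAssignment(gene, phase, phase * 4.0, correlation=0.9, confidence_p=p)

    def test_alpha_one_partitions_everything(self):
        recs = [self.make(f"g{i}", i % 3, 0.5) for i in range(9)]
        groups = select_confident(recs, 1.0)
        assert set().union(*groups.values()) == {f"g{i}" for i in range(9)}

    def test_alpha_zero_empties_all_groups(self):
        recs = [self.make(f"g{i}", i % 3, 0.01) for i in range(9)]
        groups = select_confident(recs, 0.0)
        assert all(len(g) == 0 for g in groups.values())

    def test_threshold_monotonicity(self):
        recs = [self.make(f"g{i}", 0, p) for i, p in enumerate([0.01, 0.07, 0.2])]
        g05 = select_confident(recs, 0.05)
        g10 = select_confident(recs, 0.10)
        assert g05[0] <= g10[0]


class TestCosinePhaseClassifier:
    def test_fit_attributes_and_predict_agree(self, design4, rng):
        X = zscore_rows(rng.normal(size=(20, 12)))
        clf = CosinePhaseClassifier(design=design4, n_boot=99, random_state=0).fit(X)
        np.testing.assert_array_equal(clf.predict(X), clf.labels_)
        assert clf.confidence_p_.shape == (20,)
        np.testing.assert_array_equal(clf.peak_time_h_, clf.labels_ * 4.0)
        assert np.all((clf.correlation_ >= -1) & (clf.correlation_ <= 1))

    def test_sklearn_params_round_trip(self, design4):
        from sklearn.base import clone

        clf = CosinePhaseClassifier(design=design4, n_boot=199, alpha=0.1)
        cloned = clone(clf)
        assert cloned.get_params()["n_boot"] == 199
        assert cloned.get_params()["alpha"] == 0.1

    def test_fit_deterministic_under_random_state(self, design4, rng):
        X = rng.normal(size=(10, 12))
        a = CosinePhaseClassifier(design=design4, n_boot=99, random_state=11).fit(X)
        b = CosinePhaseClassifier(design=design4, n_boot=99, random_state=11).fit(X)
        np.testing.assert_array_equal(a.confidence_p_, b.confidence_p_)
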