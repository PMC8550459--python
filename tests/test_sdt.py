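"""Signal-detection scoring: decision rule, hit/FA semantics, extreme-rate
correction, d'/criterion against an inverse-normal oracle, sweep statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from goalattn.sdt import (
    ConfusionCounts,
    criterion_location,
    decide,
    dprime,
    metrics_from_counts,
    rates,
    score_blended,
    score_standard,
    sweep_statistics,
)


class TestDecide:
    @pytest.mark.parametrize(
        "probs, k, expected",
        [
            ([0.1, 0.7, 0.2], 1, {1}),
            ([0.4, 0.4, 0.2], 1, {0}),     # tie broken toward lowest index
            ([0.5, 0.3, 0.2], 2, {0, 1}),
        ],
    )
    def test_top_k_selection(self, probs, k, expected):
        assert decide(np.array(probs), k) == expected

    def test_k_equal_n_returns_all_classes(self):
        assert decide(np.array([0.2, 0.3, 0.5]), 3) == {0, 1, 2}

    def test_k_beyond_n_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            decide(np.array([0.5, 0.5]), 3)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            decide(np.array([0.5, 0.2]), 1)


class TestScoring:
    def test_perfect_detector(self):
        c = score_standard([0] * 10 + [1] * 10, [0] * 10 + [1] * 10, {0})
        assert (c.hits, c.misses, c.false_alarms, c.correct_rejections) == (10, 0, 0, 10)

    def test_always_yes_detector(self):
        c = score_standard([0] * 20, [0] * 10 + [1] * 10, {0})
        assert (c.hits, c.misses, c.false_alarms, c.correct_rejections) == (10, 0, 10, 0)

    def test_three_trial_enumeration(self):
        c = score_standard([0, 1, 2], [0, 1, 2], {0})
        assert (c.hits, c.misses, c.false_alarms, c.correct_rejections) == (1, 0, 0, 2)

    def test_topk_set_predictions_count_target_membership(self):
        preds = [{0, 3}, {1, 2}, {1, 3}]
        c = score_standard(preds, [0, 0, 2], {0})
        assert (c.hits, c.misses) == (1, 1)
        assert (c.false_alarms, c.correct_rejections) == (0, 1)

    def test_count_conservation(self, rng):
        labels = rng.integers(0, 4, 50)
        preds = rng.integers(0, 4, 50)
        c = score_standard(preds, labels, {1})
        assert c.n_present == int(np.sum(labels == 1))
        assert c.n_absent == 50 - c.n_present

    def test_blended_hit_miss_fa_semantics(self):
        pairs = [(0, 1), (0, 2), (1, 2), (3, 2)]
        preds = [0, 1, 0, 2]
        # trials 1-2 are target-present (target 0): hit then miss;
        # trials 3-4 are target-absent: false alarm then correct rejection.
        c = score_blended(preds, pairs, {0})
        assert (c.hits, c.misses, c.false_alarms, c.correct_rejections) == (1, 1, 1, 1)

    def test_blended_identical_labels_rejected(self):
        with pytest.raises(ValueError, match="identical labels"):
            score_blended([0], [(1, 1)], {0})


class TestRates:
    def test_extreme_rates_get_half_count_correction(self):
        H, F = rates(ConfusionCounts(10, 0, 0, 10))
        assert H == pytest.approx(0.95)
        assert F == pytest.approx(0.05)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(5, 5, 5, 5), (0.5, 0.5)),
            (ConfusionCounts(8, 2, 3, 7), (0.8, 0.3)),
        ],
    )
    def test_interior_rates_unchanged(self, counts, expected):
        assert rates(counts) == pytest.approx(expected)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            rates(ConfusionCounts(0, 0, 3, 7))


class TestDprimeAndCriterion:
    def test_no_sensitivity_at_equal_rates(self):
        assert dprime(0.5, 0.5) == 0.0
        assert criterion_location(0.5, 0.5) == 0.0

    def test_symmetric_rates_against_inverse_normal_oracle(self):
        expected = stats.norm.ppf(0.84) - stats.norm.ppf(0.16)
        assert dprime(0.84, 0.16) == pytest.approx(expected, abs=1e-10)
        assert dprime(0.84, 0.16) == pytest.approx(1.98892, abs=1e-4)
        assert criterion_location(0.84, 0.16) == pytest.approx(0.0, abs=1e-10)

    def test_criterion_oracle_value(self):
        assert criterion_location(0.9, 0.5) == pytest.approx(-0.6408, abs=1e-4)

    @given(
        st.floats(0.01, 0.99),
        st.floats(0.01, 0.99),
    )
    @settings(deadline=None, max_examples=100)
    def test_antisymmetry(self, h, f):
        assert dprime(h, f) == pytest.approx(-dprime(f, h), abs=1e-10)

    def test_monotonicity_over_grid(self):
        grid = np.linspace(0.05, 0.95, 10)
        for f in (0.2, 0.5, 0.8):
            d = [dprime(h, f) for h in grid]
            assert all(a < b for a, b in zip(d, d[1:]))
            c = [criterion_location(h, f) for h in grid]
            assert all(a > b for a, b in zip(c, c[1:]))
        for h in (0.2, 0.5, 0.8):
            d = [dprime(h, f) for f in grid]
            assert all(a > b for a, b in zip(d, d[1:]))

    def test_boundary_rates_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            dprime(1.0, 0.5)

    def test_metrics_from_counts_composes(self):
        m = metrics_from_counts(ConfusionCounts(8, 2, 3, 7))
        assert m.hit_rate == 0.8 and m.fa_rate == 0.3
        assert m.dprime == pytest.approx(dprime(0.8, 0.3))


class TestSweepStatistics:
    def test_df_for_canonical_200_by_5(self, rng):
        d = rng.normal(size=(200, 5)) + np.array([0, 0.2, 0.5, 0.3, 0.1])
        s = sweep_statistics(d)
        assert s.anova_df == (4, 995)
        assert s.paired_df == 199
        assert s.anova_defined and s.paired_defined

    def test_matches_scipy_f_oneway(self, rng):
        d = rng.normal(size=(30, 4)) + np.array([0, 1, 0.5, 0.2])
        s = sweep_statistics(d)
        F, p = stats.f_oneway(*(d[:, j] for j in range(4)))
        assert s.anova_F == pytest.approx(float(F))
        assert s.anova_p == pytest.approx(float(p))

    def test_paired_t_between_two_highest_means(self, rng):
        d = rng.normal(scale=0.1, size=(50, 3)) + np.array([0.0, 2.0, 1.0])
        s = sweep_statistics(d)
        assert (s.best_alpha_index, s.second_alpha_index) == (1, 2)
        t, _ = stats.ttest_rel(d[:, 1], d[:, 2])
        assert s.paired_t == pytest.approx(float(t))

    def test_constant_matrix_flagged_undefined(self):
        s = sweep_statistics(np.full((5, 4), 1.3))
        assert not s.anova_defined and not s.paired_defined

    def test_zero_within_pair_variance_flagged(self):
        s = sweep_statistics(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert not s.paired_defined

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            sweep_statistics(np.ones((1, 5)))
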