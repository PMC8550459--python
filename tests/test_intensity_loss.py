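"""Intensity-weighted cross-entropy: exact weight arithmetic, closed-form CE,
subsampling correction, and the uniform-intensity equivalences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from goalattn.losses import (
    IntensityConfig,
    cross_entropy,
    per_image_weight,
    subsample_correction,
    weighted_batch_loss,
)


def config(alpha, n=1000, target=(0,)):
    return IntensityConfig(alpha, n, frozenset(target))


class TestPerImageWeight:
    @pytest.mark.parametrize(
        "alpha, expected_nontarget",
        [
            (0.001, 0.999 / 999),   # uniform: equals the target weight
            (0.002, 0.998 / 999),
            (0.5, 0.5 / 999),
            (0.999, 0.001 / 999),
            (1.0, 0.0),
        ],
    )
    def test_canonical_grid_weights(self, alpha, expected_nontarget):
        cfg = config(alpha)
        assert per_image_weight(0, cfg) == alpha
        assert per_image_weight(7, cfg) == pytest.approx(expected_nontarget, abs=1e-15)

    def test_uniform_intensity_weights_all_equal(self):
        cfg = config(0.001)
        assert per_image_weight(0, cfg) == pytest.approx(per_image_weight(5, cfg), abs=1e-15)

    def test_exclusive_focus_zeroes_nontarget(self):
        assert per_image_weight(3, config(1.0)) == 0.0

    @given(st.integers(2, 2000), st.floats(0, 1))
    @settings(deadline=None, max_examples=100)
    def test_class_mass_conservation(self, n, frac):
        alpha = 1.0 / n + frac * (1.0 - 1.0 / n)
        cfg = config(alpha, n)
        total = alpha + (n - 1) * cfg.nontarget_weight
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_monotonicity_in_alpha(self):
        alphas = [0.001, 0.002, 0.5, 0.999, 1.0]
        tw = [per_image_weight(0, config(a)) for a in alphas]
        nw = [per_image_weight(1, config(a)) for a in alphas]
        assert all(a <= b for a, b in zip(tw, tw[1:]))
        assert all(a >= b for a, b in zip(nw, nw[1:]))

    def test_alpha_below_uniform_rejected(self):
        with pytest.raises(ValueError, match=r"1/N"):
            config(0.0005)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            IntensityConfig(0.5, 10, frozenset())


class TestCrossEntropy:
    @pytest.mark.parametrize(
        "p, expected", [(1.0, 0.0), (0.25, np.log(4)), (0.5, np.log(2))]
    )
    def test_closed_forms(self, p, expected):
        assert cross_entropy(p) == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_probability_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            val = cross_entropy(0.0)
        assert val == pytest.approx(-np.log(1e-12))

    def test_probability_above_one_rejected(self):
        with pytest.raises(ValueError, match="above 1"):
            cross_entropy(1.5)


class TestWeightedBatchLoss:
    def test_single_target_image_full_focus(self):
        cfg = config(1.0, n=10)
        loss = weighted_batch_loss(np.array([0.5]), np.array([0]), cfg)
        assert loss == pytest.approx(np.log(2), abs=1e-10)

    def test_nontarget_annihilated_at_full_focus(self):
        cfg = config(1.0, n=10)
        loss = weighted_batch_loss(np.array([0.01]), np.array([3]), cfg)
        assert loss == 0.0

    def test_uniform_intensity_equals_scaled_sum_ce(self, rng):
        n = 10
        cfg = config(1.0 / n, n=n)
        probs = rng.uniform(0.05, 0.95, size=20)
        labels = rng.integers(0, n, size=20)
        expected = np.sum(-np.log(probs)) / n
        assert weighted_batch_loss(probs, labels, cfg) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            weighted_batch_loss(np.array([0.5, 0.5]), np.array([0]), config(0.5, 10))

    def test_target_correction_must_be_one(self):
        with pytest.raises(ValueError, match="correction exactly 1"):
            weighted_batch_loss(
                np.array([0.5]), np.array([0]), config(0.5, 10), np.array([2.0])
            )


class TestSubsampleCorrection:
    @pytest.mark.parametrize(
        "n_images, n_sampled, expected", [(20, 2, 10.0), (7, 7, 1.0), (15, 2, 7.5)]
    )
    def test_inverse_sampling_fraction(self, n_images, n_sampled, expected):
        assert subsample_correction(n_images, n_sampled) == expected

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            subsample_correction(10, 0)

    def test_oversample_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            subsample_correction(5, 6)


class TestGradientEquivalenceAtUniformIntensity:
    def test_weighted_gradient_parallel_to_unweighted_mean_ce(self, tiny_backbone, tiny_split):
        """At alpha = 1/N the weighted sum loss is (1/N) * sum CE, so its
        attention gradient must be parallel to the plain mean-CE gradient."""
        from goalattn.attention import ModulatedClassifier
        from goalattn.data import images_to_arrays
        from goalattn.losses import per_image_weight

        X, y, _ = images_to_arrays(tiny_split.train[:16])
        n = tiny_backbone.n_classes_
        cfg = config(1.0 / n, n=n, target=(0,))
        model = ModulatedClassifier(tiny_backbone)
        pre = model.insertion_activations(X)
        w_uniform = np.array([per_image_weight(int(lbl), cfg) for lbl in y])
        _, g_weighted = model.loss_and_attention_grad(pre, y, w_uniform)
        _, g_mean = model.loss_and_attention_grad(pre, y, np.full(len(y), 1.0 / len(y)))
        ghat_w = g_weighted / np.linalg.norm(g_weighted)
        ghat_m = g_mean / np.linalg.norm(g_mean)
        np.testing.assert_allclose(ghat_w, ghat_m, atol=1e-5)


class TestSubsamplingUnbiasedness:
    def test_monte_carlo_mean_matches_full_data_loss(self, rng):
        """Corrected subsampled weighted loss is an unbiased estimate of the
        full-data weighted loss (5 classes x 20 images, 2000 resamples)."""
        n_classes, per_class = 5, 20
        cfg = config(0.5, n=n_classes, target=(0,))
        labels = np.repeat(np.arange(n_classes), per_class)
        probs = rng.uniform(0.05, 0.95, size=labels.size)
        full = weighted_batch_loss(probs, labels, cfg)

        ce = -np.log(probs)
        w = np.array([per_image_weight(int(c), cfg) for c in labels])
        draws = []
        frac = 0.1
        s_c = max(1, round(frac * per_class))
        for _ in range(2000):
            total = 0.0
            for c in range(n_classes):
                idx = np.flatnonzero(labels == c)
                if c == 0:
                    total += np.sum(w[idx] * ce[idx])
                else:
                    pick = rng.choice(idx, size=s_c, replace=False)
                    total += (per_class / s_c) * np.sum(w[pick] * ce[pick])
            draws.append(total)
        draws = np.asarray(draws)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - full) <= 2 * se
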