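"""Training regime: deterministic splits, per-epoch subsampling with
corrections, relative-improvement early stopping, and reproducible
attention training with a frozen backbone."""

import numpy as np
import pytest

from goalattn.attention import ModulatedClassifier
from goalattn.data import LabeledImage
from goalattn.losses import IntensityConfig
from goalattn.training import (
    GoalDirectedAttention,
    TrainConfig,
    make_epoch_sample,
    should_stop,
    split_dataset,
    train_attention,
)


def make_pool(n_classes, per_class, size=8):
    rng = np.random.default_rng(5)
    return [
        LabeledImage(rng.uniform(size=(size, size, 3)), c, f"c{c}_i{i}")
        for c in range(n_classes)
        for i in range(per_class)
    ]


class TestSplitDataset:
    def test_per_class_counts(self):
        split = split_dataset(make_pool(10, 20), 0.9, seed=3)
        idx = split.class_index
        for c in range(10):
            assert len(idx["train"][c]) == 18
            assert len(idx["validation"][c]) == 2

    def test_full_fraction_rejected(self):
        with pytest.raises(ValueError, match="validation"):
            split_dataset(make_pool(3, 10), 1.0, seed=0)

    def test_deterministic_given_seed(self):
        a = split_dataset(make_pool(5, 12), 0.9, seed=42, test_fraction=1 / 6)
        b = split_dataset(make_pool(5, 12), 0.9, seed=42, test_fraction=1 / 6)
        for part in ("train", "validation", "test"):
            assert {i.id for i in getattr(a, part)} == {i.id for i in getattr(b, part)}

    def test_different_seed_changes_split(self):
        a = split_dataset(make_pool(5, 12), 0.9, seed=1)
        b = split_dataset(make_pool(5, 12), 0.9, seed=2)
        assert {i.id for i in a.validation} != {i.id for i in b.validation}

    def test_small_class_rejected_by_name(self):
        pool = make_pool(2, 10) + [LabeledImage(np.zeros((8, 8, 3)), 7, "lone")]
        with pytest.raises(ValueError, match="class 7"):
            split_dataset(pool, 0.9, seed=0)

    def test_splits_are_disjoint(self):
        split = split_dataset(make_pool(4, 12), 0.9, seed=9, test_fraction=1 / 6)
        ids = [i.id for part in (split.train, split.validation, split.test) for i in part]
        assert len(ids) == len(set(ids)) == 48


class TestEpochSampling:
    def setup_method(self):
        self.split = split_dataset(make_pool(5, 22), 10 / 11, seed=0)  # 20 train per class
        self.cfg = IntensityConfig(0.5, 5, frozenset({1}))

    def test_counts_and_corrections(self, rng):
        ids, corr = make_epoch_sample(self.split, self.cfg, 0.1, rng)
        # all 20 target images + 2 per non-target class
        assert len(ids) == 20 + 4 * 2
        labels = {i.id: i.label for i in self.split.train}
        for img_id, c in zip(ids, corr):
            assert c == (1.0 if labels[img_id] == 1 else 10.0)

    def test_full_fraction_no_subsampling(self, rng):
        ids, corr = make_epoch_sample(self.split, self.cfg, 1.0, rng)
        assert len(ids) == 100
        assert np.all(corr == 1.0)

    def test_minimum_one_image_per_class(self, rng):
        split = split_dataset(make_pool(3, 4), 0.75, seed=0)  # 3 train per class
        ids, corr = make_epoch_sample(split, IntensityConfig(0.5, 3, frozenset({0})), 0.1, rng)
        labels = {i.id: i.label for i in split.train}
        nontarget = [i for i in ids if labels[i] != 0]
        assert len(nontarget) == 2  # one per non-target class
        assert all(corr[ids.index(i)] == 3.0 for i in nontarget)

    def test_resampled_each_call(self, rng):
        draws = {tuple(make_epoch_sample(self.split, self.cfg, 0.1, rng)[0]) for _ in range(6)}
        assert len(draws) > 1


class TestShouldStop:
    @pytest.mark.parametrize(
        "losses, expected",
        [
            ([1.0, 0.9995, 0.99945], True),   # 0.05% then 0.005%
            ([1.0, 0.9, 0.8995], False),      # only last check is sub-threshold
            ([1.0], False),
            ([1.0, 0.9], False),
            ([1.0, 0.99, 0.9899, 0.98985], True),
        ],
    )
    def test_two_consecutive_subthreshold_checks(self, losses, expected):
        assert should_stop(losses, 0.001, 2) is expected

    def test_rising_loss_counts_toward_stopping(self):
        assert should_stop([1.0, 1.01, 1.02], 0.001, 2) is True


class TestTrainAttention:
    def _run(self, backbone, split, alpha=1.0, seed=123, max_epochs=6):
        cfg = TrainConfig(seed=seed, learning_rate=0.01, max_epochs=max_epochs)
        intensity = IntensityConfig(alpha, backbone.n_classes_, frozenset({0}))
        model = ModulatedClassifier(backbone)
        w, log = train_attention(model, split, intensity, cfg)
        return w, log, model

    def test_deterministic_given_seed(self, tiny_backbone, tiny_split):
        w1, _, _ = self._run(tiny_backbone, tiny_split)
        w2, _, _ = self._run(tiny_backbone, tiny_split)
        np.testing.assert_array_equal(w1.values, w2.values)

    def test_different_seed_differs(self, tiny_backbone, tiny_split):
        w1, _, _ = self._run(tiny_backbone, tiny_split, seed=1)
        w2, _, _ = self._run(tiny_backbone, tiny_split, seed=2)
        assert not np.array_equal(w1.values, w2.values)

    def test_weights_nonnegative_after_training(self, tiny_backbone, tiny_split):
        w, _, _ = self._run(tiny_backbone, tiny_split, max_epochs=20)
        assert np.all(w.values >= 0)

    def test_backbone_parameters_frozen(self, tiny_backbone, tiny_split):
        before = tiny_backbone.snapshot()
        self._run(tiny_backbone, tiny_split, max_epochs=8)
        after = tiny_backbone.params_
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_requires_identity_initialization(self, tiny_backbone, tiny_split):
        from goalattn.attention import AttentionWeights

        model = ModulatedClassifier(
            tiny_backbone,
            attention=AttentionWeights(np.full(tiny_backbone.insertion_filters_, 0.5)),
        )
        with pytest.raises(ValueError, match="all ones"):
            train_attention(
                model,
                tiny_split,
                IntensityConfig(0.5, tiny_backbone.n_classes_, frozenset({0})),
                TrainConfig(seed=0),
            )

    def test_log_records_epochs_and_checks(self, tiny_backbone, tiny_split, tmp_path):
        w, log, _ = self._run(tiny_backbone, tiny_split, max_epochs=6)
        assert log.n_epochs <= 6
        assert log.stopped_reason in ("early_stop", "max_epochs")
        assert all(e % 2 == 1 for e, _ in log.val_checks)  # checks at epochs 2, 4, ...
        log.to_csv(tmp_path / "log.csv")
        header = (tmp_path / "log.csv").read_text().splitlines()[0]
        assert header == "epoch,train_loss,val_loss,stopped_reason"

    def test_full_focus_improves_target_hit_rate(self, tiny_backbone, tiny_split):
        from goalattn.data import images_to_arrays

        X, y, _ = images_to_arrays(tiny_split.train)
        tgt = y == 0
        base_hits = np.mean(tiny_backbone.predict(X[tgt]) == 0)
        _, _, model = self._run(tiny_backbone, tiny_split, alpha=1.0, max_epochs=60)
        trained_hits = np.mean(model.predict(X[tgt]) == 0)
        assert trained_hits >= base_hits

    def test_uniform_intensity_keeps_validation_loss_stable(self, tiny_backbone, tiny_split):
        """The no-selective-attention control should stay near initialization:
        validation loss does not rise more than 5% above its first check."""
        n = tiny_backbone.n_classes_
        _, log, _ = self._run(tiny_backbone, tiny_split, alpha=1.0 / n, max_epochs=40)
        losses = [v for _, v in log.val_checks]
        assert losses[-1] <= 1.05 * losses[0]


class TestEstimatorInterface:
    def test_fit_predict_roundtrip(self, tiny_backbone, tiny_split):
        from goalattn.data import images_to_arrays

        est = GoalDirectedAttention(
            tiny_backbone, alpha=1.0, target=(0,), learning_rate=0.01,
            max_epochs=6, random_state=0,
        )
        est.fit_split(tiny_split)
        assert est.attention_weights_.shape == (tiny_backbone.insertion_filters_,)
        assert est.attention_.alpha == 1.0 and est.attention_.target == (0,)
        X, _, _ = images_to_arrays(tiny_split.test)
        assert est.predict(X).shape == (len(X),)

    def test_sklearn_get_set_params(self, tiny_backbone):
        est = GoalDirectedAttention(tiny_backbone, alpha=0.5)
        assert est.get_params()["alpha"] == 0.5
        est.set_params(alpha=1.0)
        assert est.alpha == 1.0
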