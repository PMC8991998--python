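import numpy as np
import pytest

from betadisc.cnn_classify import (
    BETA,
    ClusterClassifier,
    PatchBatch,
    SplitSpec,
    TrainConfig,
    batch_from_dictionaries,
    cross_entropy,
    learning_curve,
    load_results,
    prepare_patch,
    split,
    train_classifier,
)
from betadisc.evaluation import roc
from betadisc.synth_events import default_config, sample_dictionaries

from conftest import make_cluster, make_dictionary


class TestPreparePatch:
    def test_single_pixel_normalized_and_centered(self):
        patch = prepare_patch(make_cluster([[8.0]]))
        assert patch.shape == (24, 24)
        assert patch[11, 11] == 1.0
        assert patch.sum() == 1.0

    def test_block_centered(self, rng):
        raw = rng.uniform(1, 10, (3, 5))
        patch = prepare_patch(make_cluster(raw))
        nz = np.argwhere(patch > 0)
        r0, c0 = nz.min(axis=0)
        r1, c1 = nz.max(axis=0)
        assert (r1 - r0 + 1, c1 - c0 + 1) == (3, 5)
        # centered: margins differ by at most one pixel
        assert abs(r0 - (23 - r1)) <= 1 and abs(c0 - (23 - c1)) <= 1

    def test_max_is_one_and_ratios_preserved(self, rng):
        raw = rng.uniform(1, 50, (6, 4))
        patch = prepare_patch(make_cluster(raw))
        assert patch.max() == 1.0
        sub = patch[patch > 0]
        np.testing.assert_allclose(
            np.sort(sub.ravel()), np.sort(raw.ravel() / raw.max()), rtol=1e-12
        )

    def test_intensity_scale_invariance(self, rng):
        raw = rng.uniform(1, 50, (5, 5))
        p1 = prepare_patch(make_cluster(raw))
        p2 = prepare_patch(make_cluster(raw * 37.5))
        np.testing.assert_allclose(p1, p2, rtol=1e-12)

    def test_oversized_cluster_dropped_or_raises(self, rng):
        big = make_cluster(rng.uniform(1, 2, (25, 10)))
        assert prepare_patch(big) is None
        with pytest.raises(ValueError):
            prepare_patch(big, strict=True)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        pred = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(pred, pred) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log2(self):
        pred = np.array([[0.5, 0.5]])
        truth = np.array([[1.0, 0.0]])
        assert cross_entropy(pred, truth) == pytest.approx(np.log(2), abs=1e-9)

    def test_batch_is_mean_of_per_example(self, rng):
        pred = rng.dirichlet([1, 1], size=8)
        truth = np.eye(2)[rng.integers(0, 2, 8)]
        per_example = [
            cross_entropy(pred[i : i + 1], truth[i : i + 1]) for i in range(8)
        ]
        assert cross_entropy(pred, truth) == pytest.approx(np.mean(per_example))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.ones((2, 2)) / 2, np.ones((3, 2)))


class TestSplit:
    def batch(self, n_beta, n_gamma):
        patches = np.zeros((n_beta + n_gamma, 24, 24))
        patches[:, 12, 12] = 1.0
        labels = np.zeros((n_beta + n_gamma, 2))
        labels[:n_beta, BETA] = 1
        labels[n_beta:, 1 - BETA] = 1
        return PatchBatch(patches, labels)

    def test_60_20_20_counts(self):
        train, val, test = split(self.batch(50, 50), SplitSpec(seed=0))
        assert (train.n, val.n, test.n) == (60, 20, 20)

    def test_deterministic_given_seed(self):
        b = self.batch(40, 40)
        t1 = split(b, SplitSpec(seed=3))
        t2 = split(b, SplitSpec(seed=3))
        for a, c in zip(t1, t2):
            np.testing.assert_array_equal(a.labels, c.labels)
            np.testing.assert_array_equal(a.patches, c.patches)

    def test_stratification_preserves_proportions(self):
        train, val, test = split(self.batch(80, 20), SplitSpec(seed=1))
        for fold, frac in ((train, 0.6), (val, 0.2), (test, 0.2)):
            assert fold.is_beta.sum() == round(80 * frac)
            assert (~fold.is_beta).sum() == round(20 * frac)

    def test_partition_disjoint_and_exhaustive(self):
        b = self.batch(30, 30)
        b.patches += np.arange(60)[:, None, None] * 1e-6  # make rows unique
        folds = split(b, SplitSpec(seed=2))
        assert sum(f.n for f in folds) == 60
        seen = np.concatenate([f.patches[:, 0, 0] for f in folds])
        assert len(np.unique(seen)) == 60

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            split(self.batch(4, 50), SplitSpec(seed=0))


def toy_batches(rng, n=80):
    """Linearly separable toy patches: two distinct constant patterns."""
    patches = np.zeros((n, 24, 24))
    labels = np.zeros((n, 2))
    for i in range(n):
        if i % 2 == 0:  # "beta": horizontal bar
            patches[i, 12, 6:18] = 1.0
            labels[i, BETA] = 1
        else:  # "gamma": single pixel
            patches[i, 12, 12] = 1.0
            labels[i, 1 - BETA] = 1
    idx = rng.permutation(n)
    return PatchBatch(patches[idx[: n // 2]], labels[idx[: n // 2]]), PatchBatch(
        patches[idx[n // 2 :]], labels[idx[n // 2 :]]
    )


class TestTraining:
    def test_separable_toy_reaches_perfect_auc(self, rng):
        train, val = toy_batches(rng)
        res = train_classifier(
            train, val, loss="ce", config=TrainConfig(seed=0, max_epochs=15)
        )
        assert roc(res.predict_scores(val)).auc == pytest.approx(1.0)

    def test_fixed_seed_reproducible_history(self, rng):
        train, val = toy_batches(rng)
        cfg = TrainConfig(seed=7, max_epochs=5)
        r1 = train_classifier(train, val, loss="ce", config=cfg)
        r2 = train_classifier(train, val, loss="ce", config=cfg)
        assert r1.history == r2.history

    def test_probabilities_on_simplex(self, rng):
        train, val = toy_batches(rng)
        res = train_classifier(
            train, val, loss="ce", config=TrainConfig(seed=0, max_epochs=2)
        )
        probs = res.predict_proba(val.patches)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_wmw_loss_trains_on_toy_data(self, rng):
        train, val = toy_batches(rng)
        res = train_classifier(
            train, val, loss="wmw", config=TrainConfig(seed=0, max_epochs=15)
        )
        assert roc(res.predict_scores(val)).auc >= 0.95

    def test_warm_start_never_worse_than_init_on_val_loss(self, rng):
        """A fine-tune returns weights at least as good (by its own
        validation loss) as the warm-start weights."""
        from betadisc.cnn_classify import _eval_loss

        train, val = toy_batches(rng)
        ce = train_classifier(train, val, loss="ce",
                              config=TrainConfig(seed=0, max_epochs=5))
        cfg = TrainConfig(seed=1, max_epochs=5, init_state=ce.net.get_state())
        wmw = train_classifier(train, val, loss="wmw", config=cfg)
        init_loss = _eval_loss(ce.net, val, "wmw", cfg)
        final_loss = _eval_loss(wmw.net, val, "wmw", cfg)
        assert final_loss <= init_loss + 1e-9

    def test_unknown_loss_rejected(self, rng):
        train, val = toy_batches(rng)
        with pytest.raises(ValueError):
            train_classifier(train, val, loss="hinge")


@pytest.fixture(scope="module")
def fitted():
    cfg = default_config(seed=21)
    beta, gamma = sample_dictionaries(cfg, 300)
    model = ClusterClassifier.from_dictionaries(beta, gamma, SplitSpec(seed=0))
    res = model.fit(loss="ce", config=TrainConfig(seed=0, max_epochs=10))
    return cfg, model, res


class TestEndToEnd:
    def test_default_conditions_reach_high_auc(self, fitted):
        _, model, res = fitted
        assert model.test_auc(res) >= 0.9

    def test_cross_dictionary_scoring(self, fitted):
        """A model trained against one gamma source can be scored unchanged
        on dictionaries from another source."""
        cfg, _, res = fitted
        other = default_config(seed=77)
        other.separability = 0.8
        bt, gt = sample_dictionaries(other, 150)
        ss = res.score_dictionaries(bt, gt)
        assert ss.m == 150 and ss.n == 150
        assert 0.0 <= roc(ss).auc <= 1.0

    def test_checkpoint_roundtrip(self, fitted, tmp_path, rng):
        _, model, res = fitted
        path = tmp_path / "model.npz"
        res.save(path)
        back = load_results(path)
        x = model.test.patches[:16]
        np.testing.assert_allclose(
            back.predict_proba(x), res.predict_proba(x), atol=1e-7
        )
        assert "Patch classifier" in back.summary()


class TestLearningCurve:
    def test_one_row_per_fraction_and_monotone_n(self, rng):
        cfg = default_config(seed=31)
        beta, gamma = sample_dictionaries(cfg, 150)
        model = ClusterClassifier.from_dictionaries(beta, gamma, SplitSpec(seed=0))
        rows = learning_curve(
            model, [0.25, 1.0], repeats=2,
            config=TrainConfig(seed=0, max_epochs=4),
        )
        assert [r["fraction"] for r in rows] == [0.25, 1.0]
        assert rows[0]["n_train"] < rows[1]["n_train"]
        for r in rows:
            assert r["repeats"] == 2
            assert 0.0 <= r["mean_auc"] <= 1.0

    def test_invalid_fraction_rejected(self, rng):
        cfg = default_config(seed=32)
        beta, gamma = sample_dictionaries(cfg, 100)
        model = ClusterClassifier.from_dictionaries(beta, gamma, SplitSpec(seed=0))
        with pytest.raises(ValueError):
            learning_curve(model, [1.5], repeats=1)


def test_batch_from_dictionaries_counts_and_labels():
    beta = make_dictionary([make_cluster([[5.0]], label="beta")] * 3, "beta")
    gamma = make_dictionary([make_cluster([[2.0]], label="gamma")] * 2, "gamma")
    batch = batch_from_dictionaries(beta, gamma)
    assert batch.n == 5
    assert batch.is_beta.sum() == 3
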