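import numpy as np
import pytest

from betadisc.evaluation import roc
from betadisc.segmentation import (
    SegTrainConfig,
    SegmentationModel,
    SyntheticSAO,
    cluster_scores_from_segmentation,
    dice_score,
    gdl_gradient,
    generalized_dice_loss,
    make_sao_dataset,
    split_saos,
    synthesize_sao,
    train_segmenter,
)
from betadisc.synth_events import PlacementRecord, default_config, sample_dictionaries


@pytest.fixture(scope="module")
def dictionaries():
    return sample_dictionaries(default_config(seed=41), 200)


class TestSynthesizeSAO:
    def test_zero_counts_pure_background(self, dictionaries, rng):
        beta, gamma = dictionaries
        sao = synthesize_sao(beta, gamma, counts=(0, 0), rng=rng, shape=(60, 80))
        assert sao.records == []
        assert sao.target[..., 1].sum() == 0
        assert sao.target[..., 2].sum() == 0
        assert sao.target[..., 0].all()

    def test_counts_and_components(self, dictionaries, rng):
        from scipy import ndimage

        beta, gamma = dictionaries
        sao = synthesize_sao(beta, gamma, counts=(3, 2), rng=rng, shape=(120, 160))
        assert len(sao.records) == 5
        eight = np.ones((3, 3))
        _, nb = ndimage.label(sao.target[..., 1], structure=eight)
        _, ng = ndimage.label(sao.target[..., 2], structure=eight)
        assert nb == 3 and ng == 2

    def test_channels_partition_frame(self, dictionaries, rng):
        beta, gamma = dictionaries
        sao = synthesize_sao(beta, gamma, counts=(4, 4), rng=rng, shape=(120, 160))
        np.testing.assert_array_equal(sao.target.sum(axis=-1), 1.0)
        assert set(np.unique(sao.target)) <= {0.0, 1.0}

    def test_image_normalized_to_unit_range(self, dictionaries, rng):
        beta, gamma = dictionaries
        sao = synthesize_sao(beta, gamma, counts=(4, 4), rng=rng, shape=(120, 160))
        assert sao.image.min() >= 0.0
        assert sao.image.max() == pytest.approx(1.0)

    def test_default_shape_240x320(self, dictionaries, rng):
        beta, gamma = dictionaries
        sao = synthesize_sao(beta, gamma, counts=(2, 2), rng=rng)
        assert sao.image.shape == (240, 320)

    def test_split_500_images_gives_300_100_100(self):
        # split bookkeeping only; SAO objects can be lightweight stand-ins
        target = np.zeros((4, 4, 3))
        target[..., 0] = 1.0
        saos = [
            SyntheticSAO(np.zeros((4, 4)), target.copy(), []) for _ in range(500)
        ]
        train, val, test = split_saos(saos, seed=0)
        assert (len(train), len(val), len(test)) == (300, 100, 100)


class TestGeneralizedDiceLoss:
    def test_perfect_prediction_is_zero(self, rng):
        target = np.zeros((8, 8, 3))
        target[..., 0] = 1.0
        target[2:4, 2:4, 0] = 0.0
        target[2:4, 2:4, 1] = 1.0
        assert generalized_dice_loss(target, target) == pytest.approx(0.0)

    def test_disjoint_prediction_is_one(self):
        target = np.zeros((4, 4, 2))
        pred = np.zeros((4, 4, 2))
        target[:2, :, 0] = 1.0
        target[2:, :, 1] = 1.0
        pred[:2, :, 1] = 1.0
        pred[2:, :, 0] = 1.0
        assert generalized_dice_loss(pred, target) == pytest.approx(1.0)

    def test_single_class_half_overlap(self):
        """|y| = 4 pixels, binary prediction of 4 pixels overlapping 2."""
        target = np.zeros((4, 4, 1))
        pred = np.zeros((4, 4, 1))
        target[0, :, 0] = 1.0  # 4 pixels
        pred[0, 2:, 0] = 1.0  # overlap 2
        pred[1, :2, 0] = 1.0  # 2 more elsewhere
        assert generalized_dice_loss(pred, target) == pytest.approx(0.5)

    def test_equal_weights_single_class_reduces_to_one_minus_dice(self, rng):
        target = (rng.random((10, 10, 1)) < 0.3).astype(float)
        pred = (rng.random((10, 10, 1)) < 0.3).astype(float)
        if target.sum() == 0:
            target[0, 0, 0] = 1.0
        gdl = generalized_dice_loss(pred, target)
        dice = dice_score(pred[..., 0] > 0, target[..., 0] > 0)
        assert gdl == pytest.approx(1.0 - dice)

    def test_absent_class_excluded(self):
        target = np.zeros((4, 4, 3))
        target[..., 0] = 1.0  # classes 1, 2 absent
        pred = target.copy()
        assert generalized_dice_loss(pred, target) == pytest.approx(0.0)

    def test_bounded_between_zero_and_one(self, rng):
        for _ in range(20):
            target = np.eye(3)[rng.integers(0, 3, (6, 6))].astype(float)
            pred = rng.dirichlet([1, 1, 1], size=(6, 6))
            val = generalized_dice_loss(pred, target)
            assert -1e-12 <= val <= 1.0 + 1e-12

    def test_gradient_matches_finite_differences(self, rng):
        target = np.eye(3)[rng.integers(0, 3, (5, 5))].astype(float)
        pred = rng.dirichlet([1, 1, 1], size=(5, 5))
        grad = gdl_gradient(pred, target)
        eps = 1e-7
        for _ in range(10):
            i, j, c = rng.integers(0, 5), rng.integers(0, 5), rng.integers(0, 3)
            up, dn = pred.copy(), pred.copy()
            up[i, j, c] += eps
            dn[i, j, c] -= eps
            num = (
                generalized_dice_loss(up, target)
                - generalized_dice_loss(dn, target)
            ) / (2 * eps)
            assert grad[i, j, c] == pytest.approx(num, rel=1e-4, abs=1e-10)


class TestDiceScore:
    def test_identical_masks(self, rng):
        m = rng.random((6, 6)) < 0.4
        m[0, 0] = True
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[1, 1] = True
        assert dice_score(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True
        b[0, 2:] = True
        b[1, :2] = True
        assert dice_score(a, b) == 0.5

    def test_both_empty_is_one(self):
        assert dice_score(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0


class TestTraining:
    def test_memorizes_single_image(self, dictionaries):
        """Capacity check: training on one repeated small frame drives the
        training GDL near zero."""
        beta, gamma = dictionaries
        rng = np.random.default_rng(5)
        sao = synthesize_sao(beta, gamma, counts=(2, 2), rng=rng, shape=(64, 64))
        cfg = SegTrainConfig(seed=0, max_epochs=60, crop=64, crops_per_batch=1)
        res = train_segmenter([sao] * 4, [sao], config=cfg)
        assert min(res.history["train_loss"]) < 0.15

    def test_fixed_seed_reproducible(self, dictionaries):
        beta, gamma = dictionaries
        rng = np.random.default_rng(6)
        saos = make_sao_dataset(beta, gamma, 4, rng, counts=(2, 2), shape=(64, 64))
        cfg = SegTrainConfig(seed=3, max_epochs=3, crop=48)
        r1 = train_segmenter(saos[:3], saos[3:], config=cfg)
        r2 = train_segmenter(saos[:3], saos[3:], config=cfg)
        assert r1.history == r2.history

    def test_prediction_shapes_and_simplex(self, dictionaries):
        beta, gamma = dictionaries
        rng = np.random.default_rng(7)
        saos = make_sao_dataset(beta, gamma, 3, rng, counts=(2, 2), shape=(64, 64))
        res = train_segmenter(saos[:2], saos[2:],
                              config=SegTrainConfig(seed=0, max_epochs=2, crop=48))
        probs = res.predict_proba(saos[0].image)
        assert probs.shape == (64, 64, 3)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        labels = res.predict_labels(saos[0].image)
        assert set(np.unique(labels)) <= {0, 1, 2}


class TestClusterScores:
    def make_trained(self, dictionaries, n=6):
        beta, gamma = dictionaries
        rng = np.random.default_rng(8)
        saos = make_sao_dataset(beta, gamma, n, rng, counts=(3, 3), shape=(96, 96))
        res = train_segmenter(
            saos[: n - 2], saos[n - 2 :],
            config=SegTrainConfig(seed=0, max_epochs=10, crop=48),
        )
        return res, saos

    def test_scores_grouped_by_true_label(self, dictionaries):
        res, saos = self.make_trained(dictionaries)
        ss = cluster_scores_from_segmentation(res, saos[0])
        assert ss.m == 3 and ss.n == 3
        assert (ss.pooled() >= 0).all() and (ss.pooled() <= 1).all()

    def test_uninformative_model_gives_chance_auc(self, dictionaries):
        """A model predicting identical outputs everywhere scores every
        cluster equally; the ROC collapses to AUC 0.5."""
        from betadisc.segmentation import build_segmentation_network

        beta, gamma = dictionaries
        rng = np.random.default_rng(9)
        sao = synthesize_sao(beta, gamma, counts=(5, 5), rng=rng, shape=(96, 96))
        cfg = SegTrainConfig(seed=0)
        net = build_segmentation_network(cfg)
        for p in net.params:  # zero weights -> constant logits
            p[...] = 0.0
        res_like = type("R", (), {})()
        from betadisc import segmentation as seg_mod

        class Stub(seg_mod.SegmentationResults):
            def __init__(self):
                super().__init__(net, cfg, {"val_loss": []}, 0)

        ss = cluster_scores_from_segmentation(Stub(), sao)
        assert np.allclose(ss.pooled(), ss.pooled()[0])
        assert roc(ss).auc == pytest.approx(0.5)
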