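"""Semantic segmentation of SAO frames with generalized dice loss.

Instead of classifying pre-cut patches, a fully convolutional network labels
every pixel of an acquisition frame as background, beta, or gamma in one
pass.  Training frames are synthesized: clusters drawn from labeled
dictionaries are pasted onto a zero 240x320 canvas at non-overlapping
positions, the remaining zeros are filled with Gaussian background noise,
and the image is normalized to [0, 1].  Targets are three binary channels
(background, beta, gamma) that partition the frame.

Because background pixels outnumber event pixels by orders of magnitude,
the loss is the generalized dice loss (GDL): per-class overlap terms
weighted by the inverse squared ground-truth area, which keeps the tiny
event classes from being swamped.

For ROC comparison with the patch classifier, each synthesized cluster gets
a score: over its ground-truth member pixels, the (beta, gamma) outputs are
renormalized pairwise (p_b / (p_b + p_g), the two-way softmax of their
log-probabilities) and averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .cluster_detect import ClusterDictionary
from .evaluation import ScoreSet
from .synth_events import PlacementRecord, sample_cluster

logger = logging.getLogger(__name__)

SAO_SHAPE = (240, 320)
#: target channel order
CHANNELS = ("background", "beta", "gamma")
CLASS_ID = {"beta": 1, "gamma": 2}


@dataclass
class SyntheticSAO:
    """Composited frame + per-pixel ground truth + placement records."""

    image: np.ndarray  # (H, W) in [0, 1]
    target: np.ndarray  # (H, W, 3) binary, channels partition the frame
    records: list[PlacementRecord]

    def __post_init__(self) -> None:
        # compact storage: hundreds of frames are kept in memory at once
        self.image = np.asarray(self.image, dtype=np.float32)
        self.target = np.asarray(self.target, dtype=np.uint8)
        if self.target.shape != self.image.shape + (3,):
            raise ValueError("target must be (H, W, 3) matching the image")
        if not (self.target.sum(axis=-1) == 1).all():
            raise ValueError("target channels must partition the frame")


def synthesize_sao(
    beta_dict: ClusterDictionary,
    gamma_dict: ClusterDictionary,
    counts: tuple[int, int] = (2, 20),
    background: tuple[float, float] = (10.0, 2.0),
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] = SAO_SHAPE,
    min_separation: int = 2,
    max_retries: int = 200,
) -> SyntheticSAO:
    """Composite one SAO from dictionary clusters with ground truth.

    Clusters are drawn from the dictionaries with replacement and pasted at
    uniformly random non-overlapping positions on a zero image; still-zero
    pixels get N(mean, sd) background clipped at 0; the image is then
    scaled to [0, 1] by its maximum.
    """
    if len(beta_dict) == 0 or len(gamma_dict) == 0:
        raise ValueError("both dictionaries must be non-empty")
    if rng is None:
        rng = np.random.default_rng(0)
    H, W = shape
    canvas = np.zeros((H, W))
    occupied = np.zeros((H, W), dtype=bool)
    target = np.zeros((H, W, 3))
    records: list[PlacementRecord] = []

    plan = [("beta", beta_dict)] * counts[0] + [("gamma", gamma_dict)] * counts[1]
    for idx, (label, d) in enumerate(plan):
        cluster = d.clusters[int(rng.integers(len(d)))]
        h, w = cluster.patch.shape
        if h > H or w > W:
            raise ValueError(f"cluster bbox {h}x{w} exceeds SAO shape {shape}")
        placed = False
        m = min_separation
        for _ in range(max_retries):
            r0 = int(rng.integers(0, H - h + 1))
            c0 = int(rng.integers(0, W - w + 1))
            er0, ec0 = max(r0 - m, 0), max(c0 - m, 0)
            er1, ec1 = min(r0 + h + m, H), min(c0 + w + m, W)
            if occupied[er0:er1, ec0:ec1].any():
                continue
            view = canvas[r0 : r0 + h, c0 : c0 + w]
            view[cluster.mask] += cluster.patch[cluster.mask]
            target[r0 : r0 + h, c0 : c0 + w, CLASS_ID[label]][cluster.mask] = 1.0
            occupied[er0:er1, ec0:ec1] = True
            records.append(PlacementRecord(bbox=(r0, c0, h, w), label=label, cluster_index=idx))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place cluster {idx + 1}/{len(plan)} after "
                f"{max_retries} retries at SAO shape {shape}"
            )

    zero = canvas == 0
    canvas[zero] = np.clip(rng.normal(*background, int(zero.sum())), 0.0, None)
    peak = canvas.max()
    if peak > 0:
        canvas = canvas / peak
    target[..., 0] = 1.0 - target[..., 1] - target[..., 2]
    return SyntheticSAO(image=canvas, target=target, records=records)


def make_sao_dataset(
    beta_dict: ClusterDictionary,
    gamma_dict: ClusterDictionary,
    n_images: int,
    rng: np.random.Generator,
    **kwargs,
) -> list[SyntheticSAO]:
    return [
        synthesize_sao(beta_dict, gamma_dict, rng=rng, **kwargs)
        for _ in range(n_images)
    ]


def split_saos(
    saos: list[SyntheticSAO],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[SyntheticSAO], list[SyntheticSAO], list[SyntheticSAO]]:
    """Shuffled train/validation/test partition of synthesized SAOs."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(saos))
    n = len(saos)
    cut1 = int(round(fractions[0] * n))
    cut2 = cut1 + int(round(fractions[1] * n))
    pick = lambda idx: [saos[i] for i in idx]
    return pick(order[:cut1]), pick(order[cut1:cut2]), pick(order[cut2:])


# ---------------------------------------------------------------------------
# Generalized dice loss


def _gdl_terms(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class weights, intersections and unions over flattened pixels."""
    C = pred.shape[-1]
    p = pred.reshape(-1, C)
    y = target.reshape(-1, C)
    area = y.sum(axis=0)
    w = np.zeros(C)
    present = area > 0
    w[present] = 1.0 / area[present] ** 2
    if not present.all():
        logger.debug("classes absent from target excluded from GDL: %s",
                     [CHANNELS[c] for c in np.flatnonzero(~present)])
    inter = (y * p).sum(axis=0)
    union = (y + p).sum(axis=0)
    return w, inter, union


def generalized_dice_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """GDL = 1 - 2 (sum_c w_c sum_n y p) / (sum_c w_c sum_n (y + p)),
    w_c = 1 / (sum_n y_c)^2; classes absent from the target get w_c = 0.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    w, inter, union = _gdl_terms(pred, target)
    denom = (w * union).sum()
    if denom == 0:
        return 0.0
    return float(1.0 - 2.0 * (w * inter).sum() / denom)


def gdl_gradient(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d GDL / d pred (weights treated as constants)."""
    shape = pred.shape
    C = shape[-1]
    p = pred.reshape(-1, C)
    y = target.reshape(-1, C)
    w, inter, union = _gdl_terms(pred, target)
    I = (w * inter).sum()
    U = (w * union).sum()
    if U == 0:
        return np.zeros(shape)
    grad = -2.0 * w[None, :] * (y * U - I) / U**2
    return grad.reshape(shape)


def dice_score(pred_mask: np.ndarray, target_mask: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); both empty -> 1 by convention."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(target_mask, dtype=bool)
    total = a.sum() + b.sum()
    if total == 0:
        logger.debug("dice of two empty masks reported as 1.0")
        return 1.0
    return float(2.0 * (a & b).sum() / total)


# ---------------------------------------------------------------------------
# Model


@dataclass
class SegTrainConfig:
    """Segmenter optimization settings.

    Training uses random crops of the full frames (the network is fully
    convolutional, so crop training transfers to full-resolution
    inference); ``crop`` is the crop side in pixels.  Crops are biased
    toward planted clusters so event pixels appear in most batches.
    """

    learning_rate: float = 1e-3
    crop: int = 48
    crops_per_batch: int = 8
    max_epochs: int = 30
    patience: int = 10
    filters: int = 32
    seed: int = 0
    #: probability that a training crop is centered on a planted cluster
    event_crop_prob: float = 0.9
    #: among event-centered crops, probability of centering on a beta
    #: cluster (betas are rarer per frame but ~8x larger); None = uniform
    #: over planted clusters.
    beta_crop_prob: float | None = 0.4


def build_segmentation_network(config: SegTrainConfig) -> nn.Sequential:
    rng = np.random.default_rng(config.seed)
    f = config.filters
    return nn.Sequential(
        [
            nn.Conv2D(1, f, rng), nn.ReLU(),
            nn.Conv2D(f, f, rng), nn.ReLU(),
            nn.Conv2D(f, f, rng), nn.ReLU(),
            nn.Conv2D(f, 3, rng),
        ]
    )


def _random_crop(
    sao: SyntheticSAO,
    size: int,
    rng: np.random.Generator,
    event_prob: float,
    beta_prob: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    H, W = sao.image.shape
    if H <= size or W <= size:
        return sao.image, sao.target
    if sao.records and rng.random() < event_prob:
        if beta_prob is None:
            candidates = sao.records
        else:
            want = "beta" if rng.random() < beta_prob else "gamma"
            candidates = [r for r in sao.records if r.label == want] or sao.records
        rec = candidates[int(rng.integers(len(candidates)))]
        r0, c0, h, w = rec.bbox
        cr = r0 + h // 2 - size // 2 + int(rng.integers(-10, 11))
        cc = c0 + w // 2 - size // 2 + int(rng.integers(-10, 11))
    else:
        cr = int(rng.integers(0, H - size + 1))
        cc = int(rng.integers(0, W - size + 1))
    cr = min(max(cr, 0), H - size)
    cc = min(max(cc, 0), W - size)
    return (
        sao.image[cr : cr + size, cc : cc + size],
        sao.target[cr : cr + size, cc : cc + size],
    )


def _predict_probs(net: nn.Sequential, image: np.ndarray) -> np.ndarray:
    """(H, W, 3) per-pixel softmax for one frame."""
    x = image[None, None, :, :].astype(nn.F32)
    logits = net.forward(x)[0].transpose(1, 2, 0)
    return nn.softmax(logits, axis=-1).astype(np.float64)


def train_segmenter(
    train: list[SyntheticSAO],
    val: list[SyntheticSAO],
    config: SegTrainConfig = SegTrainConfig(),
) -> "SegmentationResults":
    """Minimize GDL over crop minibatches with early stopping (patience 10).

    The validation signal is the GDL over a fixed set of deterministic
    crops from the validation frames; per-class dice on those crops is
    recorded per epoch.
    """
    if not train or not val:
        raise ValueError("training and validation sets must be non-empty")
    net = build_segmentation_network(config)
    opt = nn.Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    # fixed validation crops (deterministic given the config seed)
    vrng = np.random.default_rng(config.seed + 2)
    val_crops = [
        _random_crop(s, config.crop, vrng, config.event_crop_prob,
                     config.beta_crop_prob)
        for s in val
    ]

    history: dict[str, list[float]] = {
        "train_loss": [], "val_loss": [],
        "val_dice_background": [], "val_dice_beta": [], "val_dice_gamma": [],
    }
    best_val = np.inf
    best_state = net.get_state()
    best_epoch = 0
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        losses = []
        for start in range(0, len(train), config.crops_per_batch):
            batch = [
                _random_crop(train[i], config.crop, rng,
                             config.event_crop_prob, config.beta_crop_prob)
                for i in order[start : start + config.crops_per_batch]
            ]
            x = np.stack([im for im, _ in batch])[:, None, :, :].astype(nn.F32)
            y = np.stack([t for _, t in batch])  # (B, h, w, 3)
            logits = net.forward(x).transpose(0, 2, 3, 1)
            probs = nn.softmax(logits, axis=-1).astype(np.float64)
            # GDL per crop, averaged over the batch: crops centered on one
            # event class then carry that class's full gradient (absent
            # classes drop out per crop), which keeps the rarer-area class
            # from being crowded out of a pooled batch objective
            loss = float(
                np.mean([generalized_dice_loss(probs[i], y[i]) for i in range(len(batch))])
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"segmenter training diverged at epoch {epoch}"
                )
            dprobs = np.stack(
                [gdl_gradient(probs[i], y[i]) for i in range(len(batch))]
            ) / len(batch)
            dlogits = nn.softmax_backward(probs, dprobs)
            net.backward(dlogits.transpose(0, 3, 1, 2).astype(nn.F32))
            opt.step(net.grads)
            losses.append(loss)

        vx = np.stack([im for im, _ in val_crops])[:, None, :, :].astype(nn.F32)
        vy = np.stack([t for _, t in val_crops])
        vlogits = net.forward(vx).transpose(0, 2, 3, 1)
        vprobs = nn.softmax(vlogits, axis=-1).astype(np.float64)
        val_loss = float(
            np.mean([generalized_dice_loss(vprobs[i], vy[i]) for i in range(len(val_crops))])
        )
        pred_labels = vprobs.argmax(axis=-1)
        true_labels = vy.argmax(axis=-1)
        for c, name in enumerate(CHANNELS):
            history[f"val_dice_{name}"].append(
                dice_score(pred_labels == c, true_labels == c)
            )
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-12:
            best_val = float(val_loss)
            best_state = net.get_state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    net.set_state(best_state)
    return SegmentationResults(net=net, config=config, history=history, best_epoch=best_epoch)


class SegmentationResults:
    """Fitted segmenter: per-pixel prediction, dice reporting, cluster ROC."""

    def __init__(self, net: nn.Sequential, config: SegTrainConfig,
                 history: dict[str, list[float]], best_epoch: int):
        self.net = net
        self.config = config
        self.history = history
        self.best_epoch = best_epoch

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """(H, W, 3) class probabilities for an arbitrary frame."""
        return _predict_probs(self.net, np.asarray(image, dtype=np.float64))

    def predict_labels(self, image: np.ndarray) -> np.ndarray:
        """(H, W) argmax class map: 0 background, 1 beta, 2 gamma."""
        return self.predict_proba(image).argmax(axis=-1)

    def dice(self, saos: list[SyntheticSAO], pooled: bool = False) -> dict[str, float]:
        """Per-class dice over a set of frames.

        Default: dice per image, averaged; ``pooled=True`` pools pixels
        over the whole set first.
        """
        if pooled:
            inter = np.zeros(3)
            total = np.zeros(3)
            for s in saos:
                pl = self.predict_labels(s.image)
                tl = s.target.argmax(axis=-1)
                for c in range(3):
                    inter[c] += ((pl == c) & (tl == c)).sum()
                    total[c] += (pl == c).sum() + (tl == c).sum()
            return {
                name: float(2 * inter[c] / total[c]) if total[c] else 1.0
                for c, name in enumerate(CHANNELS)
            }
        scores = {name: [] for name in CHANNELS}
        for s in saos:
            pl = self.predict_labels(s.image)
            tl = s.target.argmax(axis=-1)
            for c, name in enumerate(CHANNELS):
                scores[name].append(dice_score(pl == c, tl == c))
        return {name: float(np.mean(v)) for name, v in scores.items()}

    def cluster_scores(self, sao: SyntheticSAO) -> ScoreSet:
        return cluster_scores_from_segmentation(self, sao)

    def plot_history(self, ax=None):
        """GDL and per-class validation dice per epoch (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["train_loss"], label="training GDL")
        ax.plot(self.history["val_loss"], label="validation GDL")
        for name in CHANNELS:
            ax.plot(self.history[f"val_dice_{name}"], ls="--",
                    label=f"val dice ({name})")
        ax.set_xlabel("epoch")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        lines = [
            "SAO segmenter (generalized dice loss)",
            f"  parameters: {self.net.n_parameters()}",
            f"  epochs run: {len(self.history['val_loss'])} "
            f"(best validation at epoch {self.best_epoch})",
            f"  best val GDL: {min(self.history['val_loss']):.6g}",
            "  final val dice (crops): "
            + ", ".join(
                f"{name}={self.history[f'val_dice_{name}'][-1]:.3f}"
                for name in CHANNELS
            ),
        ]
        return "\n".join(lines)


class SegmentationModel:
    """Model object over synthesized SAO folds; ``fit`` trains the network."""

    def __init__(self, train: list[SyntheticSAO], val: list[SyntheticSAO],
                 test: list[SyntheticSAO] | None = None):
        self.train = train
        self.val = val
        self.test = test

    def fit(self, config: SegTrainConfig = SegTrainConfig()) -> SegmentationResults:
        return train_segmenter(self.train, self.val, config=config)


def cluster_scores_from_segmentation(
    results: SegmentationResults, sao: SyntheticSAO
) -> ScoreSet:
    """Per-cluster beta scores from a segmenter's output.

    For each ground-truth cluster, the (beta, gamma) probabilities at its
    member pixels are renormalized pairwise (p_b / (p_b + p_g)) and
    averaged; scores are grouped by true label for ROC construction.
    """
    probs = results.predict_proba(sao.image)
    pos, neg = [], []
    for rec in sao.records:
        r0, c0, h, w = rec.bbox
        member = sao.target[r0 : r0 + h, c0 : c0 + w, CLASS_ID[rec.label]] > 0
        if not member.any():
            logger.warning("cluster %d has no member pixels; skipped", rec.cluster_index)
            continue
        pb = probs[r0 : r0 + h, c0 : c0 + w, 1][member]
        pg = probs[r0 : r0 + h, c0 : c0 + w, 2][member]
        # pixels where the background class saturates can underflow both
        # event probabilities to 0; such pixels carry no beta/gamma
        # information and score 0.5
        denom = pb + pg
        ratio = np.where(denom > 0, pb / np.where(denom > 0, denom, 1.0), 0.5)
        score = float(ratio.mean())
        (pos if rec.label == "beta" else neg).append(score)
    return ScoreSet(positives=np.array(pos), negatives=np.array(neg))
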