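"""LeNet-derived beta/gamma patch classifier.

Detected clusters are zero-padded into fixed 24x24 patches (bounding-box
crop centered on a zero canvas) and normalized per patch to [0, 1] by their
own maximum, so only relative intensity structure — not absolute energy
scale — reaches the network.  The classifier is a reduced LeNet-5: three
3x3 convolution stages (ReLU, 2x2 max pool; 24 -> 12 -> 6 -> 3) followed by
dense layers of 128, 64, 32 and 2 units with a softmax output.

Training minimizes either categorical cross-entropy or the WMW partial-AUC
surrogate (:mod:`betadisc.pauc_loss`), with early stopping on the
validation loss (patience 10 epochs, best-validation weights restored).
The data protocol is a stratified 60/20/20 train/validation/test split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .cluster_detect import Cluster, ClusterDictionary
from .evaluation import ScoreSet, roc
from .pauc_loss import WMWParams, grad_L2, loss_L2

logger = logging.getLogger(__name__)

PATCH_SIZE = 24
#: class order of the one-hot labels / softmax output; beta is the positive
#: class and sits in column 1.
CLASSES = ("gamma", "beta")
BETA = 1


def prepare_patch(cluster: Cluster, strict: bool = False) -> np.ndarray | None:
    """Center a cluster's bounding-box crop in a zero 24x24 canvas and
    normalize by its own maximum.

    Returns ``None`` (or raises if ``strict``) for clusters whose bounding
    box exceeds 24 pixels in either dimension; the fixed patch size assumes
    such clusters are absent or excluded.
    """
    h, w = cluster.patch.shape
    if h > PATCH_SIZE or w > PATCH_SIZE:
        if strict:
            raise ValueError(
                f"cluster bbox {h}x{w} exceeds the {PATCH_SIZE}x{PATCH_SIZE} patch"
            )
        return None
    canvas = np.zeros((PATCH_SIZE, PATCH_SIZE))
    r0 = (PATCH_SIZE - h) // 2
    c0 = (PATCH_SIZE - w) // 2
    canvas[r0 : r0 + h, c0 : c0 + w] = cluster.patch
    peak = canvas.max()
    if peak <= 0:
        raise ValueError("cluster patch has no positive intensity")
    return canvas / peak


@dataclass
class PatchBatch:
    """Prepared patches with one-hot labels (column order: gamma, beta)."""

    patches: np.ndarray  # (N, 24, 24) in [0, 1]
    labels: np.ndarray  # (N, 2) one-hot

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.patches.ndim != 3 or self.patches.shape[1:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError("patches must be (N, 24, 24)")
        if self.labels.shape != (self.patches.shape[0], 2):
            raise ValueError("labels must be (N, 2) one-hot")

    @property
    def n(self) -> int:
        return self.patches.shape[0]

    @property
    def is_beta(self) -> np.ndarray:
        return self.labels[:, BETA] == 1

    def subset(self, idx: np.ndarray) -> "PatchBatch":
        return PatchBatch(self.patches[idx], self.labels[idx])


def batch_from_dictionaries(*dicts: ClusterDictionary) -> PatchBatch:
    """Prepare all clusters of the given dictionaries into one batch;
    oversized clusters are dropped with a logged count."""
    patches, labels, dropped = [], [], 0
    for d in dicts:
        col = CLASSES.index(d.label)
        for c in d:
            p = prepare_patch(c)
            if p is None:
                dropped += 1
                continue
            patches.append(p)
            onehot = np.zeros(2)
            onehot[col] = 1.0
            labels.append(onehot)
    if dropped:
        logger.warning("dropped %d clusters exceeding %dx%d", dropped, PATCH_SIZE, PATCH_SIZE)
    return PatchBatch(np.stack(patches), np.stack(labels))


@dataclass
class SplitSpec:
    """Stratified train/validation/test fractions (default 60/20/20)."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split(batch: PatchBatch, spec: SplitSpec = SplitSpec()) -> tuple[PatchBatch, PatchBatch, PatchBatch]:
    """Deterministic stratified partition into train/val/test batches."""
    rng = np.random.default_rng(spec.seed)
    folds: list[list[np.ndarray]] = [[], [], []]
    groups = (
        [np.flatnonzero(batch.is_beta), np.flatnonzero(~batch.is_beta)]
        if spec.stratified
        else [np.arange(batch.n)]
    )
    for idx in groups:
        if spec.stratified and len(idx) < 5:
            raise ValueError(
                f"cannot stratify a class with only {len(idx)} examples"
            )
        idx = rng.permutation(idx)
        n = len(idx)
        cut1 = int(round(spec.fractions[0] * n))
        cut2 = cut1 + int(round(spec.fractions[1] * n))
        for fold, part in zip(folds, np.split(idx, [cut1, cut2])):
            fold.append(part)
    out = []
    for fold in folds:
        idx = np.sort(np.concatenate(fold))
        out.append(batch.subset(idx))
    return tuple(out)


@dataclass
class TrainConfig:
    """Optimization settings for the patch classifier.

    Filter counts per convolution stage and all optimizer settings are
    declared defaults (8/16/32 filters, Adam at 1e-3, batch 128), logged in
    results for provenance.
    """

    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 10
    filters: tuple[int, int, int] = (8, 16, 32)
    dense: tuple[int, ...] = (128, 64, 32)
    seed: int = 0
    wmw: WMWParams = field(default_factory=WMWParams)
    reduction: str = "mean"  # per-pair mean of the WMW double sum
    init_state: list | None = None  # warm-start weights (e.g. CE-pretrained)


def build_classifier_network(config: TrainConfig) -> nn.Sequential:
    rng = np.random.default_rng(config.seed)
    f1, f2, f3 = config.filters
    layers: list[nn.Layer] = [
        nn.Conv2D(1, f1, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(f1, f2, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(f2, f3, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Flatten(),
    ]
    d_in = f3 * (PATCH_SIZE // 8) ** 2
    for d_out in config.dense:
        layers += [nn.Dense(d_in, d_out, rng), nn.ReLU()]
        d_in = d_out
    layers.append(nn.Dense(d_in, 2, rng))
    return nn.Sequential(layers)


def cross_entropy(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-12) -> float:
    """Categorical cross-entropy between probability rows and one-hot truth."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return float(-(truth * np.log(pred + eps)).sum() / pred.shape[0])


def _forward_probs(net: nn.Sequential, patches: np.ndarray, chunk: int = 1024) -> np.ndarray:
    """Softmax probabilities, chunked to bound memory."""
    outs = []
    for i in range(0, patches.shape[0], chunk):
        x = patches[i : i + chunk, None, :, :].astype(nn.F32)
        outs.append(nn.softmax(net.forward(x)))
    return np.concatenate(outs).astype(np.float64)


def _eval_loss(net: nn.Sequential, batch: PatchBatch, loss: str, config: TrainConfig) -> float:
    probs = _forward_probs(net, batch.patches)
    if loss == "ce":
        return cross_entropy(probs, batch.labels)
    ss = ScoreSet(probs[batch.is_beta, BETA], probs[~batch.is_beta, BETA])
    return loss_L2(ss, config.wmw, reduction=config.reduction)


def train_classifier(
    train: PatchBatch,
    val: PatchBatch,
    loss: str = "ce",
    config: TrainConfig = TrainConfig(),
) -> "ClassifierResults":
    """Mini-batch training with early stopping on the validation loss.

    ``loss`` is ``'ce'`` (categorical cross-entropy) or ``'wmw'`` (the
    lower-left-ROC focused surrogate L2).  Training stops once the
    validation loss has not improved for ``config.patience`` consecutive
    epochs; the best-validation weights are restored.
    """
    if loss not in ("ce", "wmw"):
        raise ValueError(f"unknown loss {loss!r}")
    if train.n == 0 or val.n == 0:
        raise ValueError("training and validation folds must be non-empty")
    net = build_classifier_network(config)
    if config.init_state is not None:
        net.set_state(config.init_state)
    opt = nn.Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    # the initial state is the first best-validation candidate, so a
    # warm-started fine-tune never returns weights worse (by its own
    # validation loss) than the weights it started from
    best_val = _eval_loss(net, val, loss, config)
    best_state = net.get_state()
    best_epoch = -1
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(train.n)
        epoch_losses = []
        for start in range(0, train.n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = train.patches[idx][:, None, :, :].astype(nn.F32)
            y = train.labels[idx]
            probs = nn.softmax(net.forward(x))
            if loss == "ce":
                batch_loss = cross_entropy(probs, y)
                dlogits = (probs - y) / len(idx)
            else:
                is_beta = y[:, BETA] == 1
                if is_beta.all() or not is_beta.any():
                    continue  # no positive-negative pairs in this batch
                s = probs[:, BETA]
                ss = ScoreSet(s[is_beta], s[~is_beta])
                batch_loss = loss_L2(ss, config.wmw, reduction=config.reduction)
                gx, gy = grad_L2(ss, config.wmw, reduction=config.reduction)
                if not (np.any(gx) or np.any(gy)):
                    # cold start: all scores at/below the batch mean map to 0
                    # and the L2 gradient vanishes identically; fall back to
                    # the un-mapped surrogate L1 for this batch so training
                    # can spread the scores until the focusing map engages
                    gx, gy = grad_L1(ss, config.wmw, reduction=config.reduction)
                ds = np.zeros(len(idx))
                ds[is_beta] = gx
                ds[~is_beta] = gy
                dprobs = np.zeros_like(probs)
                dprobs[:, BETA] = ds
                dlogits = nn.softmax_backward(probs, dprobs)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            net.backward(dlogits.astype(nn.F32))
            opt.step(net.grads)
            epoch_losses.append(batch_loss)

        val_loss = _eval_loss(net, val, loss, config)
        history["train_loss"].append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = net.get_state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    net.set_state(best_state)
    return ClassifierResults(
        net=net, loss_name=loss, config=config, history=history, best_epoch=best_epoch
    )


class ClassifierResults:
    """Fitted patch classifier: weights, training history, scoring API."""

    def __init__(
        self,
        net: nn.Sequential,
        loss_name: str,
        config: TrainConfig,
        history: dict[str, list[float]],
        best_epoch: int,
    ):
        self.net = net
        self.loss_name = loss_name
        self.config = config
        self.history = history
        self.best_epoch = best_epoch

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """(N, 2) softmax rows, column order (gamma, beta)."""
        return _forward_probs(self.net, np.asarray(patches))

    def predict_scores(self, batch: PatchBatch) -> ScoreSet:
        """Beta-probability scores grouped by true label."""
        probs = self.predict_proba(batch.patches)
        return ScoreSet(
            positives=probs[batch.is_beta, BETA],
            negatives=probs[~batch.is_beta, BETA],
        )

    def score_dictionaries(
        self, beta: ClusterDictionary, gamma: ClusterDictionary
    ) -> ScoreSet:
        """Score arbitrary labeled dictionaries — including gamma sources
        the model was never trained on (cross-dictionary testing)."""
        return self.predict_scores(batch_from_dictionaries(beta, gamma))

    def plot_history(self, ax=None):
        """Training and validation loss per epoch (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["train_loss"], label="training loss")
        ax.plot(self.history["val_loss"], label="validation loss")
        ax.axvline(self.best_epoch, ls=":", color="gray", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel(f"{self.loss_name} loss")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            f"Patch classifier ({self.loss_name} loss)",
            f"  parameters: {self.net.n_parameters()}",
            f"  conv filters {self.config.filters}, dense {self.config.dense} -> 2",
            f"  epochs run: {len(self.history['val_loss'])} "
            f"(best validation at epoch {self.best_epoch})",
            f"  final train loss: {self.history['train_loss'][-1]:.6g}",
            f"  best val loss:  {min(self.history['val_loss']):.6g}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        state = {f"param{i}": p for i, p in enumerate(self.net.params)}
        np.savez(
            path,
            loss_name=self.loss_name,
            best_epoch=self.best_epoch,
            filters=np.array(self.config.filters),
            dense=np.array(self.config.dense),
            seed=self.config.seed,
            train_loss=np.array(self.history["train_loss"]),
            val_loss=np.array(self.history["val_loss"]),
            **state,
        )


def load_results(path) -> ClassifierResults:
    """Rebuild a saved :class:`ClassifierResults` from an .npz checkpoint."""
    data = np.load(path, allow_pickle=False)
    config = TrainConfig(
        filters=tuple(int(v) for v in data["filters"]),
        dense=tuple(int(v) for v in data["dense"]),
        seed=int(data["seed"]),
    )
    net = build_classifier_network(config)
    state = [data[f"param{i}"] for i in range(len(net.params))]
    net.set_state(state)
    history = {
        "train_loss": list(data["train_loss"]),
        "val_loss": list(data["val_loss"]),
    }
    return ClassifierResults(
        net=net,
        loss_name=str(data["loss_name"]),
        config=config,
        history=history,
        best_epoch=int(data["best_epoch"]),
    )


class ClusterClassifier:
    """Model object tying the data protocol to training.

    Build from labeled dictionaries (stratified 60/20/20 split) or from
    pre-made folds; ``fit`` trains with the chosen loss and returns a
    :class:`ClassifierResults`.
    """

    def __init__(self, train: PatchBatch, val: PatchBatch, test: PatchBatch | None = None):
        self.train = train
        self.val = val
        self.test = test

    @classmethod
    def from_dictionaries(
        cls,
        beta: ClusterDictionary,
        gamma: ClusterDictionary,
        spec: SplitSpec = SplitSpec(),
    ) -> "ClusterClassifier":
        batch = batch_from_dictionaries(beta, gamma)
        return cls(*split(batch, spec))

    def fit(self, loss: str = "ce", config: TrainConfig = TrainConfig()) -> ClassifierResults:
        return train_classifier(self.train, self.val, loss=loss, config=config)

    def test_auc(self, results: ClassifierResults) -> float:
        if self.test is None:
            raise ValueError("no test fold attached")
        return roc(results.predict_scores(self.test)).auc


def predict_scores(results: ClassifierResults, batch: PatchBatch) -> ScoreSet:
    return results.predict_scores(batch)


def learning_curve(
    model: ClusterClassifier,
    fractions: list[float],
    repeats: int = 5,
    loss: str = "ce",
    config: TrainConfig = TrainConfig(),
) -> list[dict]:
    """Retrain at subsampled training-fold sizes; test AUC mean/sd per
    fraction over ``repeats`` (fresh subsample and initialization seeds)."""
    if model.test is None:
        raise ValueError("learning_curve needs a test fold")
    rows = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"fraction {frac} outside (0, 1]")
        aucs = []
        for r in range(repeats):
            rng = np.random.default_rng(config.seed * 1000 + r)
            k = max(2, int(round(frac * model.train.n)))
            idx = rng.choice(model.train.n, size=k, replace=False)
            sub = model.train.subset(np.sort(idx))
            if len(set(sub.labels[:, BETA])) < 2:
                warnings.warn("subsample lost a class; skipping repeat")
                continue
            cfg = replace(config, seed=config.seed * 1000 + r)
            res = train_classifier(sub, model.val, loss=loss, config=cfg)
            aucs.append(roc(res.predict_scores(model.test)).auc)
        rows.append(
            {
                "fraction": frac,
                "n_train": max(2, int(round(frac * model.train.n))),
                "mean_auc": float(np.mean(aucs)),
                "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                "repeats": len(aucs),
            }
        )
    return rows
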