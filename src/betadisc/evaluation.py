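"""ROC construction, AUC, and partial AUC at high specificity.

The beta class is the positive class throughout: a false positive is a
gamma cluster called beta, which in the surgical application falsely flags
healthy tissue as cancerous.  The clinically relevant operating region is
therefore the lower-left part of the ROC (FPR <= 0.02), summarized by the
un-normalized partial AUC (an area out of a maximum of ``fpr_max``).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve


@dataclass
class ScoreSet:
    """Per-example beta-probability scores grouped by true class."""

    positives: np.ndarray  # beta scores x_i
    negatives: np.ndarray  # gamma scores y_j

    def __post_init__(self) -> None:
        self.positives = np.asarray(self.positives, dtype=np.float64).ravel()
        self.negatives = np.asarray(self.negatives, dtype=np.float64).ravel()
        if self.positives.size == 0 and self.negatives.size == 0:
            raise ValueError("score set needs at least one score")

    @property
    def m(self) -> int:
        return self.positives.size

    @property
    def n(self) -> int:
        return self.negatives.size

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.positives, self.negatives])


@dataclass
class ROCCurve:
    """ROC curve with thresholds in descending order and trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc = float(np.trapezoid(self.tpr, self.fpr))

    def tpr_at(self, fpr_value: float) -> float:
        """TPR at a given FPR, linearly interpolated."""
        return float(np.interp(fpr_value, self.fpr, self.tpr))

    def plot(self, ax=None, label: str | None = None, fpr_max: float = 1.0):
        """Draw the ROC curve (matplotlib); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        name = f"AUC = {self.auc:.3f}" if label is None else label
        ax.plot(self.fpr, self.tpr, label=name)
        ax.plot([0, 1], [0, 1], ls=":", color="gray", lw=0.8)
        ax.set_xlim(0, fpr_max)
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax


def roc(scores: ScoreSet) -> ROCCurve:
    """Threshold sweep over the scores; tied scores collapse to one step."""
    if scores.m < 1 or scores.n < 1:
        raise ValueError("ROC needs at least one positive and one negative")
    y_true = np.concatenate(
        [np.ones(scores.m, dtype=int), np.zeros(scores.n, dtype=int)]
    )
    fpr, tpr, thr = roc_curve(y_true, scores.pooled(), drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc(scores: ScoreSet) -> float:
    return roc(scores).auc


def partial_auc(curve: ROCCurve, fpr_max: float = 0.02) -> float:
    """Area under the ROC restricted to FPR <= fpr_max (un-normalized).

    The curve is linearly interpolated at the cut, so a perfect classifier
    scores ``fpr_max`` and a chance classifier ``fpr_max**2 / 2``.
    """
    if not 0.0 < fpr_max <= 1.0:
        raise ValueError("fpr_max must lie in (0, 1]")
    # clip every curve segment to [0, fpr_max]; vertical segments (tied FPR)
    # have zero width and contribute nothing
    x0, x1 = curve.fpr[:-1], curve.fpr[1:]
    y0, y1 = curve.tpr[:-1], curve.tpr[1:]
    xc = np.minimum(x1, fpr_max)
    width = np.clip(xc - x0, 0.0, None)
    dx = x1 - x0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(dx > 0, (xc - x0) / np.where(dx > 0, dx, 1.0), 0.0)
    yc = y0 + (y1 - y0) * frac
    return float((width * (y0 + yc) / 2.0).sum())


def compare_models(
    score_sets: dict[str, ScoreSet],
    fpr_max: float = 0.02,
    fpr_grid: tuple[float, ...] = (0.01, 0.02, 0.05, 0.1),
) -> list[dict]:
    """Tabulate AUC, partial AUC and TPR-at-FPR for named score sets.

    Supports cross-dictionary ("transfer") entries directly: score a model
    on whatever test set you like, name the ScoreSet accordingly, and pass
    it here.
    """
    if not score_sets:
        raise ValueError("no score sets to compare")
    rows = []
    for name, ss in score_sets.items():
        curve = roc(ss)
        row = {
            "model": name,
            "auc": curve.auc,
            f"pauc_{fpr_max:g}": partial_auc(curve, fpr_max),
            "m": ss.m,
            "n": ss.n,
        }
        for f in fpr_grid:
            row[f"tpr_at_fpr_{f:g}"] = curve.tpr_at(f)
        rows.append(row)
    return rows


def save_report(rows: list[dict], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2))
    elif path.suffix == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unsupported report format {path.suffix!r}")


def load_report(path: str | Path) -> list[dict]:
    path = Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    if path.suffix == ".csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        for row in rows:
            for key in row:
                if key != "model":
                    row[key] = int(row[key]) if key in ("m", "n") else float(row[key])
        return rows
    raise ValueError(f"unsupported report format {path.suffix!r}")
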