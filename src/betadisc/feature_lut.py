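"""Feature-based lookup-table discriminator.

The classical alternative to the learned classifiers: each cluster is
reduced to two handcrafted features, mean intensity and area (whose product
is proportional to the total energy deposited).  Per-class 2D histograms of
these features, each normalized to a probability distribution, are divided
element-wise (beta / gamma) to give a *selectivity map*; a cluster falling
in a bin whose selectivity exceeds a threshold is called beta.

Policies the ratio map needs but the features do not define: bins occupied
only by betas get +inf selectivity (beta at any finite threshold); bins
empty in both classes score 0 (gamma); clusters outside the fitted range
clamp to edge bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .cluster_detect import Cluster, ClusterDictionary
from .evaluation import ScoreSet


@dataclass
class LookupTable:
    """Fitted selectivity map over (mean intensity, area) bins."""

    mean_intensity_edges: np.ndarray
    area_edges: np.ndarray
    beta_hist: np.ndarray  # P(bin | beta), sums to 1
    gamma_hist: np.ndarray  # P(bin | gamma), sums to 1
    selectivity: np.ndarray  # beta_hist / gamma_hist with policies above
    threshold: float = 1.0


def fit_lookup(
    beta: ClusterDictionary,
    gamma: ClusterDictionary,
    intensity_bins: int = 64,
    max_area: int | None = None,
    threshold: float = 1.0,
) -> LookupTable:
    """Build per-class probability histograms and their selectivity ratio.

    Area bins are unit-width integer bins up to ``max_area`` (default: the
    largest training area); intensity bins are ``intensity_bins`` equal-width
    bins spanning the pooled training range.
    """
    if len(beta) == 0 or len(gamma) == 0:
        raise ValueError("both cluster dictionaries must be non-empty")

    mi = np.concatenate([beta.mean_intensities, gamma.mean_intensities])
    areas = np.concatenate([beta.areas, gamma.areas])
    if max_area is None:
        max_area = int(areas.max())
    area_edges = np.arange(0.5, max_area + 1.5)
    lo, hi = float(mi.min()), float(mi.max())
    if hi <= lo:
        hi = lo + 1.0
    mi_edges = np.linspace(lo, hi, intensity_bins + 1)

    def hist(d: ClusterDictionary) -> np.ndarray:
        h, _, _ = np.histogram2d(
            np.clip(d.mean_intensities, lo, hi),
            np.clip(d.areas, 1, max_area),
            bins=(mi_edges, area_edges),
        )
        return h / len(d)

    beta_hist = hist(beta)
    gamma_hist = hist(gamma)
    selectivity = np.zeros_like(beta_hist)
    occupied = gamma_hist > 0
    selectivity[occupied] = beta_hist[occupied] / gamma_hist[occupied]
    selectivity[(~occupied) & (beta_hist > 0)] = np.inf
    return LookupTable(
        mean_intensity_edges=mi_edges,
        area_edges=area_edges,
        beta_hist=beta_hist,
        gamma_hist=gamma_hist,
        selectivity=selectivity,
        threshold=threshold,
    )


def _bin_index(value: float, edges: np.ndarray) -> int:
    """Bin index with clamping of out-of-range values to the edge bins."""
    idx = int(np.searchsorted(edges, value, side="right")) - 1
    return min(max(idx, 0), len(edges) - 2)


def classify_lut(
    table: LookupTable, cluster: Cluster
) -> tuple[float, str]:
    """Selectivity score and label for one cluster."""
    i = _bin_index(cluster.mean_intensity, table.mean_intensity_edges)
    j = _bin_index(float(cluster.area), table.area_edges)
    score = float(table.selectivity[i, j])
    return score, ("beta" if score > table.threshold else "gamma")


def score_dictionaries(
    table: LookupTable, beta: ClusterDictionary, gamma: ClusterDictionary
) -> ScoreSet:
    """Selectivity scores for labeled test dictionaries, ready for ROC."""
    pos = np.array([classify_lut(table, c)[0] for c in beta])
    neg = np.array([classify_lut(table, c)[0] for c in gamma])
    # +inf sentinels rank above every finite score; ROC code needs finite
    # values, so map them to one step above the largest finite selectivity.
    finite = np.concatenate([pos, neg])
    finite = finite[np.isfinite(finite)]
    cap = (finite.max() + 1.0) if finite.size else 1.0
    return ScoreSet(
        positives=np.where(np.isfinite(pos), pos, cap),
        negatives=np.where(np.isfinite(neg), neg, cap),
    )


class LookupTableClassifier:
    """Model object for the lookup-table discriminator.

    Parameters are the training dictionaries; ``fit`` produces a
    :class:`LookupTableResults` wrapping the fitted table.
    """

    def __init__(self, beta: ClusterDictionary, gamma: ClusterDictionary):
        self.beta = beta
        self.gamma = gamma

    def fit(
        self,
        intensity_bins: int = 64,
        max_area: int | None = None,
        threshold: float = 1.0,
    ) -> "LookupTableResults":
        table = fit_lookup(
            self.beta,
            self.gamma,
            intensity_bins=intensity_bins,
            max_area=max_area,
            threshold=threshold,
        )
        return LookupTableResults(self, table)


class LookupTableResults:
    def __init__(self, model: LookupTableClassifier, table: LookupTable):
        self.model = model
        self.table = table

    def predict(self, clusters: list[Cluster]) -> list[str]:
        return [classify_lut(self.table, c)[1] for c in clusters]

    def scores(
        self, beta: ClusterDictionary, gamma: ClusterDictionary
    ) -> ScoreSet:
        return score_dictionaries(self.table, beta, gamma)

    def summary(self) -> str:
        t = self.table
        occ = (t.beta_hist > 0) | (t.gamma_hist > 0)
        lines = [
            "Lookup-table discriminator (mean intensity x area)",
            f"  training clusters: beta={len(self.model.beta)}, "
            f"gamma={len(self.model.gamma)}",
            f"  grid: {t.beta_hist.shape[0]} intensity bins x "
            f"{t.beta_hist.shape[1]} area bins ({int(occ.sum())} occupied)",
            f"  beta-only bins (selectivity=+inf): "
            f"{int(np.isinf(t.selectivity).sum())}",
            f"  decision threshold on selectivity: {t.threshold}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path, group: str = "lookup_table") -> None:
        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.create_dataset("mean_intensity_edges", data=self.table.mean_intensity_edges)
            g.create_dataset("area_edges", data=self.table.area_edges)
            g.create_dataset("beta_hist", data=self.table.beta_hist)
            g.create_dataset("gamma_hist", data=self.table.gamma_hist)
            g.create_dataset("selectivity", data=self.table.selectivity)
            g.attrs["threshold"] = self.table.threshold


def load_table(path: str | Path, group: str = "lookup_table") -> LookupTable:
    with h5py.File(path, "r") as f:
        g = f[group]
        return LookupTable(
            mean_intensity_edges=g["mean_intensity_edges"][()],
            area_edges=g["area_edges"][()],
            beta_hist=g["beta_hist"][()],
            gamma_hist=g["gamma_hist"][()],
            selectivity=g["selectivity"][()],
            threshold=float(g.attrs["threshold"]),
        )
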