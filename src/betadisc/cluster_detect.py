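"""Event-cluster detection: connected-components labeling and dictionaries.

A particle depositing energy in the thin epitaxial layer spreads charge over
a small neighborhood of pixels.  After dark correction and thresholding,
each event appears as a connected group of foreground pixels.  Clusters are
found by 8-connectivity connected-components labeling of the binary frame
and cut out of the *corrected* frame, so their intensities retain the
deposited-energy information (area x mean intensity ~ total energy).

Labeled clusters from one radionuclide are collected into a
:class:`ClusterDictionary`, the training currency of every classifier here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

from .frames import Frame, FrameRole

#: 8-connectivity structuring element (edge or corner adjacency).
EIGHT_CONNECTIVITY = np.ones((3, 3), dtype=int)


@dataclass
class Cluster:
    """One detected event cluster.

    ``patch`` is the tight bounding-box crop from the corrected frame;
    ``mask`` marks member pixels within the crop.  ``area`` and
    ``mean_intensity`` are computed over member pixels only, so their
    product equals the summed deposited intensity.
    """

    patch: np.ndarray
    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (row0, col0, height, width)
    label: str = "unknown"
    source_id: str = ""
    on_border: bool = False

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.patch.shape != self.mask.shape:
            raise ValueError("patch and mask shapes differ")
        if not self.mask.any():
            raise ValueError("cluster mask has no member pixels")
        # tight crop: no all-zero border rows/cols in the mask
        rows = self.mask.any(axis=1)
        cols = self.mask.any(axis=0)
        if not (rows[0] and rows[-1] and cols[0] and cols[-1]):
            raise ValueError("mask does not fit its bounding box tightly")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def mean_intensity(self) -> float:
        return float(self.patch[self.mask].mean())

    @property
    def total_intensity(self) -> float:
        """Summed member-pixel intensity, proportional to deposited energy."""
        return float(self.patch[self.mask].sum())


@dataclass
class ClusterDictionary:
    """Labeled cluster collection from one source/radionuclide."""

    clusters: list[Cluster] = field(default_factory=list)
    label: str = "unknown"
    radionuclide: str = ""
    detection_threshold: float = float("nan")
    created_from: int = 0

    def __post_init__(self) -> None:
        labels = {c.label for c in self.clusters}
        if labels - {self.label}:
            raise ValueError(
                f"dictionary labeled {self.label!r} contains clusters "
                f"labeled {sorted(labels)}"
            )

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.clusters])

    @property
    def mean_intensities(self) -> np.ndarray:
        return np.array([c.mean_intensity for c in self.clusters])


def label_components(binary: Frame) -> tuple[np.ndarray, int]:
    """8-connectivity connected-components labeling of a binary frame.

    Returns the labeled array (background 0, components 1..n) and n.
    """
    if binary.role is not FrameRole.BINARY:
        raise ValueError("label_components expects a binary frame")
    labeled, n = ndimage.label(binary.pixels, structure=EIGHT_CONNECTIVITY)
    return labeled, int(n)


def extract_clusters(
    corrected: Frame,
    binary: Frame,
    label: str = "unknown",
    source_id: str = "",
) -> list[Cluster]:
    """Cut one Cluster per connected component out of the corrected frame."""
    if corrected.shape != binary.shape:
        raise ValueError(
            f"corrected shape {corrected.shape} != binary shape {binary.shape}"
        )
    labeled, n = label_components(binary)
    clusters: list[Cluster] = []
    H, W = corrected.shape
    for comp_id, sl in enumerate(ndimage.find_objects(labeled, n), start=1):
        if sl is None:  # pragma: no cover - find_objects contract
            continue
        mask = labeled[sl] == comp_id
        patch = corrected.pixels[sl].copy()
        r0, c0 = sl[0].start, sl[1].start
        h, w = mask.shape
        on_border = r0 == 0 or c0 == 0 or r0 + h == H or c0 + w == W
        clusters.append(
            Cluster(
                patch=patch,
                mask=mask,
                bbox=(r0, c0, h, w),
                label=label,
                source_id=source_id,
                on_border=on_border,
            )
        )
    return clusters


def build_dictionary(
    corrected_frames: list[Frame],
    binary_frames: list[Frame],
    label: str,
    radionuclide: str = "",
    detection_threshold: float = float("nan"),
) -> ClusterDictionary:
    """Concatenate extract_clusters over frames into one labeled dictionary."""
    if len(corrected_frames) < 1:
        raise ValueError("need at least one frame to build a dictionary")
    if len(corrected_frames) != len(binary_frames):
        raise ValueError("corrected and binary frame lists differ in length")
    clusters: list[Cluster] = []
    for i, (corr, binf) in enumerate(zip(corrected_frames, binary_frames)):
        clusters.extend(
            extract_clusters(corr, binf, label=label, source_id=f"frame{i}")
        )
    return ClusterDictionary(
        clusters=clusters,
        label=label,
        radionuclide=radionuclide,
        detection_threshold=detection_threshold,
        created_from=len(corrected_frames),
    )


# ---------------------------------------------------------------------------
# HDF5 persistence: one group per dictionary, one subgroup per cluster.

def save_dictionary(path: str | Path, d: ClusterDictionary, group: str = "dictionary") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.attrs["label"] = d.label
        g.attrs["radionuclide"] = d.radionuclide
        g.attrs["detection_threshold"] = d.detection_threshold
        g.attrs["created_from"] = d.created_from
        for i, c in enumerate(d.clusters):
            cg = g.create_group(f"cluster{i:06d}")
            cg.create_dataset("patch", data=c.patch)
            cg.create_dataset("mask", data=c.mask.astype(np.uint8))
            cg.attrs["bbox"] = c.bbox
            cg.attrs["area"] = c.area
            cg.attrs["mean_intensity"] = c.mean_intensity
            cg.attrs["source_id"] = c.source_id
            cg.attrs["on_border"] = c.on_border


def load_dictionary(path: str | Path, group: str = "dictionary") -> ClusterDictionary:
    with h5py.File(path, "r") as f:
        g = f[group]
        clusters = []
        for name in sorted(k for k in g if k.startswith("cluster")):
            cg = g[name]
            clusters.append(
                Cluster(
                    patch=cg["patch"][()],
                    mask=cg["mask"][()].astype(bool),
                    bbox=tuple(int(v) for v in cg.attrs["bbox"]),
                    label=str(g.attrs["label"]),
                    source_id=str(cg.attrs["source_id"]),
                    on_border=bool(cg.attrs["on_border"]),
                )
            )
        return ClusterDictionary(
            clusters=clusters,
            label=str(g.attrs["label"]),
            radionuclide=str(g.attrs["radionuclide"]),
            detection_threshold=float(g.attrs["detection_threshold"]),
            created_from=int(g.attrs["created_from"]),
        )
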