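"""Detector frames: dark-current correction and binarization.

A CMOS monolithic active pixel sensor reads out full 2D intensity frames
(sensor array outputs, SAOs).  Each pixel carries a dark-current baseline,
so acquisition starts with several blank frames whose per-pixel mean forms a
dark reference that is subtracted from every subsequent frame.  Events are
then isolated by thresholding the corrected frame into a binary image.

Conventions (fixed across the package): frames are row-major float arrays,
0-based (row, col) indexing; corrected frames are clamped at zero;
binarization uses a strict ``>`` comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class FrameRole(str, enum.Enum):
    """Acquisition role of a frame within the processing chain."""

    BLANK = "blank"
    RAW = "raw"
    CORRECTED = "corrected"
    BINARY = "binary"


@dataclass
class Frame:
    """A single detector frame.

    Parameters
    ----------
    pixels : ndarray
        2D intensity array in arbitrary detector units (ADU).
    role : FrameRole
        Where the frame sits in the chain (blank, raw, corrected, binary).
    """

    pixels: np.ndarray
    role: FrameRole = FrameRole.RAW

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"frame must be 2D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("frame must have height >= 1 and width >= 1")
        self.role = FrameRole(self.role)
        if self.role is FrameRole.BINARY:
            vals = np.unique(self.pixels)
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("binary frame must contain only {0, 1}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DarkReference:
    """Per-pixel mean of a stack of blank frames."""

    mean_dark: np.ndarray
    n_blank_frames: int = field(default=1)

    def __post_init__(self) -> None:
        self.mean_dark = np.asarray(self.mean_dark, dtype=np.float64)
        if self.n_blank_frames < 1:
            raise ValueError("n_blank_frames must be >= 1")


def build_dark_reference(blanks: list[Frame]) -> DarkReference:
    """Average blank frames into a dark reference.

    Raises ``ValueError`` on an empty list or a shape mismatch (the error
    names the first offending frame index).
    """
    if len(blanks) == 0:
        raise ValueError("cannot build a dark reference from zero blank frames")
    shape = blanks[0].shape
    for i, b in enumerate(blanks):
        if b.shape != shape:
            raise ValueError(
                f"blank frame {i} has shape {b.shape}, expected {shape}"
            )
    stack = np.stack([b.pixels for b in blanks])
    return DarkReference(mean_dark=stack.mean(axis=0), n_blank_frames=len(blanks))


def dark_correct(raw: Frame, dark: DarkReference) -> Frame:
    """Subtract the dark reference; negative residuals are clamped to 0.

    Clamping keeps corrected intensities nonnegative, which the downstream
    [0, 1] patch normalization assumes; sub-baseline excursions are noise.
    """
    if raw.shape != dark.mean_dark.shape:
        raise ValueError(
            f"raw frame shape {raw.shape} != dark reference shape "
            f"{dark.mean_dark.shape}"
        )
    corrected = np.maximum(raw.pixels - dark.mean_dark, 0.0)
    return Frame(corrected, FrameRole.CORRECTED)


def binarize(corrected: Frame, threshold: float) -> Frame:
    """Threshold a corrected frame: pixel = 1 iff intensity > threshold."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return Frame(
        (corrected.pixels > threshold).astype(np.float64), FrameRole.BINARY
    )


def estimate_threshold(corrected: Frame, k: float = 5.0) -> float:
    """Background-driven detection threshold: mu_bg + k * sigma_bg.

    The background statistics are estimated robustly (median and scaled
    median absolute deviation) so that bright event pixels do not inflate
    the estimate.  ``k = 5`` is the usual seed/noise separation for pixel
    detectors.
    """
    px = corrected.pixels.ravel()
    mu = float(np.median(px))
    sigma = 1.4826 * float(np.median(np.abs(px - mu)))
    if sigma == 0.0:
        # heavily clamped background: fall back to the plain std of the
        # sub-median pixels, and to a floor of 1 ADU
        sigma = float(px[px <= mu].std()) or 1.0
    return mu + k * sigma


def resolve_threshold(
    corrected: Frame,
    mode: str = "sigma",
    k: float = 5.0,
    value: float | None = None,
) -> float:
    """Resolve a config-style threshold spec to an absolute intensity.

    ``mode='sigma'`` estimates mu + k*sigma from the frame background;
    ``mode='absolute'`` uses ``value`` directly.
    """
    if mode == "sigma":
        return estimate_threshold(corrected, k=k)
    if mode == "absolute":
        if value is None or value <= 0:
            raise ValueError("absolute threshold mode requires a positive value")
        return float(value)
    raise ValueError(f"unknown threshold mode {mode!r}")


# ---------------------------------------------------------------------------
# Frame I/O: 16-bit grayscale TIFF / PNG, and NPY single-array containers.

def write_frame(path: str | Path, frame: Frame) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, frame.pixels)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, _to_uint16(frame.pixels))
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, _to_uint16(frame.pixels))
    else:
        raise ValueError(f"unsupported frame format {suffix!r}")


def read_frame(path: str | Path, role: FrameRole = FrameRole.RAW) -> Frame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        pixels = np.load(path)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        pixels = iio.imread(path)
    else:
        raise ValueError(f"unsupported frame format {suffix!r}")
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"{path} does not hold a single 2D grayscale image")
    return Frame(pixels.astype(np.float64), role)


def _to_uint16(pixels: np.ndarray) -> np.ndarray:
    clipped = np.clip(np.rint(pixels), 0, np.iinfo(np.uint16).max)
    return clipped.astype(np.uint16)
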