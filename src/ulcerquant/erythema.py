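"""Erythema segmentation, red-value histogramming, and relief maps.

Erythema (abnormal mucosal redness) is the visual marker of gastric
ulceration.  Because erythema expresses red, only the red channel is used
as the segmentation standard: tissue pixels whose red value reaches a
threshold are counted as erythematous, and the erythema fraction of the
tissue area feeds the ulcer index.  Near-white regions (specular glare,
gastric juice) and near-black regions (unlit background, shadow) are
masked out first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

from .imaging import RGBImage, ShieldColor, _CHANNEL_INDEX

__all__ = [
    "RedHistogram",
    "ErythemaResult",
    "ReliefMap",
    "tissue_mask",
    "red_histogram",
    "otsu_red_threshold",
    "segment_erythema",
    "detect_dark_spots",
    "relief_map",
]

DEFAULT_WHITE_CUTOFF = 240
DEFAULT_BLACK_CUTOFF = 20


@dataclass(frozen=True)
class RedHistogram:
    """Counts of masked pixels per red value 0-255."""

    counts: np.ndarray  # 256 ints
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError("histogram must have 256 bins")
        if counts.min() < 0 or counts.sum() != self.total:
            raise ValueError("histogram counts must be non-negative and sum to total")
        object.__setattr__(self, "counts", counts)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("bin,count\n")
            for v, c in enumerate(self.counts):
                fh.write(f"{v},{c}\n")


@dataclass(frozen=True)
class ErythemaResult:
    """Segmentation outcome for one image: mask, counts, and fraction."""

    mask: np.ndarray  # H x W bool, True = erythematous
    erythema_pixels: int
    tissue_pixels: int

    @property
    def erythema_fraction(self) -> float:
        return self.erythema_pixels / self.tissue_pixels

    def to_json(self) -> str:
        return json.dumps(
            {
                "erythema_pixels": int(self.erythema_pixels),
                "tissue_pixels": int(self.tissue_pixels),
                "erythema_fraction": self.erythema_fraction,
            }
        )

    def save_mask(self, path: str | Path) -> None:
        """Write the mask as a single-channel PNG (0 background, 255 lesion)."""
        import imageio.v3 as iio

        iio.imwrite(Path(path), (self.mask.astype(np.uint8)) * 255)


@dataclass(frozen=True)
class ReliefMap:
    """Color-density relief: per-pixel heights in [0, 1].

    Higher channel density maps to greater height, so exporting the array
    to any 3D viewer reproduces the relief rendering of a molecular imager.
    """

    heights: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.min() < 0 or h.max() > 1:
            raise ValueError("relief heights must lie in [0, 1]")
        object.__setattr__(self, "heights", h)


def tissue_mask(
    image: RGBImage,
    white_cutoff: int = DEFAULT_WHITE_CUTOFF,
    black_cutoff: int = DEFAULT_BLACK_CUTOFF,
) -> np.ndarray:
    """Boolean mask of analysable tissue.

    Excludes near-white pixels (min channel >= white_cutoff: glare or
    gastric juice) and near-black pixels (max channel <= black_cutoff:
    background or shadow).
    """
    if white_cutoff <= black_cutoff:
        raise ValueError("white_cutoff must exceed black_cutoff")
    px = image.pixels
    near_white = px.min(axis=2) >= white_cutoff
    near_black = px.max(axis=2) <= black_cutoff
    return ~(near_white | near_black)


def red_histogram(image: RGBImage, mask: np.ndarray) -> RedHistogram:
    """Histogram of red values over the masked pixels.

    The red value spans the x-axis (0-255) and the pixel count per value
    the y-axis; the sum of counts always equals the masked pixel count.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.pixels.shape[:2]:
        raise ValueError("mask shape does not match image")
    reds = image.red()[mask]
    counts = np.bincount(reds.ravel(), minlength=256)
    return RedHistogram(counts=counts, total=int(mask.sum()))


def otsu_red_threshold(image: RGBImage, tissue: np.ndarray) -> float:
    """Automatic red threshold: Otsu's method on the tissue red values.

    Used as the reproducible default when no clinician-chosen threshold is
    supplied.
    """
    reds = image.red()[np.asarray(tissue, dtype=bool)]
    if reds.size == 0:
        raise ValueError("tissue mask is empty")
    if np.ptp(reds) == 0:
        return float(reds[0])
    # threshold_otsu splits as (<= t | > t); segmentation here uses >=, so
    # shift half a level to place the cutoff between the two classes
    return float(threshold_otsu(reds)) + 0.5


def segment_erythema(
    image: RGBImage,
    red_threshold: float | None,
    tissue: np.ndarray,
) -> ErythemaResult:
    """Bisect the tissue into erythematous and normal zones.

    A tissue pixel is erythematous when its red value is >= red_threshold
    (Otsu-selected when None).  Raising the threshold never increases the
    erythema pixel count.
    """
    tissue = np.asarray(tissue, dtype=bool)
    if tissue.shape != image.pixels.shape[:2]:
        raise ValueError("tissue mask shape does not match image")
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty; erythema fraction undefined")
    if red_threshold is None:
        red_threshold = otsu_red_threshold(image, tissue)
    mask = tissue & (image.red() >= red_threshold)
    return ErythemaResult(
        mask=mask, erythema_pixels=int(mask.sum()), tissue_pixels=n_tissue
    )


def detect_dark_spots(
    image: RGBImage,
    tissue: np.ndarray,
    value_cutoff: float = 100,
) -> np.ndarray:
    """Detect dark spot lesions (stress-ulcer phenotype).

    Stress-induced ulcers present as dark low-value spots rather than red
    stripes, so the red-threshold criterion is inverted: a tissue pixel is
    flagged when its maximum channel value falls below ``value_cutoff``.
    The exact clinical criterion for this phenotype is less settled than
    the erythema rule; the cutoff is exposed for that reason.
    """
    tissue = np.asarray(tissue, dtype=bool)
    return tissue & (image.pixels.max(axis=2) < value_cutoff)


def relief_map(image: RGBImage, channel: ShieldColor) -> ReliefMap:
    """Color-density relief of one channel, normalised to [0, 1] heights."""
    c = _CHANNEL_INDEX[channel]
    return ReliefMap(heights=image.pixels[:, :, c].astype(float) / 255.0)
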