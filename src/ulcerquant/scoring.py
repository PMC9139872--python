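"""Ulcer-index normalisation, the clinical length/width rubric, and RGB-mean
severity classification.

Three scoring surfaces coexist:

* the ulcer index (UI): a sample's erythema fraction expressed relative to
  the untreated control group, whose mean is adjusted to 100%;
* the conventional clinical observation (CCO) rubric: per-lesion points
  from length bands (small round corrosion 1 pt; <1 mm 2 pts; 1-2 mm
  3 pts; 2-3 mm 4 pts; longer 5 pts), doubled when a lesion is wider than
  1 mm, summed over lesions;
* a nearest-centroid classifier on the image's mean RGB value against the
  three clinically judged class means (normal 247.964, mild 233.184,
  severe 206.857).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .imaging import RGBImage

__all__ = [
    "LesionMeasurement",
    "CCOScore",
    "UlcerIndexResult",
    "SeverityClass",
    "DEFAULT_CENTROIDS",
    "ulcer_index",
    "cco_score",
    "mean_rgb",
    "classify_rgb",
    "read_lesion_csv",
]

# Clinically judged class means of whole-image RGB averages.
DEFAULT_CENTROIDS: dict[str, float] = {
    "normal": 247.964,
    "mild": 233.184,
    "severe": 206.857,
}
_SEVERITY_ORDER = {"normal": 0, "mild": 1, "severe": 2}

GapPolicy = Literal["five_from_3", "four_to_4"]
DoublingScope = Literal["per_lesion", "total"]


@dataclass(frozen=True)
class LesionMeasurement:
    """One hemorrhagic corrosion: small round, or linear with caliper dims."""

    kind: Literal["small_round", "linear"]
    width: float  # mm
    length: float | None = None  # mm, linear lesions only

    def __post_init__(self) -> None:
        if self.kind not in ("small_round", "linear"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.width <= 0:
            raise ValueError("lesion width must be positive")
        if self.kind == "linear":
            if self.length is None or self.length <= 0:
                raise ValueError("linear lesions need a positive length")


@dataclass(frozen=True)
class CCOScore:
    per_lesion_points: tuple[int, ...]
    total: int


@dataclass(frozen=True)
class UlcerIndexResult:
    """UI in percent, normalised so the control-group mean is 100."""

    ui: float
    raw_fraction: float
    control_mean_fraction: float


@dataclass(frozen=True)
class SeverityClass:
    label: Literal["normal", "mild", "severe"]
    mean_rgb: float


def ulcer_index(
    sample_fraction: float, control_fractions: Sequence[float]
) -> UlcerIndexResult:
    """Normalise an erythema fraction against the control group.

    ui = 100 * sample_fraction / mean(control_fractions); a sample equal to
    the control mean scores exactly 100.
    """
    controls = np.asarray(control_fractions, dtype=float)
    if controls.size == 0:
        raise ValueError("control group is empty")
    cmean = float(controls.mean())
    if cmean <= 0:
        raise ZeroDivisionError("control mean fraction must be positive")
    return UlcerIndexResult(
        ui=100.0 * sample_fraction / cmean,
        raw_fraction=float(sample_fraction),
        control_mean_fraction=cmean,
    )


def _length_points(length: float, gap_policy: GapPolicy) -> int:
    """Points from the length bands.

    The published bands leave lengths in (3, 4] mm unassigned; the default
    policy extends the 5-point band down to >3 mm so the rubric is monotone
    and gap-free.  ``four_to_4`` instead extends the 4-point band up to
    4 mm, keeping the 5-point band literal (>4 mm).
    """
    if length < 1.0:
        return 2
    if length <= 2.0:
        return 3
    if gap_policy == "five_from_3":
        return 4 if length <= 3.0 else 5
    return 4 if length <= 4.0 else 5


def cco_score(
    lesions: Sequence[LesionMeasurement],
    gap_policy: GapPolicy = "five_from_3",
    doubling: DoublingScope = "per_lesion",
) -> CCOScore:
    """Apply the clinical length/width rubric to a lesion list.

    A small round corrosion scores 1 point; linear lesions score by length
    band.  With the default ``per_lesion`` doubling, a lesion wider than
    1 mm doubles its own points; ``total`` instead doubles the grand total
    when any lesion exceeds 1 mm width (the rubric sentence admits both
    readings).
    """
    points = []
    for lesion in lesions:
        p = 1 if lesion.kind == "small_round" else _length_points(lesion.length, gap_policy)
        if doubling == "per_lesion" and lesion.width > 1.0:
            p *= 2
        points.append(p)
    total = sum(points)
    if doubling == "total" and any(l.width > 1.0 for l in lesions):
        total *= 2
    return CCOScore(per_lesion_points=tuple(points), total=total)


def mean_rgb(
    image: RGBImage, mask: np.ndarray | None = None, red_only: bool = False
) -> float:
    """Mean channel value of the masked pixels.

    Default is the arithmetic mean over all three channels; ``red_only``
    averages the red channel alone (whether the clinical averages used all
    channels or red only is not settled).
    """
    if mask is None:
        mask = np.ones(image.pixels.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    px = image.pixels[mask].astype(float)
    if red_only:
        return float(px[:, 0].mean())
    return float(px.mean())


def classify_rgb(
    mean_value: float, centroids: dict[str, float] | None = None
) -> SeverityClass:
    """Nearest-centroid severity label for a mean RGB value.

    Ties between centroids break toward the more severe label.  With the
    default centroids the effective midpoint thresholds are 240.574
    (normal/mild) and 220.0205 (mild/severe).
    """
    if not (0.0 <= mean_value <= 255.0):
        raise ValueError("mean RGB value must lie in [0, 255]")
    cents = DEFAULT_CENTROIDS if centroids is None else centroids
    dists = {label: abs(mean_value - c) for label, c in cents.items()}
    best = min(dists.values())
    # exact midpoints are ties up to floating rounding; break toward severity
    tied = [label for label, d in dists.items() if d - best <= 1e-9]
    label = max(tied, key=lambda l: _SEVERITY_ORDER[l])
    return SeverityClass(label=label, mean_rgb=float(mean_value))


def read_lesion_csv(path: str | Path) -> list[LesionMeasurement]:
    """Read lesions from CSV with columns kind, length_mm, width_mm."""
    df = pd.read_csv(path)
    lesions = []
    for _, row in df.iterrows():
        length = row.get("length_mm")
        lesions.append(
            LesionMeasurement(
                kind=row["kind"],
                width=float(row["width_mm"]),
                length=None if pd.isna(length) else float(length),
            )
        )
    return lesions
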