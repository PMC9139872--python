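"""Blood-dilution erythema standard: series, linear fit, inverse prediction.

Erythema severity is anchored to a physical standard: whole blood serially
diluted two-fold in saline (50%, 25%, 12.5%, 6.25%, 3.125%, plus a 0%
blank) photographed in a 6-well plate.  A color response measured on each
well is regressed on blood concentration; the fitted line converts a
measured tissue response back to a blood-concentration equivalent, which
is clamped to the 0-80% working range and binned into severity classes
(>= 60% is the severe zone).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DilutionSeries",
    "CalibrationCurve",
    "SeverityBin",
    "dilution_series",
    "fit_standard",
    "predict_concentration",
    "bin_severity",
    "read_standard_csv",
]

MAX_CONCENTRATION = 0.8  # upper edge of the 0-80% severity range
SEVERE_CUTOFF = 0.60
BIN_WIDTH = 0.10


@dataclass(frozen=True)
class DilutionSeries:
    """A two-fold serial dilution plus terminal 0 blank."""

    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.concentrations)
        if len(c) < 2 or c[-1] != 0.0:
            raise ValueError("series must end with a 0 blank")
        body = c[:-1]
        for prev, nxt in zip(body, body[1:]):
            if not math.isclose(nxt, prev / 2.0, rel_tol=1e-12):
                raise ValueError("non-blank entries must halve at each step")
        object.__setattr__(self, "concentrations", c)

    def __iter__(self):
        return iter(self.concentrations)

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line (response = slope * concentration + intercept) with R^2."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 3:
            raise ValueError("a standard curve needs at least 3 points")

    def response_at(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
                "n_points": self.n_points,
            }
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


@dataclass(frozen=True)
class SeverityBin:
    """One 10%-wide blood-concentration bin of the 0-80% range."""

    lower: float
    upper: float
    severe_flag: bool


def dilution_series(start: float = 0.50, steps: int = 5) -> DilutionSeries:
    """Serial two-fold dilution from ``start`` over ``steps`` halvings + blank.

    dilution_series(0.50, 5) reproduces the standard plate:
    [0.50, 0.25, 0.125, 0.0625, 0.03125, 0].
    """
    if not (0.0 < start <= 1.0):
        raise ValueError("start concentration must lie in (0, 1]")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    body = [start / 2**k for k in range(steps)]
    return DilutionSeries(tuple(body + [0.0]))


def fit_standard(
    concentrations: Sequence[float], responses: Sequence[float]
) -> CalibrationCurve:
    """Ordinary-least-squares fit of response on concentration.

    Closed-form slope/intercept from the centered covariance; R^2 is
    1 - SS_res/SS_tot.  Flat responses (SS_tot = 0) fit a horizontal line
    with R^2 defined as 0.  Identical concentrations cannot be fitted.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(x) == 0:
        raise ValueError("all concentrations identical; fit is degenerate")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = float(np.sum((y - ym) ** 2))
    if ss_tot == 0.0:
        return CalibrationCurve(slope=0.0, intercept=ym, r_squared=0.0, n_points=n)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    # floating rounding can push a perfect fit a hair past the bounds
    r2 = min(max(r2, 0.0), 1.0)
    return CalibrationCurve(slope=slope, intercept=intercept, r_squared=r2, n_points=n)


def predict_concentration(curve: CalibrationCurve, response: float) -> float:
    """Invert the standard curve: x = (y - intercept) / slope.

    Predictions are clamped into the [0, 0.8] working range since the
    line is applied to whole photographs where extreme responses occur.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("cannot invert a zero-slope curve")
    x = (response - curve.intercept) / curve.slope
    return min(max(x, 0.0), MAX_CONCENTRATION)


def bin_severity(concentration: float) -> SeverityBin:
    """Assign a clamped blood-concentration equivalent to its severity bin.

    Eight 10%-wide bins tile [0, 0.8]; a concentration at or above the 60%
    balance point is flagged severe.
    """
    if not (0.0 <= concentration <= MAX_CONCENTRATION):
        raise ValueError("concentration must be pre-clamped to [0, 0.8]")
    # guard against 0.6/0.1 -> 5.999... under binary floating point
    idx = min(int(math.floor(concentration / BIN_WIDTH + 1e-9)), 7)
    lower = idx * BIN_WIDTH
    upper = lower + BIN_WIDTH
    return SeverityBin(
        lower=round(lower, 10),
        upper=round(upper, 10),
        severe_flag=concentration >= SEVERE_CUTOFF,
    )


def read_standard_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a standard table with ``concentration`` and ``response`` columns."""
    df = pd.read_csv(path)
    missing = {"concentration", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"standard CSV missing columns: {sorted(missing)}")
    return df["concentration"].to_numpy(float), df["response"].to_numpy(float)
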