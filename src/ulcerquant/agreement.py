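"""Multi-rater agreement: per-subject SD panels and Bland-Altman analysis.

A panel of trained raters scores each subject with two methods (manual
rubric vs image analysis).  Reproducibility is summarised two ways: the
sample SD across raters for each subject, and a Bland-Altman comparison of
paired method scores — bias (mean difference) with limits of agreement at
bias +/- 1.96 SD of the differences, expected to contain ~95% of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RaterPanel",
    "BlandAltmanResult",
    "rater_sd",
    "bland_altman",
    "plot_bland_altman",
    "read_panel_csv",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class RaterPanel:
    """Subjects x raters matrix of ulcer-index scores, no missing cells."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] < 1 or s.shape[1] < 2:
            raise ValueError("panel must be subjects x raters with >= 2 raters")
        if np.isnan(s).any():
            raise ValueError("panel has missing cells")
        if (s < 0).any():
            raise ValueError("scores must be non-negative")
        object.__setattr__(self, "scores", s)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]

    def subject_means(self) -> np.ndarray:
        return self.scores.mean(axis=1)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pairs: int
    means: np.ndarray  # per-pair (a+b)/2, for plotting
    diffs: np.ndarray  # per-pair a-b

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pairs": self.pairs,
        }


def rater_sd(panel: RaterPanel) -> np.ndarray:
    """Per-subject sample SD (n-1 denominator) across raters."""
    return panel.scores.std(axis=1, ddof=1)


def bland_altman(
    method_a: Sequence[float], method_b: Sequence[float]
) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired scoring methods.

    Differences are a - b; bias is their mean and the limits of agreement
    are bias +/- 1.96 * SD(differences) (sample SD).  Swapping the methods
    flips the sign of the bias and leaves sd_diff unchanged.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("methods must be equal-length 1-D paired values")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        pairs=a.size,
        means=(a + b) / 2.0,
        diffs=diffs,
    )


def plot_bland_altman(result: BlandAltmanResult, path: str | Path) -> None:
    """Scatter of differences vs means with bias and LoA reference lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(result.bias, color="tab:blue", label=f"bias = {result.bias:.2f}")
    for y, lbl in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="tab:red", linestyle="--", label=f"{lbl} = {y:.2f}")
    ax.set_xlabel("Mean of methods")
    ax.set_ylabel("Difference (A - B)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_panel_csv(path: str | Path) -> dict[str, RaterPanel]:
    """Read long-format panels: columns subject_id, rater_id, method, score.

    Returns one RaterPanel per method, subjects and raters sorted for
    determinism.
    """
    df = pd.read_csv(path)
    needed = {"subject_id", "rater_id", "method", "score"}
    if missing := needed - set(df.columns):
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    panels = {}
    for method, grp in df.groupby("method"):
        wide = grp.pivot(index="subject_id", columns="rater_id", values="score")
        wide = wide.sort_index().sort_index(axis=1)
        panels[str(method)] = RaterPanel(wide.to_numpy(float))
    return panels
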