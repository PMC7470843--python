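"""Quantitative descriptors of SPB structure and label distribution.

The asymmetry index of a spindle is |a - b| / (a + b) over the label
intensities (optionally reference-normalised) at its two SPBs: 0 is
absolute symmetry, 1 all label at one pole.  Label distribution modes are
classified from the fold-difference between SPBs: at least 8-fold is
"strongly asymmetric", between 8- and 1.3-fold "asymmetric", under 1.3-fold
"symmetric", and label detectable at only one outer plaque is "one pole".
Cell-cycle stages are assigned from SPB inter-distances with boundaries at
0.35, 1 and 2.5 um.  Distributions are summarised by the 5/25/50/75/95th
centiles with a median notch (median +/- 1.58 * IQR / sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .spotfit import SpotFit

__all__ = [
    "PlaqueMeasurement", "AsymmetryRecord", "StageLabel", "asymmetry_index",
    "ip_op_ratio", "classify_mode", "stage_by_distance", "is_top_view",
    "summarize_distribution", "MODES", "STAGE_LABELS", "UndefinedIndexError",
    "NoLabelError",
]

MODES = ("one_pole", "strongly_asymmetric", "asymmetric", "symmetric")
STAGE_LABELS = ("unseparated", "spindle_lt_1um", "spindle_1_2p5um",
                "elongated_gt_2p5um")

#: Fold-ratio boundaries of the mode classifier.
STRONG_FOLD = 8.0
SYM_FOLD = 1.3

#: Inter-distance boundaries (um) of the staging rule.
STAGE_BOUNDARIES_UM = (0.35, 1.0, 2.5)


class UndefinedIndexError(ValueError):
    """Raised when the asymmetry index is undefined (a + b == 0)."""


class NoLabelError(ValueError):
    """Raised when neither SPB carries detectable label."""


@dataclass
class PlaqueMeasurement:
    """Per-SPB inner- and outer-plaque intensities and their ratio."""

    ip_intensity: float
    op_intensity: float
    spb_identity: str  # 'old' | 'new'
    ip_op_ratio: Optional[float] = None
    one_sided: bool = False

    def __post_init__(self) -> None:
        if self.ip_intensity < 0 or self.op_intensity < 0:
            raise ValueError("plaque intensities must be >= 0")
        if self.op_intensity > 0:
            self.ip_op_ratio = self.ip_intensity / self.op_intensity
        else:
            self.ip_op_ratio = None
            self.one_sided = True


@dataclass
class AsymmetryRecord:
    """Asymmetry index with its classification mode and measurement basis."""

    index: float
    mode: Optional[str]
    basis: str  # 'sim_raw' | 'widefield_ref_normalized'

    def __post_init__(self) -> None:
        if not 0.0 <= self.index <= 1.0:
            raise ValueError("asymmetry index must lie in [0, 1]")
        if self.mode is not None and self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class StageLabel:
    label: str
    inter_distance: float  # um


def asymmetry_index(a: float, b: float) -> float:
    """|a - b| / (a + b): 0 = absolute symmetry, 1 = absolute asymmetry."""
    if a < 0 or b < 0:
        raise ValueError("intensities must be >= 0")
    total = a + b
    if total == 0:
        raise UndefinedIndexError("asymmetry index undefined for a + b == 0")
    return abs(a - b) / total


def ip_op_ratio(meas: PlaqueMeasurement) -> Optional[float]:
    """Inner:outer plaque intensity ratio; None when the SPB is one-sided
    (no outer-plaque signal)."""
    return meas.ip_op_ratio


def classify_mode(i_old: float, i_new: float, detect_floor: float) -> str:
    """Classify the label distribution between the two SPBs.

    ``one_pole`` when only one SPB carries detectable label; otherwise, with
    r = max/min: ``strongly_asymmetric`` for r >= 8, ``symmetric`` for
    r < 1.3, ``asymmetric`` in between.
    """
    if i_old < 0 or i_new < 0 or detect_floor < 0:
        raise ValueError("intensities and floor must be >= 0")
    hi, lo = max(i_old, i_new), min(i_old, i_new)
    if hi < detect_floor:
        raise NoLabelError("no label detectable at either SPB")
    if lo < detect_floor:
        return "one_pole"
    r = hi / lo if lo > 0 else np.inf
    if r >= STRONG_FOLD:
        return "strongly_asymmetric"
    if r < SYM_FOLD:
        return "symmetric"
    return "asymmetric"


def stage_by_distance(d_um: float) -> StageLabel:
    """Assign a cell-cycle stage from the SPB inter-distance (um).

    Boundaries: < 0.35 unseparated; 0.35 <= d < 1 short spindle; 1 <= d
    <= 2.5 medium spindle; > 2.5 elongated.  Interior boundaries are
    assigned rightward (d = 0.35 -> short spindle) so the partition of
    [0, inf) is exact.
    """
    if d_um < 0:
        raise ValueError("inter-distance must be >= 0")
    b1, b2, b3 = STAGE_BOUNDARIES_UM
    if d_um < b1:
        label = "unseparated"
    elif d_um < b2:
        label = "spindle_lt_1um"
    elif d_um <= b3:
        label = "spindle_1_2p5um"
    else:
        label = "elongated_gt_2p5um"
    return StageLabel(label=label, inter_distance=float(d_um))


def is_top_view(fit_inner: SpotFit, fit_outer: SpotFit,
                sigma_xy: float, overlap_factor: float = 2.0) -> bool:
    """True when the inner- and outer-plaque signals overlap laterally
    (xy distance < overlap_factor * sigma_xy) while their axial separation
    dominates — the plaque axis points along the optical axis."""
    delta = fit_outer.center - fit_inner.center
    lateral = float(np.hypot(delta[0], delta[1]))
    axial = abs(float(delta[2]))
    return lateral < overlap_factor * sigma_xy and axial >= lateral


def summarize_distribution(values: Sequence[float]) -> dict:
    """Boxplot-style summary: 5/25/50/75/95th centiles (linear interpolation
    of order statistics) plus the median notch interval
    median +/- 1.58 * IQR / sqrt(n)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    c5, c25, c50, c75, c95 = np.percentile(v, [5, 25, 50, 75, 95])
    iqr = c75 - c25
    half_notch = 1.58 * iqr / np.sqrt(v.size)
    return {
        "n": int(v.size),
        "p5": float(c5), "p25": float(c25), "median": float(c50),
        "p75": float(c75), "p95": float(c95),
        "notch_low": float(c50 - half_notch),
        "notch_high": float(c50 + half_notch),
    }
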