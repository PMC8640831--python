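"""Liver volumetry from per-slice ROI areas and measurement-error-aware
classification of volume change across reproductive stages.

Volume is the slice-summation estimate: the ROI area on each axial slice
times the fixed inter-slice interval, summed over slices. Change between
visits is classified gain / no-change / loss against a symmetric percent
tolerance whose default (7%) is the interoperator measurement-error band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SliceROISeries",
    "ChangePattern",
    "compute_liver_volume",
    "percent_change",
    "interoperator_variability",
    "classify_change",
    "classify_pattern",
    "eliminate_station_overlap",
    "DEFAULT_TOLERANCE_PCT",
]

#: symmetric no-change band, percent; from the interoperator benchmark
DEFAULT_TOLERANCE_PCT = 7.0

Change = Literal["gain", "no-change", "loss"]

STAGES = ("early", "late", "postwean")


@dataclass
class SliceROISeries:
    """Ordered per-slice liver ROI areas (cm2) at a fixed interval (cm)."""

    areas: np.ndarray
    interval_cm: float
    stage: str | None = None

    def __post_init__(self) -> None:
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=np.float64))
        if self.areas.ndim != 1 or self.areas.size < 1:
            raise ValueError("areas must be a 1D sequence with >= 1 slice")
        if np.any(self.areas < 0) or not np.all(np.isfinite(self.areas)):
            raise ValueError("areas must be finite and nonnegative")
        if self.interval_cm <= 0:
            raise ValueError(f"interval must be positive, got {self.interval_cm}")
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")

    def __len__(self) -> int:
        return self.areas.size


@dataclass(frozen=True)
class ChangePattern:
    """Joint pregnancy/postwean classification of one participant."""

    pregnancy_change: Change
    postwean_change: Change | None
    label: str  # "gain-loss" | "not gain-loss" | "undefined"
    subtype: str

    @property
    def is_gain_loss(self) -> bool:
        return self.label == "gain-loss"


def compute_liver_volume(series: SliceROISeries) -> float:
    """Slice-summation liver volume in cm3: sum(area_i) * interval."""
    return float(np.sum(series.areas) * series.interval_cm)


def percent_change(v_ref: float, v_new: float) -> float:
    """Percent change of ``v_new`` relative to ``v_ref`` (the denominator)."""
    if v_ref <= 0:
        raise ValueError(f"reference volume must be positive, got {v_ref}")
    return 100.0 * (v_new - v_ref) / v_ref


def interoperator_variability(
    op_a: Sequence[float], op_b: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Per-case percent differences between two operators and their range.

    The percent difference uses the pair mean as denominator, making the
    statistic symmetric in the operators; the range is the maximum absolute
    difference, defining a symmetric +/- measurement-error band.
    """
    a = np.asarray(op_a, dtype=np.float64)
    b = np.asarray(op_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("operators must supply paired 1D volume lists of equal length")
    means = (a + b) / 2.0
    if np.any(means <= 0):
        raise ValueError("pair means must be positive")
    diffs = 100.0 * (a - b) / means
    return diffs, float(np.max(np.abs(diffs)))


def classify_change(
    v_before: float, v_after: float, tolerance_pct: float = DEFAULT_TOLERANCE_PCT
) -> Change:
    """gain / no-change / loss against the symmetric percent tolerance."""
    if tolerance_pct < 0:
        raise ValueError("tolerance must be nonnegative")
    pct = percent_change(v_before, v_after)
    if pct > tolerance_pct:
        return "gain"
    if pct < -tolerance_pct:
        return "loss"
    return "no-change"


_SUBTYPES = {
    ("gain", "loss"): "gain-loss",
    ("loss", "gain"): "loss-gain",
    ("no-change", "no-change"): "no-change",
    ("gain", "gain"): "continuous-gain",
    ("loss", "loss"): "continuous-loss",
}


def classify_pattern(
    early: float,
    late: float,
    postwean: float | None,
    tolerance_pct: float = DEFAULT_TOLERANCE_PCT,
) -> ChangePattern:
    """Two-visit-change pattern: gain-loss iff pregnancy gain AND postwean loss.

    Pregnancy change is judged against the early-visit volume, postwean
    change against the late-visit volume. A missing postwean volume leaves
    the pattern undefined (flagged, not an error).
    """
    preg = classify_change(early, late, tolerance_pct)
    if postwean is None or (isinstance(postwean, float) and np.isnan(postwean)):
        return ChangePattern(preg, None, "undefined", "missing-postwean")
    post = classify_change(late, postwean, tolerance_pct)
    subtype = _SUBTYPES.get((preg, post), "other")
    label = "gain-loss" if subtype == "gain-loss" else "not gain-loss"
    return ChangePattern(preg, post, label, subtype)


def eliminate_station_overlap(
    stack_upper: SliceROISeries, stack_lower: SliceROISeries, overlap_slices: int
) -> SliceROISeries:
    """Merge two scan stations, dropping duplicated overlap slices.

    Overlapping slices are kept from the upper (liver-centered) station;
    the first ``overlap_slices`` slices of the lower station are dropped.
    """
    if overlap_slices < 0:
        raise ValueError("overlap must be nonnegative")
    if overlap_slices >= len(stack_upper) or overlap_slices >= len(stack_lower):
        raise ValueError(
            f"overlap of {overlap_slices} slices is not smaller than both stacks "
            f"({len(stack_upper)}, {len(stack_lower)})"
        )
    if not np.isclose(stack_upper.interval_cm, stack_lower.interval_cm):
        raise ValueError("stations must share the inter-slice interval")
    merged = np.concatenate([stack_upper.areas, stack_lower.areas[overlap_slices:]])
    return SliceROISeries(merged, stack_upper.interval_cm, stack_upper.stage)
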