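"""Region-fraction segmentation metrics.

The confusion "rates" here are area fractions, not pixel counts. In the
default fractional mode the misses are normalized by the ground-truth disc
area and the false alarms by the background-minus-disc area, so TP + FN = 1
and TN + FP = 1 for every mask pair:

    TP = 1 - |OA \\ SA| / OA          FN = |OA \\ SA| / OA
    FP = |SA \\ OA| / (BA - OA)       TN = 1 - FP

with SA the segmented disc region, OA the ground-truth disc region and
BA the background area (total - OA). Accuracy, Dice and the overlap error E
are then

    Acc  = (TN + TP) / (TN + FN + FP + TP)
    Dice = 2 TP / (2 TP + FP + FN)
    E    = 1 - TP / (TP + FP + FN)

Two alternative modes are provided: ``strict-scalar`` applies the same
formulas to scalar area differences (so a disjoint equal-area prediction
scores TP = 1 — kept only for literal comparability), and ``pixelwise`` is
the standard pixel-count confusion matrix normalized by the image size.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionAreas",
    "MetricsReport",
    "region_areas",
    "fractional_confusion",
    "accuracy",
    "dice",
    "overlap_error",
    "evaluate_masks",
    "cumulative_error_report",
]

MODES = ("fractional", "strict-scalar", "pixelwise")


@dataclass(frozen=True)
class RegionAreas:
    """Pixel counts of the regions entering the metrics."""

    sa: int  # segmented disc area
    oa: int  # ground-truth disc area
    ba: int  # background area (total - oa)
    overlap: int  # |SA intersect OA|

    def __post_init__(self) -> None:
        if min(self.sa, self.oa, self.ba, self.overlap) < 0:
            raise ValueError("areas must be non-negative")
        if self.overlap > min(self.sa, self.oa):
            raise ValueError("overlap cannot exceed either region's area")


@dataclass(frozen=True)
class MetricsReport:
    tp: float
    fp: float
    tn: float
    fn: float
    acc: float
    dice: float
    error: float
    mode: str

    def to_dict(self) -> dict:
        return asdict(self)


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))) and not np.all(np.isin(vals, (0, 255))):
            raise ValueError(f"{name} is not binary (values {vals[:5]}...)")
        m = m > 0
    return m


def region_areas(pred_mask: np.ndarray, truth_mask: np.ndarray) -> RegionAreas:
    """Count the region areas of a predicted/ground-truth mask pair."""
    pred = _as_binary(pred_mask, "pred_mask")
    truth = _as_binary(truth_mask, "truth_mask")
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    sa = int(pred.sum())
    oa = int(truth.sum())
    return RegionAreas(sa=sa, oa=oa, ba=pred.size - oa, overlap=int((pred & truth).sum()))


def fractional_confusion(
    areas: RegionAreas, mode: str = "fractional"
) -> tuple[float, float, float, float]:
    """(TP, FP, TN, FN) as area fractions. See the module docstring."""
    if mode not in ("fractional", "strict-scalar"):
        raise ValueError(f"mode must be 'fractional' or 'strict-scalar', got {mode!r}")
    if areas.oa == 0:
        raise ValueError("ground truth contains no disc pixels (OA = 0)")
    denom_bg = areas.ba - areas.oa
    if denom_bg <= 0:
        raise ValueError("background area does not exceed the disc area")
    if mode == "fractional":
        miss = areas.oa - areas.overlap  # |OA \ SA|
        excess = areas.sa - areas.overlap  # |SA \ OA|
    else:  # strict scalar-area differences, exactly as printed
        miss = max(areas.oa - areas.sa, 0)
        excess = max(areas.sa - areas.oa, 0)
    fn = miss / areas.oa
    tp = 1.0 - fn
    fp = excess / denom_bg
    tn = 1.0 - fp
    return tp, fp, tn, fn


def accuracy(tp: float, fp: float, tn: float, fn: float) -> float:
    total = tn + fn + fp + tp
    return (tn + tp) / total if total > 0 else 0.0


def dice(tp: float, fp: float, fn: float) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def overlap_error(tp: float, fp: float, fn: float) -> float:
    denom = tp + fp + fn
    return 1.0 - tp / denom if denom > 0 else 1.0


def evaluate_masks(
    pred_mask: np.ndarray, truth_mask: np.ndarray, mode: str = "fractional"
) -> MetricsReport:
    """Full metrics report for one mask pair."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    areas = region_areas(pred_mask, truth_mask)
    if mode == "pixelwise":
        total = areas.oa + areas.ba
        tp = areas.overlap / total
        fp = (areas.sa - areas.overlap) / total
        fn = (areas.oa - areas.overlap) / total
        tn = 1.0 - tp - fp - fn
    else:
        tp, fp, tn, fn = fractional_confusion(areas, mode=mode)
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        acc=accuracy(tp, fp, tn, fn),
        dice=dice(tp, fp, fn),
        error=overlap_error(tp, fp, fn),
        mode=mode,
    )


def cumulative_error_report(
    errors: Sequence[float] | Iterable[float],
    accs: Sequence[float] | None = None,
    dices: Sequence[float] | None = None,
    thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """One-row summary: fraction of images with E <= tau per threshold plus
    mean E (and mean Acc/Dice when given). Fractions are in [0, 1] and
    non-decreasing in tau."""
    e = np.asarray(list(errors), dtype=np.float64)
    if e.size == 0:
        raise ValueError("cumulative report needs at least one per-image error")
    row: dict[str, float] = {f"E<={tau:g}": float(np.mean(e <= tau)) for tau in thresholds}
    row["mean_E"] = float(e.mean())
    if accs is not None:
        row["mean_Acc"] = float(np.mean(np.asarray(list(accs))))
    if dices is not None:
        row["mean_Dice"] = float(np.mean(np.asarray(list(dices))))
    return pd.DataFrame([row])
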