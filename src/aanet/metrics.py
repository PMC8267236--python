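"""Evaluation indexes over the nested tumor regions.

Four per-region indexes: Dice coefficient ``2TP / (2TP + FP + FN)``,
precision ``TP / (TP + FP)``, sensitivity ``TP / (TP + FN)``, and the
symmetric Hausdorff distance between mask boundaries in pixel units.

Degenerate-denominator conventions (tumor-free slices): when prediction and
truth are both empty the slice is scored perfect (Dice, precision,
sensitivity = 1; Hausdorff = 0); when exactly one mask is empty the overlap
indexes fall out of the formulas (0) and the Hausdorff distance is a
configurable sentinel, by default the image diagonal.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .brats_io import RegionTargets

REGIONS = ("wt", "ct", "et")
INDEXES = ("dice", "precision", "sensitivity", "hausdorff")

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def dice_coefficient(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2.0 * c.tp / denom


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        return 1.0 if c.fn == 0 else 0.0
    return c.tp / (c.tp + c.fp)


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / (c.tp + c.fn)


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbor."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=1)
    return mask & ~eroded


def hausdorff_distance(pred: np.ndarray, truth: np.ndarray,
                       empty_sentinel: Optional[float] = None) -> float:
    """Symmetric Hausdorff distance between the two masks' boundaries."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p_empty, t_empty = not pred.any(), not truth.any()
    if p_empty and t_empty:
        return 0.0
    if p_empty or t_empty:
        if empty_sentinel is None:
            empty_sentinel = float(np.hypot(*pred.shape))
        return float(empty_sentinel)
    a = np.argwhere(mask_boundary(pred)).astype(float)
    b = np.argwhere(mask_boundary(truth)).astype(float)
    return float(max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0]))


def region_metrics(pred: RegionTargets, truth: RegionTargets) -> Dict[str, Dict[str, float]]:
    """All four indexes for one slice, keyed region -> index."""
    out = {}
    for region in REGIONS:
        p, t = getattr(pred, region), getattr(truth, region)
        c = confusion_counts(p, t)
        out[region] = {
            "dice": dice_coefficient(c),
            "precision": precision(c),
            "sensitivity": sensitivity(c),
            "hausdorff": hausdorff_distance(p, t),
        }
    return out


@dataclasses.dataclass
class RegionReport:
    """Dataset-level metric table: mean per-slice value per region and index."""

    table: pd.DataFrame  # rows = REGIONS, columns = INDEXES
    n_slices: int

    def mean_over_regions(self) -> pd.Series:
        return self.table.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        frame = self.table.copy()
        frame.loc["mean"] = self.mean_over_regions()
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def __str__(self) -> str:
        return self.to_frame().to_string(float_format=lambda v: f"{v:.4f}")


def evaluate(preds: Sequence[RegionTargets],
             truths: Sequence[RegionTargets]) -> RegionReport:
    """Per-slice metrics averaged over an aligned dataset."""
    if len(preds) != len(truths):
        raise ValueError(f"got {len(preds)} predictions vs {len(truths)} truths")
    if not preds:
        raise ValueError("cannot evaluate an empty dataset")
    acc = np.zeros((len(REGIONS), len(INDEXES)))
    for p, t in zip(preds, truths):
        m = region_metrics(p, t)
        for i, region in enumerate(REGIONS):
            acc[i] += [m[region][idx] for idx in INDEXES]
    table = pd.DataFrame(acc / len(preds), index=list(REGIONS),
                         columns=list(INDEXES))
    return RegionReport(table=table, n_slices=len(preds))
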