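"""Soft dice training loss and evaluation metrics (DSC, Hausdorff distance).

The Hausdorff distance is computed over foreground pixel-centre coordinates
scaled by the physical pixel spacing (mm), using the symmetric
max-of-directed form.  Empty masks make it undefined: such cases carry a
marker and are excluded from aggregate means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .nn import functional as F
from .nn.autograd import Tensor

__all__ = [
    "BinaryMask", "MetricsReport", "soft_dice_loss", "dsc",
    "hausdorff", "evaluate_dataset",
]


@dataclass
class BinaryMask:
    """A 2-D {0,1} mask with physical pixel spacing in mm (row, col)."""

    values: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask must contain only 0/1, found values {uniq[:5]}")
        if self.values.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.values.shape}")
        if min(self.spacing) <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def foreground_fraction(self) -> float:
        return float(self.values.mean())

    def points_mm(self) -> np.ndarray:
        """Foreground pixel-centre coordinates scaled to mm, shape (n, 2)."""
        pts = np.argwhere(self.values > 0).astype(np.float64)
        pts[:, 0] *= self.spacing[0]
        pts[:, 1] *= self.spacing[1]
        return pts


def _as_mask_array(m) -> np.ndarray:
    if isinstance(m, BinaryMask):
        return m.values
    return np.asarray(m)


def soft_dice_loss(pred, target, smooth: float = 1.0):
    """Soft dice loss ``1 - (2*sum(p*t)+s) / (sum(p^2)+sum(t^2)+s)``.

    Sums run over all pixels of each sample; for batched 4-D inputs the
    per-sample losses are averaged.  Accepts an autograd :class:`Tensor`
    prediction (returns a differentiable scalar Tensor) or plain arrays
    (returns a float).
    """
    if smooth <= 0:
        raise ValueError(f"smooth must be positive, got {smooth}")
    differentiable = isinstance(pred, Tensor)
    t = np.asarray(target.values if isinstance(target, BinaryMask) else target,
                   dtype=np.float32)
    pdata = pred.data if differentiable else np.asarray(pred, dtype=np.float32)
    if pdata.shape != t.shape:
        raise ValueError(f"pred shape {pdata.shape} != target shape {t.shape}")
    if pdata.min() < 0 or pdata.max() > 1:
        raise ValueError("pred must be a probability map in [0, 1]")
    if pdata.ndim < 4:  # single sample: promote to a 1-item batch
        orig, orig_shape = pred, pdata.shape
        pdata = pdata.reshape((1,) + pdata.shape)
        t = t.reshape((1,) + t.shape)
        if differentiable:
            pred = Tensor._make(
                pdata, (orig,),
                lambda g: orig.accumulate_grad(g.reshape(orig_shape)),
            )
    axes = tuple(range(1, pdata.ndim))
    if differentiable:
        tt = Tensor(t)
        inter = F.sum_tensor(F.mul(pred, tt), axis=axes)
        denom = F.add(F.sum_tensor(F.mul(pred, pred), axis=axes),
                      F.sum_tensor(F.mul(tt, tt), axis=axes))
        ratio = F.div(F.add(F.mul(inter, 2.0), smooth), F.add(denom, smooth))
        return F.mean_tensor(F.sub(1.0, ratio))
    inter = (pdata * t).sum(axis=axes)
    denom = (pdata * pdata).sum(axis=axes) + (t * t).sum(axis=axes)
    return float(np.mean(1.0 - (2.0 * inter + smooth) / (denom + smooth)))


def dsc(a, b) -> float:
    """Dice similarity ``2|A.B| / (|A|+|B|)``; two empty masks give 1.0."""
    av, bv = _as_mask_array(a), _as_mask_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"mask shapes differ: {av.shape} vs {bv.shape}")
    total = int(av.sum()) + int(bv.sum())
    if total == 0:
        return 1.0
    inter = int(np.logical_and(av > 0, bv > 0).sum())
    return 2.0 * inter / total


def hausdorff(a, b) -> float:
    """Symmetric Hausdorff distance in mm; ``nan`` if either mask is empty."""
    am = a if isinstance(a, BinaryMask) else BinaryMask(np.asarray(a))
    bm = b if isinstance(b, BinaryMask) else BinaryMask(np.asarray(b))
    if am.values.shape != bm.values.shape:
        raise ValueError(
            f"mask shapes differ: {am.values.shape} vs {bm.values.shape}"
        )
    pa, pb = am.points_mm(), bm.points_mm()
    if len(pa) == 0 or len(pb) == 0:
        return math.nan
    d_ab = directed_hausdorff(pa, pb)[0]
    d_ba = directed_hausdorff(pb, pa)[0]
    return max(d_ab, d_ba)


@dataclass
class MetricsReport:
    """Per-case and aggregate segmentation metrics."""

    per_case: list[dict] = field(default_factory=list)
    mean_dsc: float = math.nan
    mean_hd: float = math.nan
    n_excluded_from_hd: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [dict(r) for r in self.per_case]
        rows.append({
            "case_id": "mean",
            "dsc": self.mean_dsc,
            "hd_mm": self.mean_hd,
            "pred_empty": "",
            "gt_empty": "",
        })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def evaluate_dataset(pred_masks: Sequence, gt_masks: Sequence,
                     case_ids: Sequence[str] | None = None) -> MetricsReport:
    """Compute DSC and Hausdorff per case plus aggregates.

    Cases where either mask is empty are excluded from the Hausdorff mean
    (and counted); DSC of two empty masks is 1 by convention, flagged.
    """
    if len(pred_masks) != len(gt_masks):
        raise ValueError(
            f"got {len(pred_masks)} predictions for {len(gt_masks)} ground truths"
        )
    if case_ids is None:
        case_ids = [f"case_{i:04d}" for i in range(len(pred_masks))]
    report = MetricsReport()
    hds = []
    for cid, pm, gm in zip(case_ids, pred_masks, gt_masks):
        pv, gv = _as_mask_array(pm), _as_mask_array(gm)
        d = dsc(pv, gv)
        h = hausdorff(pm, gm)
        report.per_case.append({
            "case_id": cid,
            "dsc": d,
            "hd_mm": h,
            "pred_empty": bool(pv.sum() == 0),
            "gt_empty": bool(gv.sum() == 0),
        })
        if math.isnan(h):
            report.n_excluded_from_hd += 1
        else:
            hds.append(h)
    if report.per_case:
        report.mean_dsc = float(np.mean([r["dsc"] for r in report.per_case]))
    report.mean_hd = float(np.mean(hds)) if hds else math.nan
    return report
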