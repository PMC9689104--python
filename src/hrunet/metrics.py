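"""Segmentation evaluation: Dice, IoU, pixel accuracy, modified
Hausdorff distance (MHD), plaque areas, Bland-Altman agreement, and
paired t-tests with Bonferroni correction.

Conventions for degenerate masks: an empty-vs-empty pair scores
Dice = IoU = Acc = 1 (perfect agreement on "no plaque"); empty-vs-
nonempty scores Dice = IoU = 0.  MHD is undefined for empty boundaries
and is skipped (NaN) with a warning in the record-building helper.
Boundaries use the 4-connectivity inner-boundary definition with the
image border counting as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial.distance import cdist

__all__ = [
    "MetricRecord", "dice", "iou", "accuracy", "extract_boundary", "mhd",
    "mhd_masks", "plaque_area", "bland_altman", "paired_ttest_bonferroni",
    "evaluate_pair", "summarize_records",
]


def _check_pair(L: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L, S = np.asarray(L), np.asarray(S)
    if L.shape != S.shape:
        raise ValueError(f"mask shapes differ: {L.shape} vs {S.shape}")
    return L.astype(bool), S.astype(bool)


def dice(L: np.ndarray, S: np.ndarray) -> float:
    """2|L∩S| / (|L|+|S|); 1.0 when both masks are empty."""
    L, S = _check_pair(L, S)
    denom = L.sum() + S.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(L, S).sum() / denom)


def iou(L: np.ndarray, S: np.ndarray) -> float:
    """|L∩S| / |L∪S|; 1.0 when both masks are empty."""
    L, S = _check_pair(L, S)
    union = np.logical_or(L, S).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(L, S).sum() / union)


def accuracy(L: np.ndarray, S: np.ndarray) -> float:
    """Fraction of pixels on which the two masks agree."""
    L, S = _check_pair(L, S)
    return float((L == S).mean())


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """(N, 2) row/col coordinates of the inner boundary of a binary mask.

    A mask pixel is a boundary pixel if at least one of its 4-neighbors
    is background, with pixels beyond the image border treated as
    background (so a full-frame mask still has a boundary ring).
    Returns an empty (0, 2) array for an empty mask.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    cross = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    boundary = mask & ~interior
    return np.argwhere(boundary).astype(np.int64)


def _directed_mean_min(A: np.ndarray, B: np.ndarray) -> float:
    return float(cdist(A, B).min(axis=1).mean())


def mhd(Lb: np.ndarray, Sb: np.ndarray) -> float:
    """Modified Hausdorff distance between two boundary point sets.

    max of the two directed distances, each the mean over one set of the
    minimum Euclidean distance to the other set.  Requires both sets
    nonempty.
    """
    Lb = np.asarray(Lb, dtype=float).reshape(-1, 2)
    Sb = np.asarray(Sb, dtype=float).reshape(-1, 2)
    if len(Lb) == 0 or len(Sb) == 0:
        raise ValueError("MHD is undefined for empty boundary point sets")
    return max(_directed_mean_min(Lb, Sb), _directed_mean_min(Sb, Lb))


def mhd_masks(L: np.ndarray, S: np.ndarray) -> float:
    """MHD between the boundaries of two masks; NaN if either is empty."""
    Lb, Sb = extract_boundary(L), extract_boundary(S)
    if len(Lb) == 0 or len(Sb) == 0:
        warnings.warn("empty mask: MHD skipped", stacklevel=2)
        return float("nan")
    return mhd(Lb, Sb)


def plaque_area(mask: np.ndarray, pixel_spacing: float = 1.0) -> float:
    """Mask area: pixel count x spacing^2 (mm^2 when spacing is mm/px)."""
    if pixel_spacing <= 0:
        raise ValueError(f"pixel_spacing must be positive, got {pixel_spacing}")
    return float(np.asarray(mask).astype(bool).sum() * pixel_spacing ** 2)


@dataclass(frozen=True)
class MetricRecord:
    dice: float
    iou: float
    acc: float
    mhd: float          # pixels (or mm when spacing given); NaN if undefined
    area_gt: float
    area_pred: float

    @property
    def delta_tpa(self) -> float:
        """Signed total-plaque-area error, predicted minus ground truth."""
        return self.area_pred - self.area_gt


def evaluate_pair(L: np.ndarray, S: np.ndarray,
                  pixel_spacing: float = 1.0) -> MetricRecord:
    """All per-image metrics for one ground-truth / prediction mask pair."""
    return MetricRecord(
        dice=dice(L, S), iou=iou(L, S), acc=accuracy(L, S),
        mhd=mhd_masks(L, S),
        area_gt=plaque_area(L, pixel_spacing),
        area_pred=plaque_area(S, pixel_spacing),
    )


def summarize_records(records) -> dict[str, tuple[float, float]]:
    """mean +/- SD per metric over a list of MetricRecords (NaNs dropped
    for MHD)."""
    out = {}
    for name in ("dice", "iou", "acc", "mhd"):
        vals = np.array([getattr(r, name) for r in records], dtype=float)
        if name == "mhd":
            vals = vals[~np.isnan(vals)]
        out[name] = (float(np.mean(vals)) if len(vals) else float("nan"),
                     float(np.std(vals)) if len(vals) else float("nan"))
    deltas = np.array([r.delta_tpa for r in records], dtype=float)
    out["delta_tpa"] = (float(np.mean(deltas)), float(np.std(deltas)))
    return out


def bland_altman(areas_gt, areas_pred):
    """Bland-Altman agreement between paired area measurements.

    Returns (bias, (lower_loa, upper_loa), abs_percentage_errors) where
    bias is the mean of (pred - gt), the limits of agreement are
    bias +/- 1.96 SD, and the percentage errors are |pred-gt|/gt per
    pair (pairs with zero ground-truth area are excluded with a
    warning).
    """
    gt = np.asarray(areas_gt, dtype=float)
    pred = np.asarray(areas_pred, dtype=float)
    if gt.shape != pred.shape:
        raise ValueError("paired lists must have equal length")
    diff = pred - gt
    bias = float(diff.mean())
    sd = float(diff.std())
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    nonzero = gt != 0
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} pair(s) with zero ground-truth "
                      "area excluded from percentage errors", stacklevel=2)
    ape = np.abs(diff[nonzero]) / gt[nonzero]
    return bias, loa, ape


def plot_bland_altman(areas_gt, areas_pred, ax=None):
    """Basic Bland-Altman scatter: per-pair mean vs difference with the
    bias and 1.96-SD limits of agreement drawn as horizontal lines.
    Requires matplotlib; returns the axes."""
    import matplotlib.pyplot as plt

    gt = np.asarray(areas_gt, dtype=float)
    pred = np.asarray(areas_pred, dtype=float)
    bias, (lo, hi), _ = bland_altman(gt, pred)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((gt + pred) / 2.0, pred - gt, s=14, alpha=0.7)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean plaque area")
    ax.set_ylabel("area difference (pred − GT)")
    return ax


def paired_ttest_bonferroni(metric_a, metric_b, n_comparisons: int = 1) -> float:
    """Two-sided paired t-test p-value, Bonferroni-multiplied and capped at 1.

    Zero-variance differences (e.g. identical lists) are degenerate for
    the t statistic; they are reported as p = 1.0 (no evidence of a
    difference).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        # degenerate: the t statistic is undefined (0/0 or +/-inf)
        if np.allclose(d.mean(), 0.0):
            return 1.0
        warnings.warn("zero-variance nonzero differences: t undefined, "
                      "reporting p = 0", stacklevel=2)
        return 0.0
    p = stats.ttest_rel(a, b).pvalue
    return float(min(1.0, p * n_comparisons))
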