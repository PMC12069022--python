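"""Segmentation agreement and group-comparison metrics.

Dice similarity coefficient (DSC), voxel-wise sensitivity/specificity and
their mean ("accuracy"), probabilistic templates binarized at a 50%
threshold, and Cohen's d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EvaluationError
from .volio import BinaryMask, HemiMaskPair, Volume

__all__ = [
    "EvalReport",
    "dsc",
    "sens_spec",
    "probabilistic_template",
    "cohens_d",
    "evaluate_subject",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Voxel-overlap agreement summary for one mask comparison."""

    dsc: float
    sensitivity: float = None
    specificity: float = None
    accuracy: float = None
    n_pred_voxels: int = 0
    n_ref_voxels: int = 0


def _check_same_grid(x: BinaryMask, y: BinaryMask) -> None:
    if x.shape != y.shape:
        raise ValueError(f"mask grids differ: {x.shape} vs {y.shape}")


def dsc(x: BinaryMask, y: BinaryMask, empty_value: float = 1.0) -> float:
    """Dice similarity coefficient 2|X n Y| / (|X| + |Y|).

    Two empty masks have no defined overlap; by convention we return
    ``empty_value`` (default 1.0, agreement on absence) with a warning.
    """
    _check_same_grid(x, y)
    nx, ny = x.n_voxels, y.n_voxels
    if nx == 0 and ny == 0:
        logger.warning("DSC of two empty masks; returning convention value %g", empty_value)
        return float(empty_value)
    inter = int(np.count_nonzero((x.data == 1) & (y.data == 1)))
    return 2.0 * inter / (nx + ny)


def sens_spec(pred: BinaryMask, ref: BinaryMask):
    """Voxel-wise (sensitivity, specificity, accuracy) against a reference.

    accuracy = (sensitivity + specificity) / 2.
    """
    _check_same_grid(pred, ref)
    n_ref = ref.n_voxels
    n_total = int(np.prod(ref.shape))
    if n_ref == 0 or n_ref == n_total:
        raise EvaluationError("reference mask must be neither empty nor full")
    p = pred.data == 1
    r = ref.data == 1
    tp = int(np.count_nonzero(p & r))
    tn = int(np.count_nonzero(~p & ~r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return sensitivity, specificity, (sensitivity + specificity) / 2.0


def probabilistic_template(masks, threshold: float = 0.5):
    """Voxel-wise mask frequency and its thresholded binarization.

    The probability volume holds, per voxel, the fraction of input masks
    labeling it; the binary template includes voxels whose probability is
    ``>= threshold`` (an exact 50% split with an even count is included).
    Masks must already live on one common grid — spatial normalization is
    a precondition, not performed here.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    for m in masks[1:]:
        if m.shape != first.shape or not np.allclose(m.affine, first.affine):
            raise ValueError("all masks must share one grid")
    acc = np.zeros(first.shape, dtype=np.float64)
    for m in masks:
        acc += m.data
    prob = acc / len(masks)
    binary = BinaryMask((prob > threshold - 1e-12).astype(np.uint8), first.affine)
    return Volume(prob, first.affine), binary


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference with the pooled sample SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise EvaluationError("pooled SD is zero; effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def evaluate_subject(pred: HemiMaskPair, ref: HemiMaskPair) -> dict:
    """Per-hemisphere DSC plus the bilateral mean of the two DSCs."""
    left = dsc(pred.left, ref.left)
    right = dsc(pred.right, ref.right)
    return {
        "left": EvalReport(
            dsc=left, n_pred_voxels=pred.left.n_voxels, n_ref_voxels=ref.left.n_voxels
        ),
        "right": EvalReport(
            dsc=right, n_pred_voxels=pred.right.n_voxels, n_ref_voxels=ref.right.n_voxels
        ),
        "bilateral_dsc": (left + right) / 2.0,
    }
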