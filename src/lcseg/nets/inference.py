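"""Ensemble inference primitives: localization, voting, patch segmentation.

The localization stage averages the five members' probability maps on the
downsampled grid, thresholds at 0.5 and takes the two largest connected
components as the left/right LC candidates. The segmentation stage
thresholds each member's probability map into a hard mask and combines
the five by per-voxel majority vote (>= 3 of 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..errors import LocalizationError
from ..volio import BinaryMask, Volume
from .training import EnsembleModel, _pad_to_multiple, _zscore, block_pool

__all__ = ["LocalizationResult", "localize", "majority_vote", "segment_patch"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_MIN_LOC_COMPONENT_VOX = 2


@dataclass
class LocalizationResult:
    """Left/right LC candidate centers in full-resolution voxel coordinates."""

    center_left: np.ndarray
    center_right: np.ndarray
    used_fallback: bool
    n_components: int


def majority_vote(masks) -> BinaryMask:
    """Per-voxel majority vote of exactly 5 binary masks (1 iff >= 3 vote 1)."""
    masks = list(masks)
    if len(masks) != 5:
        raise ValueError(f"majority vote requires exactly 5 masks, got {len(masks)}")
    first = masks[0]
    for m in masks[1:]:
        if m.shape != first.shape or not np.allclose(m.affine, first.affine):
            raise ValueError("all masks must share one grid")
    votes = np.zeros(first.shape, dtype=np.int16)
    for m in masks:
        votes += m.data
    return BinaryMask((votes >= 3).astype(np.uint8), first.affine)


def _lowres_to_fullres(center_lowres: np.ndarray, f: int) -> np.ndarray:
    """Map a low-res voxel coordinate to the center of its full-res block."""
    return center_lowres * f + (f - 1) / 2.0


def localize(model: EnsembleModel, volume: Volume) -> LocalizationResult:
    """Average the 5 localization members and extract the two LC centers.

    Left/right are assigned along the world left-right axis (left = lower
    world x under a RAS+ affine). If only one above-threshold component is
    found, it is split at its left-right midpoint and ``used_fallback`` is
    set; zero components raise :class:`LocalizationError`.
    """
    cfg = model.config
    f = cfg.loc_downsample
    x = block_pool(volume.data.astype(np.float64), f, "mean")
    lowres_shape = x.shape
    x = _zscore(x)
    x, _ = _pad_to_multiple(x, 2**cfg.depth)
    prob = np.zeros(x.shape, dtype=np.float64)
    for net in model.loc_members:
        prob += net.forward(x, train=False)
    prob /= len(model.loc_members)
    prob = prob[tuple(slice(0, s) for s in lowres_shape)]

    above = prob >= 0.5
    labels, n = ndimage.label(above, structure=_CONN26)
    if n == 0:
        raise LocalizationError("no component above the 0.5 ensemble threshold")
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    keep = [order[i] + 1 for i in range(len(order)) if sizes[order[i]] >= _MIN_LOC_COMPONENT_VOX]
    if not keep:
        keep = [order[0] + 1]

    def world_x(vox_lowres):
        full = _lowres_to_fullres(np.asarray(vox_lowres, dtype=float), f)
        return float(volume.voxel_to_world(full)[0])

    if len(keep) >= 2:
        c1 = np.array(ndimage.center_of_mass(above, labels, keep[0]))
        c2 = np.array(ndimage.center_of_mass(above, labels, keep[1]))
        pair = sorted([c1, c2], key=world_x)
        left_c, right_c = pair
        used_fallback = False
    else:
        coords = np.argwhere(labels == keep[0]).astype(float)
        xs = np.array(
            [world_x(c) for c in coords]
        )
        mid = (xs.min() + xs.max()) / 2.0
        left_pts = coords[xs <= mid]
        right_pts = coords[xs > mid]
        if len(left_pts) == 0 or len(right_pts) == 0:
            raise LocalizationError("single-component fallback could not split left/right")
        left_c = left_pts.mean(axis=0)
        right_c = right_pts.mean(axis=0)
        used_fallback = True

    return LocalizationResult(
        center_left=_lowres_to_fullres(left_c, f),
        center_right=_lowres_to_fullres(right_c, f),
        used_fallback=used_fallback,
        n_components=int(n),
    )


def segment_patch(model: EnsembleModel, patch: Volume, return_members: bool = False):
    """Majority-vote segmentation of an already-normalized patch.

    Each member's probability map is thresholded at 0.5 into a hard mask;
    the five masks are combined with :func:`majority_vote`.
    """
    cfg = model.config
    expected = tuple(cfg.patch_size_vox)
    if patch.shape != expected:
        raise ValueError(f"patch shape {patch.shape} != configured {expected}")
    member_masks = []
    for net in model.seg_members:
        p = net.forward(patch.data, train=False)
        member_masks.append(BinaryMask((p >= 0.5).astype(np.uint8), patch.affine))
    voted = majority_vote(member_masks)
    if return_members:
        return voted, member_masks
    return voted
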