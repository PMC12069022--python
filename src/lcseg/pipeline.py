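"""End-to-end inference: localize -> crop -> re-normalize -> segment -> split.

The pipeline crops a single patch covering both hemispheres (centered at
the midpoint of the two localization candidates), z-scores it, runs the
five-member segmentation ensemble with majority voting, re-inserts the
voted mask into the full grid, drops speckle components and splits the
result into hemispheres using the world left-right axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import LocalizationError, NormalizationError
from .nets.inference import localize, segment_patch
from .nets.training import EnsembleModel
from .volio import BinaryMask, HemiMaskPair, Volume

__all__ = [
    "PatchRecord",
    "SegmentationResult",
    "extract_patch",
    "normalize_patch",
    "insert_patch",
    "split_hemispheres",
    "run_inference",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
MIN_COMPONENT_VOX = 3  # smaller components are dropped as speckle


@dataclass
class PatchRecord:
    """Where a patch came from; allows exact re-insertion."""

    start: tuple  # patch-origin voxel index in the full grid (may be negative)
    size: tuple
    grid_shape: tuple


@dataclass
class SegmentationResult:
    masks: HemiMaskPair
    patch_record: PatchRecord = None
    qc_flags: list = field(default_factory=list)


def extract_patch(volume: Volume, center, size):
    """Axis-aligned crop centered at ``center``, zero-padded at borders.

    Returns ``(patch Volume, PatchRecord)``; the patch affine is shifted so
    world coordinates are preserved.
    """
    size = tuple(int(s) for s in (size if np.iterable(size) else (size,) * 3))
    center = np.asarray(center, dtype=float)
    shape = volume.shape
    if np.any(center < 0) or np.any(center > np.asarray(shape) - 1):
        raise ValueError(f"patch center {center} outside grid {shape}")
    if any(s > g for s, g in zip(size, shape)):
        raise ValueError(f"patch size {size} exceeds grid {shape}")
    start = tuple(int(round(c)) - s // 2 for c, s in zip(center, size))
    data = np.zeros(size, dtype=volume.data.dtype)
    src = tuple(
        slice(max(0, st), min(g, st + s)) for st, s, g in zip(start, size, shape)
    )
    dst = tuple(
        slice(sl.start - st, sl.stop - st) for sl, st in zip(src, start)
    )
    data[dst] = volume.data[src]
    affine = volume.affine.copy()
    affine[:3, 3] = volume.voxel_to_world(np.asarray(start, dtype=float))
    record = PatchRecord(start=start, size=size, grid_shape=shape)
    return Volume(data, affine, volume.axis_convention), record


def insert_patch(patch_data: np.ndarray, record: PatchRecord) -> np.ndarray:
    """Place patch voxels back onto the full grid (zeros elsewhere)."""
    full = np.zeros(record.grid_shape, dtype=patch_data.dtype)
    src = tuple(
        slice(max(0, st), min(g, st + s))
        for st, s, g in zip(record.start, record.size, record.grid_shape)
    )
    dst = tuple(slice(sl.start - st, sl.stop - st) for sl, st in zip(src, record.start))
    full[src] = patch_data[dst]
    return full


def normalize_patch(patch: Volume) -> Volume:
    """Z-score the patch intensities (mean 0, SD 1)."""
    sd = patch.data.std()
    if sd == 0:
        raise NormalizationError("constant patch; z-score undefined")
    data = (patch.data - patch.data.mean()) / sd
    return Volume(data, patch.affine, patch.axis_convention)


def split_hemispheres(mask: BinaryMask, affine: np.ndarray = None) -> HemiMaskPair:
    """Assign connected components to hemispheres via the world left-right axis.

    Components whose centroid world-x is below the combined centroid's go
    left (RAS+: smaller x is the anatomical left), the rest right. A single
    component is divided at the plane through its left-right centroid.
    """
    if mask.is_empty:
        raise ValueError("cannot split an empty mask")
    affine = mask.affine if affine is None else np.asarray(affine, dtype=float)
    labels, n = ndimage.label(mask.data, structure=_CONN26)
    coords = np.argwhere(mask.data == 1).astype(float)
    world = coords @ affine[:3, :3].T + affine[:3, 3]
    mid_x = world[:, 0].mean()

    left = np.zeros(mask.shape, dtype=np.uint8)
    right = np.zeros(mask.shape, dtype=np.uint8)
    if n == 1:
        is_left = world[:, 0] <= mid_x
        # guard: a plane through the centroid can leave one side empty only
        # for degenerate single-voxel masks; fall back to index split then.
        if is_left.all() or not is_left.any():
            is_left = np.zeros(len(world), dtype=bool)
            is_left[: len(world) // 2] = True
        for c, flag in zip(coords.astype(int), is_left):
            (left if flag else right)[tuple(c)] = 1
    else:
        for lab in range(1, n + 1):
            comp = labels == lab
            cw = np.argwhere(comp).astype(float) @ affine[:3, :3].T + affine[:3, 3]
            if cw[:, 0].mean() <= mid_x:
                left[comp] = 1
            else:
                right[comp] = 1
    return HemiMaskPair(
        left=BinaryMask(left, affine), right=BinaryMask(right, affine)
    )


def _drop_small_components(data: np.ndarray, min_vox: int) -> np.ndarray:
    labels, n = ndimage.label(data, structure=_CONN26)
    if n == 0:
        return data
    sizes = ndimage.sum_labels(data > 0, labels, index=np.arange(1, n + 1))
    out = np.zeros_like(data)
    for lab in range(1, n + 1):
        if sizes[lab - 1] >= min_vox:
            out[labels == lab] = 1
    return out


def run_inference(
    model: EnsembleModel, volume: Volume, raise_on_failure: bool = False
) -> SegmentationResult:
    """Full pipeline on a working-resolution volume.

    Always returns a result; degenerate inputs yield empty hemisphere
    masks with explanatory ``qc_flags`` unless ``raise_on_failure``.
    """
    qc = []
    empty = lambda: HemiMaskPair(  # noqa: E731
        left=BinaryMask(np.zeros(volume.shape, np.uint8), volume.affine),
        right=BinaryMask(np.zeros(volume.shape, np.uint8), volume.affine),
    )
    try:
        loc = localize(model, volume)
    except LocalizationError as exc:
        if raise_on_failure:
            raise LocalizationError(f"localization stage failed: {exc}") from exc
        qc.append("localization_failed")
        return SegmentationResult(masks=empty(), qc_flags=qc)
    if loc.used_fallback:
        qc.append("localization_fallback_single_component")

    center = (loc.center_left + loc.center_right) / 2.0
    center = np.clip(center, 0, np.asarray(volume.shape, dtype=float) - 1)
    patch, record = extract_patch(volume, center, model.config.patch_size_vox)
    try:
        patch = normalize_patch(patch)
    except NormalizationError as exc:
        if raise_on_failure:
            raise NormalizationError(f"normalization stage failed: {exc}") from exc
        qc.append("constant_patch")
        return SegmentationResult(masks=empty(), patch_record=record, qc_flags=qc)

    voted = segment_patch(model, patch)
    full = insert_patch(voted.data, record)
    full = _drop_small_components(full, MIN_COMPONENT_VOX)
    if full.sum() == 0:
        qc.append("empty_segmentation")
        return SegmentationResult(masks=empty(), patch_record=record, qc_flags=qc)
    pair = split_hemispheres(BinaryMask(full, volume.affine))
    if pair.left.is_empty:
        qc.append("empty_left_hemisphere")
    if pair.right.is_empty:
        qc.append("empty_right_hemisphere")
    return SegmentationResult(masks=pair, patch_record=record, qc_flags=qc)
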