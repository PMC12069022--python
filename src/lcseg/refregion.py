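"""LC-oriented orthonormal coordinate frame and reference-region placement.

The frame is built from the two hemisphere masks: the first principal
direction of each mask's voxel coordinates (``l1``, ``r1``) and the two
centers of mass (``c_l``, ``c_r``) give

    v1 = normalize((l1 + r1) / 2)
    v2 = normalize((c_l - c_r) x v1)
    v3 = v1 x v2
    origin = (c_l + c_r) / 2

With the superior-pointing sign convention for ``l1``/``r1`` and
left-minus-right ordering of the centers, ``v1`` points roughly superior,
``v2`` roughly anterior and ``v3`` toward the anatomical left.

Reference regions are frame-axis-aligned boxes placed at per-hemisphere
mean offsets learned from training data, so placement requires neither a
pons segmentation nor registration and inherits the frame's rotation
equivariance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, PlacementError
from .volio import BinaryMask, HemiMaskPair, Volume

__all__ = [
    "PrincipalAxes",
    "CoordinateFrame",
    "OffsetModel",
    "principal_axis",
    "mask_center_of_mass",
    "compute_frame",
    "world_to_frame",
    "frame_to_world",
    "learn_offset",
    "place_reference_region",
]

logger = logging.getLogger(__name__)

_SUPERIOR = np.array([0.0, 0.0, 1.0])


def _mask_world_coords(mask: BinaryMask, affine: np.ndarray) -> np.ndarray:
    ijk = np.argwhere(mask.data == 1).astype(float)
    return ijk @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


def mask_center_of_mass(mask: BinaryMask, affine: np.ndarray) -> np.ndarray:
    """Unweighted centroid of the mask voxels' world coordinates (mm)."""
    if mask.is_empty:
        raise DegenerateGeometryError("cannot compute center of mass of empty mask")
    return _mask_world_coords(mask, affine).mean(axis=0)


def principal_axis(mask: BinaryMask, affine: np.ndarray) -> np.ndarray:
    """First principal direction of a mask's voxel world coordinates.

    The unit eigenvector of the coordinate covariance with the largest
    eigenvalue, its sign fixed so the superior (world z) component is
    non-negative.

    Raises
    ------
    DegenerateGeometryError
        For masks with < 3 voxels, or point-like masks whose leading
        coordinate variance vanishes (no direction is defined). A straight
        rod is fine: its first principal direction is well defined.
    """
    pts = _mask_world_coords(mask, affine)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"principal axis needs >= 3 voxels, got {pts.shape[0]}"
        )
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-12:
        raise DegenerateGeometryError("mask voxels are coincident; no principal axis")
    v = evecs[:, -1]
    s = float(v @ _SUPERIOR)
    if s < 0 or (s == 0 and (v[1] < 0 or (v[1] == 0 and v[0] < 0))):
        v = -v
    return v / np.linalg.norm(v)


@dataclass
class PrincipalAxes:
    """Per-hemisphere principal directions and centers of mass (world mm)."""

    l1: np.ndarray
    r1: np.ndarray
    c_l: np.ndarray
    c_r: np.ndarray

    @classmethod
    def from_masks(cls, pair: HemiMaskPair, affine: np.ndarray) -> "PrincipalAxes":
        return cls(
            l1=principal_axis(pair.left, affine),
            r1=principal_axis(pair.right, affine),
            c_l=mask_center_of_mass(pair.left, affine),
            c_r=mask_center_of_mass(pair.right, affine),
        )


@dataclass
class CoordinateFrame:
    """Orthonormal right-handed basis (v1, v2, v3) with a world origin."""

    origin: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.v1 = np.asarray(self.v1, dtype=float)
        self.v2 = np.asarray(self.v2, dtype=float)
        self.v3 = np.asarray(self.v3, dtype=float)
        B = self.basis
        if not np.allclose(B @ B.T, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("frame basis is not orthonormal")
        if float(self.v1 @ np.cross(self.v2, self.v3)) <= 0:
            raise DegenerateGeometryError("frame basis is not right-handed")

    @property
    def basis(self) -> np.ndarray:
        """Rows are (v1, v2, v3)."""
        return np.stack([self.v1, self.v2, self.v3])


def compute_frame(pair: HemiMaskPair, affine: np.ndarray) -> CoordinateFrame:
    """Build the LC-oriented coordinate frame from a hemisphere mask pair."""
    axes = PrincipalAxes.from_masks(pair, affine)
    v1 = (axes.l1 + axes.r1) / 2.0
    n1 = np.linalg.norm(v1)
    if n1 < 1e-6:
        raise DegenerateGeometryError("hemisphere principal axes are anti-parallel")
    v1 /= n1
    lr = axes.c_l - axes.c_r
    v2 = np.cross(lr, v1)
    n2 = np.linalg.norm(v2)
    if n2 < 1e-9:
        raise DegenerateGeometryError(
            "hemisphere centers coincide or lie along the principal axis"
        )
    v2 /= n2
    v3 = np.cross(v1, v2)
    origin = (axes.c_l + axes.c_r) / 2.0
    return CoordinateFrame(origin=origin, v1=v1, v2=v2, v3=v3)


def world_to_frame(frame: CoordinateFrame, point: np.ndarray) -> np.ndarray:
    """World mm -> frame coordinates in (v1, v2, v3) order."""
    p = np.asarray(point, dtype=float)
    return (p - frame.origin) @ frame.basis.T


def frame_to_world(frame: CoordinateFrame, coords: np.ndarray) -> np.ndarray:
    """Frame coordinates (v1, v2, v3 order) -> world mm."""
    q = np.asarray(coords, dtype=float)
    return q @ frame.basis + frame.origin


@dataclass
class OffsetModel:
    """Per-hemisphere mean reference-region offsets in frame coordinates (mm)."""

    mean_offset_left: np.ndarray
    mean_offset_right: np.ndarray
    n_training: int
    offsets_left: np.ndarray = field(default=None)
    offsets_right: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.mean_offset_left = np.asarray(self.mean_offset_left, dtype=float)
        self.mean_offset_right = np.asarray(self.mean_offset_right, dtype=float)
        if self.offsets_left is None:
            self.offsets_left = self.mean_offset_left[None, :].copy()
        if self.offsets_right is None:
            self.offsets_right = self.mean_offset_right[None, :].copy()
        self.offsets_left = np.asarray(self.offsets_left, dtype=float)
        self.offsets_right = np.asarray(self.offsets_right, dtype=float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "units": "mm",
                "frame_order": ["v1", "v2", "v3"],
                "mean_offset_left": self.mean_offset_left.tolist(),
                "mean_offset_right": self.mean_offset_right.tolist(),
                "n_training": self.n_training,
                "offsets_left": self.offsets_left.tolist(),
                "offsets_right": self.offsets_right.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "OffsetModel":
        d = json.loads(text)
        return cls(
            mean_offset_left=np.array(d["mean_offset_left"]),
            mean_offset_right=np.array(d["mean_offset_right"]),
            n_training=int(d["n_training"]),
            offsets_left=np.array(d["offsets_left"]),
            offsets_right=np.array(d["offsets_right"]),
        )


def learn_offset(training) -> OffsetModel:
    """Average per-hemisphere reference-region offsets in the LC frame.

    Parameters
    ----------
    training : iterable of (HemiMaskPair lc, HemiMaskPair ref, affine)

    Degenerate samples (frame construction fails) are skipped with a
    warning; if every sample is degenerate an error is raised.
    """
    offs_l, offs_r = [], []
    n_seen = 0
    for i, (lc, ref, affine) in enumerate(training):
        n_seen += 1
        try:
            frame = compute_frame(lc, affine)
        except DegenerateGeometryError as exc:
            logger.warning("skipping degenerate training sample %d: %s", i, exc)
            continue
        offs_l.append(world_to_frame(frame, mask_center_of_mass(ref.left, affine)))
        offs_r.append(world_to_frame(frame, mask_center_of_mass(ref.right, affine)))
    if n_seen == 0:
        raise ValueError("learn_offset requires at least one training sample")
    if not offs_l:
        raise DegenerateGeometryError("all training samples had degenerate frames")
    offs_l = np.stack(offs_l)
    offs_r = np.stack(offs_r)
    return OffsetModel(
        mean_offset_left=offs_l.mean(axis=0),
        mean_offset_right=offs_r.mean(axis=0),
        n_training=offs_l.shape[0],
        offsets_left=offs_l,
        offsets_right=offs_r,
    )


def _rasterize_frame_box(
    frame: CoordinateFrame,
    center_frame: np.ndarray,
    shape_mm: np.ndarray,
    grid: Volume,
) -> BinaryMask:
    """Voxels whose center's frame coordinates fall inside the half-open box
    ``[center - shape/2, center + shape/2)``."""
    shape_mm = np.asarray(shape_mm, dtype=float)
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = grid.voxel_to_world(ijk)
    q = world_to_frame(frame, world) - np.asarray(center_frame, dtype=float)
    half = shape_mm / 2.0
    inside = np.all((q >= -half) & (q < half), axis=1)
    data = inside.reshape(grid.shape).astype(np.uint8)
    return BinaryMask(data, grid.affine)


DEFAULT_REF_SHAPE_MM = (5.0, 3.0, 3.0)  # frame order (v1, v2, v3): long axis rostrocaudal


def place_reference_region(
    frame: CoordinateFrame,
    model: OffsetModel,
    shape_mm=DEFAULT_REF_SHAPE_MM,
    grid: Volume = None,
) -> HemiMaskPair:
    """Rasterize the per-hemisphere reference boxes on a volume grid.

    ``shape_mm`` gives the box edge lengths in frame order (v1, v2, v3);
    the default 5x3x3 mm box has its long axis along v1 (rostrocaudal).
    A voxel belongs to a box iff its center's frame coordinates lie in the
    half-open interval ``[center - shape/2, center + shape/2)`` per axis.
    """
    if grid is None:
        raise ValueError("grid volume metadata is required")
    shape_mm = np.asarray(shape_mm, dtype=float)
    if shape_mm.shape != (3,) or np.any(shape_mm <= 0):
        raise ValueError("shape_mm must be 3 positive edge lengths")
    left = _rasterize_frame_box(frame, model.mean_offset_left, shape_mm, grid)
    right = _rasterize_frame_box(frame, model.mean_offset_right, shape_mm, grid)
    if left.is_empty:
        raise PlacementError("left reference region falls fully outside the grid")
    if right.is_empty:
        raise PlacementError("right reference region falls fully outside the grid")
    return HemiMaskPair(left=left, right=right)
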