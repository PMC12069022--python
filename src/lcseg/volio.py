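"""Core volumetric data types, NIfTI I/O and ideal-sinc (Fourier) upsampling.

Conventions
-----------
* Voxel indices are 0-based throughout.
* World coordinates follow the NIfTI affine (RAS+: +x right, +y anterior,
  +z superior).
* An "axial slice" is a plane of constant index along the grid axis whose
  affine column is closest to the world superior axis (``axial_axis``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import FormatError

__all__ = [
    "Volume",
    "BinaryMask",
    "HemiMaskPair",
    "read_nifti",
    "write_nifti",
    "sinc_upsample",
]

logger = logging.getLogger(__name__)


def _infer_axial_axis(affine: np.ndarray) -> int:
    """Grid axis whose direction is closest to the world superior axis."""
    cols = affine[:3, :3]
    scores = np.abs(cols[2, :]) / np.linalg.norm(cols, axis=0)
    return int(np.argmax(scores))


def _axial_sign(affine: np.ndarray, axis: int) -> int:
    """+1 if increasing index along ``axis`` moves toward superior, else -1."""
    return 1 if affine[2, axis] >= 0 else -1


@dataclass
class Volume:
    """A 3-D scalar intensity grid with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Scalar intensities; must be finite.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map; must be invertible.
    axis_convention : int, optional
        Index of the inferior->superior ("axial stacking") grid axis.
        Derived from the affine when omitted.
    """

    data: np.ndarray
    affine: np.ndarray
    axis_convention: int = field(default=-1)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume intensities must be finite")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible")
        if np.any(self.voxel_size <= 0):
            raise FormatError("voxel sizes must be strictly positive")
        if self.axis_convention < 0:
            self.axis_convention = _infer_axial_axis(self.affine)
        if self.axis_convention not in (0, 1, 2):
            raise FormatError("axis_convention must name one of the 3 grid axes")
        vs = self.voxel_size
        if not np.allclose(vs, vs[0], rtol=1e-3):
            logger.warning("non-isotropic voxel sizes %s; mm features use per-axis sizes", vs)

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def axial_axis(self) -> int:
        return self.axis_convention

    @property
    def axial_voxel_mm(self) -> float:
        return float(self.voxel_size[self.axis_convention])

    @property
    def axial_sign(self) -> int:
        """+1 if increasing axial index points superior, else -1."""
        return _axial_sign(self.affine, self.axis_convention)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel coordinates to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class BinaryMask:
    """A 3-D {0,1} voxel grid sharing its geometry with a Volume."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError("mask values must be exactly 0 or 1")
        if self.data.dtype != np.uint8:
            self.data = self.data.astype(np.uint8)
        if self.data.ndim != 3:
            raise FormatError("mask must be 3-D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    def same_grid(self, other: "BinaryMask") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class HemiMaskPair:
    """Left and right hemisphere binary masks on a common grid."""

    left: BinaryMask
    right: BinaryMask

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise FormatError("hemisphere masks must share a grid shape")
        if np.any((self.left.data == 1) & (self.right.data == 1)):
            raise FormatError("left and right masks must be disjoint")

    @property
    def union(self) -> BinaryMask:
        return BinaryMask(
            np.maximum(self.left.data, self.right.data), self.left.affine
        )

    @property
    def both_nonempty(self) -> bool:
        return not self.left.is_empty and not self.right.is_empty


def read_nifti(path) -> Volume:
    """Read a NIfTI-1/2 scalar image into a :class:`Volume`.

    Raises
    ------
    FormatError
        If the image is not a 3-D scalar volume.
    OSError
        If the file cannot be read.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises its own hierarchy
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3-D scalar image, got shape {data.shape}")
    return Volume(data.astype(np.float64), np.asarray(img.affine))


def read_nifti_mask(path) -> BinaryMask:
    """Read a NIfTI file containing a {0,1} mask."""
    vol = read_nifti(path)
    data = vol.data
    if not np.all(np.isin(np.unique(data), (0.0, 1.0))):
        raise FormatError(f"{path}: mask values must be 0/1")
    return BinaryMask(data.astype(np.uint8), vol.affine)


def write_nifti(volume_or_mask, path) -> None:
    """Write a Volume (float64) or BinaryMask (uint8) as NIfTI-1."""
    if isinstance(volume_or_mask, BinaryMask):
        data = volume_or_mask.data.astype(np.uint8)
    elif isinstance(volume_or_mask, Volume):
        data = volume_or_mask.data.astype(np.float64)
    else:
        raise TypeError("expected Volume or BinaryMask")
    img = nib.Nifti1Image(data, volume_or_mask.affine)
    nib.save(img, str(path))


def _upsample_axis_fourier(x: np.ndarray, factor: int, axis: int) -> np.ndarray:
    """1-D ideal-sinc upsampling along one axis via FFT zero padding.

    The Nyquist bin of an even-length input is split between the positive
    and negative halves so that real cosine inputs are interpolated exactly.
    """
    n = x.shape[axis]
    m = n * factor
    X = np.fft.fft(x, axis=axis)
    out_shape = list(x.shape)
    out_shape[axis] = m
    Y = np.zeros(out_shape, dtype=complex)

    def sl(idx):
        s = [slice(None)] * x.ndim
        s[axis] = idx
        return tuple(s)

    half = n // 2
    if n % 2 == 0:
        Y[sl(slice(0, half))] = X[sl(slice(0, half))]
        Y[sl(half)] = 0.5 * X[sl(half)]
        Y[sl(m - half)] = 0.5 * X[sl(half)]
        if half + 1 < n:
            Y[sl(slice(m - half + 1, m))] = X[sl(slice(half + 1, n))]
    else:
        Y[sl(slice(0, half + 1))] = X[sl(slice(0, half + 1))]
        Y[sl(slice(m - half, m))] = X[sl(slice(half + 1, n))]
    return np.fft.ifft(Y, axis=axis).real * factor


def sinc_upsample(volume: Volume, factor: int) -> Volume:
    """Upsample a volume by an integer factor with the discrete ideal sinc.

    Implemented as Fourier zero padding, which is exact on band-limited
    inputs and preserves the volume mean. ``factor=1`` is the identity.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"upsampling factor must be an integer >= 1, got {factor!r}")
    if factor == 1:
        return Volume(volume.data.copy(), volume.affine.copy(), volume.axis_convention)
    out = volume.data.astype(np.float64)
    for axis in range(3):
        out = _upsample_axis_fourier(out, factor, axis)
    # new voxel (0,0,0) keeps the world position of old voxel (0,0,0);
    # spacing shrinks by `factor`.
    new_affine = volume.affine.copy()
    new_affine[:3, :3] /= factor
    return Volume(out, new_affine, volume.axis_convention)
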