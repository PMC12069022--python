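"""LC MRI feature extraction.

Contrast ratios relate LC mask intensities to the median intensity of a
same-side reference region:

    CR_stat = (stat(LC voxels) - median(REF voxels)) / median(REF voxels)

with ``stat`` either the maximum or the median. Subregional CRs split the
mask along the axial (inferior->superior) grid axis into two or three
sections of equal slice length; length counts occupied axial slices
converted to mm; volume counts mask voxels converted to mm^3. Reported
bilateral features are the unweighted mean of the two hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import FeatureError
from .volio import BinaryMask, HemiMaskPair, Volume

__all__ = [
    "FeatureSet",
    "contrast_ratio",
    "split_rostrocaudal",
    "lc_length_mm",
    "lc_volume_mm3",
    "extract_features",
]

_SCALAR_FIELDS = ("cr_max", "cr_median", "length_mm", "volume_mm3")
_TUPLE_FIELDS = ("sub2_cr_max", "sub2_cr_median", "sub3_cr_max", "sub3_cr_median")


@dataclass
class FeatureSet:
    """Per-scope LC features; subregional tuples are ordered caudal->rostral."""

    cr_max: float = None
    cr_median: float = None
    sub2_cr_max: tuple = None
    sub2_cr_median: tuple = None
    sub3_cr_max: tuple = None
    sub3_cr_median: tuple = None
    length_mm: float = None
    volume_mm3: float = None
    scope: str = "bilateral"
    partial: bool = False

    def as_dict(self) -> dict:
        out = {"scope": self.scope, "partial": self.partial}
        for f in _SCALAR_FIELDS:
            out[f] = getattr(self, f)
        for f in _TUPLE_FIELDS:
            vals = getattr(self, f)
            n = int(f[3])  # "sub2_..." / "sub3_..."
            labels = (
                ("caudal", "rostral") if n == 2 else ("caudal", "medial", "rostral")
            )
            for lab, v in zip(labels, vals if vals is not None else [None] * n):
                out[f"{f}_{lab}"] = v
        return out


def _round_half_up(x: float) -> int:
    """Round half away from zero (x >= 0 here)."""
    return int(np.floor(x + 0.5))


def contrast_ratio(
    lc_mask: BinaryMask, volume: Volume, ref_mask: BinaryMask, statistic: str = "max"
) -> float:
    """(stat(LC) - median(REF)) / median(REF) with stat in {max, median}."""
    if statistic not in ("max", "median"):
        raise ValueError(f"statistic must be 'max' or 'median', got {statistic!r}")
    if lc_mask.is_empty:
        raise FeatureError("LC mask is empty")
    if ref_mask.is_empty:
        raise FeatureError("reference mask is empty")
    lc_vals = volume.data[lc_mask.data == 1]
    ref_vals = volume.data[ref_mask.data == 1]
    ref_median = float(np.median(ref_vals))
    if ref_median == 0:
        raise ZeroDivisionError("reference median intensity is zero")
    stat = float(np.max(lc_vals)) if statistic == "max" else float(np.median(lc_vals))
    return (stat - ref_median) / ref_median


def split_rostrocaudal(mask: BinaryMask, n_sections: int, axis: int = 2):
    """Split a mask into equal-length contiguous axial sections.

    Sections span the occupied slice range ``s_min..s_max`` (gaps included)
    with boundaries at ``s_min + round(S * j / n)``; returned in
    caudal->rostral *index* order (ascending slice index). Callers whose
    axial axis decreases toward superior must reverse the list.
    """
    if n_sections not in (2, 3):
        raise ValueError("n_sections must be 2 or 3")
    if mask.is_empty:
        raise FeatureError("cannot split an empty mask")
    occupied = np.any(mask.data, axis=tuple(i for i in range(3) if i != axis))
    s_min, s_max = np.flatnonzero(occupied)[[0, -1]]
    S = int(s_max - s_min + 1)
    if S < n_sections:
        raise FeatureError(f"mask spans {S} slices; cannot split into {n_sections}")
    bounds = [0] + [_round_half_up(S * j / n_sections) for j in range(1, n_sections)] + [S]
    sections = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        keep = np.zeros(mask.shape[axis], dtype=bool)
        keep[s_min + lo : s_min + hi] = True
        shape = [1, 1, 1]
        shape[axis] = -1
        data = mask.data * keep.reshape(shape).astype(np.uint8)
        sections.append(BinaryMask(data, mask.affine))
    return sections


def lc_length_mm(mask: BinaryMask, axial_voxel_mm: float = None, axis: int = 2) -> float:
    """Occupied axial slice count times axial voxel size (gaps not counted)."""
    if axial_voxel_mm is None:
        axial_voxel_mm = float(mask.voxel_size[axis])
    occupied = np.any(mask.data, axis=tuple(i for i in range(3) if i != axis))
    return float(np.count_nonzero(occupied)) * float(axial_voxel_mm)


def lc_volume_mm3(mask: BinaryMask, voxel_size=None) -> float:
    """Mask voxel count times the single-voxel volume in mm^3."""
    if voxel_size is None:
        voxel_size = mask.voxel_size
    unit = float(np.prod(np.asarray(voxel_size, dtype=float)))
    return mask.n_voxels * unit


def _hemisphere_features(
    volume: Volume, lc: BinaryMask, ref: BinaryMask, scope: str
) -> FeatureSet:
    axis = volume.axial_axis
    fs = FeatureSet(scope=scope)
    fs.cr_max = contrast_ratio(lc, volume, ref, "max")
    fs.cr_median = contrast_ratio(lc, volume, ref, "median")
    fs.length_mm = lc_length_mm(lc, volume.voxel_size[axis], axis)
    fs.volume_mm3 = lc_volume_mm3(lc, volume.voxel_size)
    for n in (2, 3):
        try:
            secs = split_rostrocaudal(lc, n, axis)
        except FeatureError:
            setattr(fs, f"sub{n}_cr_max", None)
            setattr(fs, f"sub{n}_cr_median", None)
            continue
        if volume.axial_sign < 0:  # ascending index points inferior
            secs = secs[::-1]
        crs_max, crs_med = [], []
        for sec in secs:
            crs_max.append(contrast_ratio(sec, volume, ref, "max"))
            crs_med.append(contrast_ratio(sec, volume, ref, "median"))
        setattr(fs, f"sub{n}_cr_max", tuple(crs_max))
        setattr(fs, f"sub{n}_cr_median", tuple(crs_med))
    return fs


def _mean_or_none(a, b):
    if a is None or b is None:
        return None
    if isinstance(a, tuple):
        return tuple((x + y) / 2.0 for x, y in zip(a, b))
    return (a + b) / 2.0


def extract_features(volume: Volume, lc: HemiMaskPair, ref: HemiMaskPair):
    """Per-hemisphere and bilateral feature sets.

    Each hemisphere's CRs use the same-side reference region. Bilateral
    values are field-wise unweighted means; if one hemisphere is empty its
    fields are None and the bilateral set carries the other side's values
    flagged ``partial``.
    """
    for name, m in (("LC", lc), ("reference", ref)):
        if m.left.shape != volume.shape or m.right.shape != volume.shape:
            raise FeatureError(f"{name} masks are not on the volume's grid")

    sides = {}
    for scope, lc_m, ref_m in (
        ("left", lc.left, ref.left),
        ("right", lc.right, ref.right),
    ):
        if lc_m.is_empty:
            sides[scope] = FeatureSet(scope=scope, partial=True)
        else:
            sides[scope] = _hemisphere_features(volume, lc_m, ref_m, scope)

    lf, rf = sides["left"], sides["right"]
    bilateral = FeatureSet(scope="bilateral")
    if lf.partial or rf.partial:
        src = rf if lf.partial else lf
        for f in _SCALAR_FIELDS + _TUPLE_FIELDS:
            setattr(bilateral, f, getattr(src, f))
        bilateral.partial = True
    else:
        for f in _SCALAR_FIELDS + _TUPLE_FIELDS:
            setattr(bilateral, f, _mean_or_none(getattr(lf, f), getattr(rf, f)))
    return lf, rf, bilateral
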