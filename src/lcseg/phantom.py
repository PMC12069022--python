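"""Synthetic FLASH-like brainstem phantoms with ground-truth LC masks.

Each phantom is a pons-like background holding two roughly parallel,
hyperintense, slightly bowed tubes (the left/right LC, ~2 mm diameter)
plus per-hemisphere reference-region boxes planted at known offsets in
the LC-oriented coordinate frame. The scene can be rigidly rotated, a
smooth multiplicative bias field applied, and Gaussian noise added.

The tube *interior intensity* is constructed so that, before noise and
bias, ``(max LC intensity - median reference intensity) / median
reference intensity`` equals the requested contrast ratio exactly; the
ground-truth masks are hard rasterizations of the analytic geometry on
the (rotated) grid, so no mask interpolation ever occurs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import GeometryError
from .refregion import OffsetModel, compute_frame, place_reference_region
from .volio import BinaryMask, HemiMaskPair, Volume

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_dataset"]

_CENTERLINE_STEP_MM = 0.05

#: spec fields treated as geometry for dataset-level jitter
JITTERABLE = (
    "lc_diameter_mm",
    "lc_length_mm",
    "lc_curvature_mm",
    "inter_lc_distance_mm",
    "true_cr",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic LC phantom."""

    grid_shape: tuple = (72, 72, 72)
    voxel_size_mm: float = 0.375
    lc_diameter_mm: float = 2.0
    lc_length_mm: float = 10.0
    lc_curvature_mm: float = 0.75
    inter_lc_distance_mm: float = 7.0
    true_cr: float = 0.2
    background_level: float = 100.0
    noise_sd: float = 0.02
    bias_amplitude: float = 0.1
    rotation_deg: float = 10.0
    ref_offset_frame: tuple = (0.0, -6.0, 2.0)  # left hemisphere, (v1, v2, v3) mm
    ref_region_shape_mm: tuple = (5.0, 3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lc_diameter_mm", "lc_length_mm", "inter_lc_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.true_cr <= 0:
            raise ValueError("true_cr must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must be in [0, 1)")
        if not 0 <= self.rotation_deg <= 45:
            raise ValueError("rotation_deg must be in [0, 45]")

    @property
    def ref_offset_frame_right(self) -> tuple:
        """Right-hemisphere offset: v3 (left-pointing) component mirrored."""
        a, b, c = self.ref_offset_frame
        return (a, b, -c)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("grid_shape", "ref_offset_frame", "ref_region_shape_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomSample:
    """A generated phantom: volume, ground-truth masks and provenance."""

    volume: Volume
    lc_truth: HemiMaskPair
    ref_truth: HemiMaskPair
    spec: PhantomSpec
    applied_rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _centered_affine(shape, voxel_mm: float) -> np.ndarray:
    """Isotropic RAS affine placing the world origin at the grid center."""
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = -(np.asarray(shape, dtype=float) - 1.0) / 2.0 * voxel_mm
    return affine


def _tube_centerline(spec: PhantomSpec, side: int, rot: Rotation) -> np.ndarray:
    """Dense world-mm samples of one LC centerline, extended beyond the caps.

    ``side`` is -1 for the (anatomical, -x) left tube and +1 for the right.
    The lateral bow displaces the tube outward, peaking mid-length.
    """
    L = spec.lc_length_mm
    r = spec.lc_diameter_mm / 2.0
    n = max(int(np.ceil((L + 2 * r) / _CENTERLINE_STEP_MM)), 16)
    t = np.linspace(-L / 2.0 - r, L / 2.0 + r, n + 1)
    u = np.clip(2.0 * t / L, -1.0, 1.0)
    x = side * (spec.inter_lc_distance_mm / 2.0 + spec.lc_curvature_mm * (1.0 - u**2))
    pts = np.stack([x, np.zeros_like(t), t], axis=1)
    return rot.apply(pts), t


def _rasterize_tube(spec: PhantomSpec, side: int, rot: Rotation, vol: Volume) -> np.ndarray:
    """Hard tube mask: voxel centers within radius of the centerline and
    whose nearest centerline point lies between the end caps."""
    pts, t = _tube_centerline(spec, side, rot)
    r = spec.lc_diameter_mm / 2.0
    shape = vol.shape
    ijk = np.stack(
        np.meshgrid(*(np.arange(s) for s in shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = vol.voxel_to_world(ijk)
    # restrict to the tube's bounding box for speed
    lo = pts.min(axis=0) - r - 1.0
    hi = pts.max(axis=0) + r + 1.0
    box = np.all((world >= lo) & (world <= hi), axis=1)
    cand = world[box]
    tree = cKDTree(pts)
    dist, idx = tree.query(cand, workers=1)
    L = spec.lc_length_mm
    inside = (dist <= r) & (np.abs(t[idx]) <= L / 2.0)
    mask = np.zeros(np.prod(shape), dtype=np.uint8)
    sel = np.flatnonzero(box)[inside]
    mask[sel] = 1
    return mask.reshape(shape)


def _check_in_bounds(spec: PhantomSpec, rot: Rotation, vol: Volume) -> None:
    r = spec.lc_diameter_mm / 2.0
    lo = vol.voxel_to_world(np.zeros(3))
    hi = vol.voxel_to_world(np.asarray(vol.shape, dtype=float) - 1.0)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    for side in (-1, 1):
        pts, _ = _tube_centerline(spec, side, rot)
        if np.any(pts - r < lo) or np.any(pts + r > hi):
            raise GeometryError(
                "LC tube exceeds the phantom grid; enlarge grid_shape or "
                "shorten lc_length_mm"
            )


def _bias_field(spec: PhantomSpec, vol: Volume, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: 3 low-order cosine modes, random phases,
    scaled so the peak-to-trough range equals ``bias_amplitude``."""
    if spec.bias_amplitude == 0:
        return np.ones(vol.shape)
    shape = vol.shape
    grids = np.meshgrid(
        *(np.arange(s) / s for s in shape), indexing="ij"
    )
    f = np.zeros(shape)
    for _ in range(3):
        freq = rng.integers(1, 3, size=3)  # 1 or 2 cycles per axis
        phase = rng.uniform(0, 2 * np.pi, size=3)
        amp = rng.uniform(0.5, 1.0)
        f += amp * np.prod(
            [np.cos(2 * np.pi * fq * g + ph) for fq, g, ph in zip(freq, grids, phase)],
            axis=0,
        )
    span = f.max() - f.min()
    if span < 1e-12:
        return np.ones(shape)
    f = (f - f.min()) / span - 0.5  # in [-0.5, 0.5]
    return 1.0 + spec.bias_amplitude * f


def generate_phantom(spec: PhantomSpec, seed=None) -> PhantomSample:
    """Generate one phantom; identical (spec, seed) gives identical output."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    angles = rng.uniform(-spec.rotation_deg, spec.rotation_deg, size=3)
    rot = Rotation.from_euler("xyz", angles, degrees=True)

    affine = _centered_affine(spec.grid_shape, spec.voxel_size_mm)
    base = Volume(np.zeros(spec.grid_shape), affine)
    _check_in_bounds(spec, rot, base)

    left = _rasterize_tube(spec, -1, rot, base)
    right = _rasterize_tube(spec, +1, rot, base)
    lc_truth = HemiMaskPair(
        left=BinaryMask(left, affine), right=BinaryMask(right, affine)
    )
    if lc_truth.left.is_empty or lc_truth.right.is_empty:
        raise GeometryError("rasterized LC tube is empty; grid too coarse")

    # intensity: plateau + one-voxel Gaussian softening, renormalized so the
    # in-mask maximum hits background * (1 + true_cr) exactly (pre-noise).
    soft = gaussian_filter((left | right).astype(np.float64), sigma=1.0)
    peak = soft.max()
    if peak > 0:
        soft /= peak
    intensities = spec.background_level * (1.0 + spec.true_cr * soft)

    bias = _bias_field(spec, base, rng)
    intensities = intensities * bias
    if spec.noise_sd > 0:
        intensities = intensities + rng.normal(
            0.0, spec.noise_sd * spec.background_level, size=intensities.shape
        )

    volume = Volume(intensities, affine)

    # reference boxes planted at the configured frame offsets, using the frame
    # computed from the rasterized truth (what learn_offset will later see).
    frame = compute_frame(lc_truth, affine)
    planted = OffsetModel(
        mean_offset_left=np.asarray(spec.ref_offset_frame, dtype=float),
        mean_offset_right=np.asarray(spec.ref_offset_frame_right, dtype=float),
        n_training=0,
    )
    ref_truth = place_reference_region(
        frame, planted, shape_mm=spec.ref_region_shape_mm, grid=volume
    )
    overlap = (lc_truth.union.data & ref_truth.union.data).sum()
    if overlap:
        raise GeometryError(
            f"reference region overlaps the LC ({overlap} voxels); "
            "adjust ref_offset_frame"
        )
    return PhantomSample(
        volume=volume,
        lc_truth=lc_truth,
        ref_truth=ref_truth,
        spec=spec,
        applied_rotation_deg=angles,
    )


def generate_dataset(n: int, spec: PhantomSpec, seed=None, jitter=0.0):
    """Generate ``n`` phantoms with per-sample seeds and jittered geometry.

    Parameters
    ----------
    n : int
        Number of samples (>= 1).
    jitter : float or dict
        Relative half-width of uniform multiplicative jitter. A float is
        applied to every field in :data:`JITTERABLE`; a dict maps field
        names to per-field half-widths. A parameter ``p`` is drawn as
        ``p * U(1 - j, 1 + j)``, giving a coefficient of variation of
        approximately ``j / sqrt(3)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(jitter, dict):
        jmap = {k: float(v) for k, v in jitter.items()}
        unknown = set(jmap) - set(JITTERABLE)
        if unknown:
            raise ValueError(f"unknown jitter fields: {sorted(unknown)}")
    else:
        jmap = {k: float(jitter) for k in JITTERABLE} if jitter else {}
    master = np.random.default_rng(spec.seed if seed is None else seed)
    samples = []
    for _ in range(n):
        sample_seed = int(master.integers(0, 2**63 - 1))
        srng = np.random.default_rng(sample_seed)
        overrides = {}
        for name in JITTERABLE:
            j = jmap.get(name, 0.0)
            if j > 0:
                overrides[name] = getattr(spec, name) * srng.uniform(1 - j, 1 + j)
        sub = dataclasses.replace(spec, **overrides) if overrides else spec
        samples.append(generate_phantom(sub, seed=int(srng.integers(0, 2**63 - 1))))
    return samples
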