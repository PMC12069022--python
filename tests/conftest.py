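"""Shared fixtures: synthetic geometries and a small trained ensemble."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lcseg.phantom import PhantomSpec, generate_dataset
from lcseg.volio import BinaryMask, HemiMaskPair, Volume


def centered_affine(shape, voxel_mm=0.375):
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = -(np.asarray(shape, dtype=float) - 1.0) / 2.0 * voxel_mm
    return affine


def rasterize_rod(shape, affine, anchor, direction, length, radius):
    """Independent cylinder rasterizer (projection formula, no polylines)."""
    ijk = np.stack(
        np.meshgrid(*(np.arange(s) for s in shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    rel = world - np.asarray(anchor, dtype=float)
    t = rel @ u
    radial = np.linalg.norm(rel - t[:, None] * u, axis=1)
    inside = (radial <= radius) & (np.abs(t) <= length / 2.0)
    return inside.reshape(shape).astype(np.uint8)


def rod_pair(
    shape=(48, 48, 48),
    voxel_mm=0.375,
    length=10.0,
    diameter=2.0,
    separation=7.0,
    rotation=None,
):
    """Two parallel rods (left at -x) as a HemiMaskPair, optionally rotated."""
    affine = centered_affine(shape, voxel_mm)
    R = np.eye(3) if rotation is None else rotation
    axis = R @ np.array([0.0, 0.0, 1.0])
    masks = {}
    for name, side in (("left", -1), ("right", +1)):
        anchor = R @ np.array([side * separation / 2.0, 0.0, 0.0])
        masks[name] = BinaryMask(
            rasterize_rod(shape, affine, anchor, axis, length, diameter / 2.0), affine
        )
    return HemiMaskPair(**masks), affine


def random_rotation(rng, max_deg):
    angles = rng.uniform(-max_deg, max_deg, size=3)
    return Rotation.from_euler("xyz", angles, degrees=True).as_matrix()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, unrotated, straight-tube phantom (exact constructions)."""
    from lcseg.phantom import generate_phantom

    spec = PhantomSpec(
        noise_sd=0.0, bias_amplitude=0.0, rotation_deg=0.0, lc_curvature_mm=0.0,
        true_cr=0.2, background_level=100.0,
    )
    return generate_phantom(spec, seed=11)


@pytest.fixture(scope="session")
def tiny_ensemble():
    """A small but genuinely trained ensemble shared across test modules.

    Trained on 10 default phantoms with a reduced patch size so the whole
    fixture builds in about a minute.
    """
    from lcseg.nets import NetConfig, train_ensemble

    spec = PhantomSpec(grid_shape=(64, 64, 64), seed=0)
    data = generate_dataset(12, spec, seed=1234, jitter=0.05)
    cfg = NetConfig(
        patch_size_vox=(48, 48, 48), train_crop_vox=32, max_epochs=4, patience=2,
        lr=2e-3, seed=7,
    )
    model = train_ensemble(data[:10], cfg)
    return model, data[10:], cfg
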