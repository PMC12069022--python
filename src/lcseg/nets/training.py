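"""Two-stage ensemble training: localization and segmentation members.

Five member networks per stage are trained on the five train/validation
partitions of :func:`make_final_split`; each member early-stops on its own
validation loss and the best-epoch parameters are kept.

Stage input representations:

* localization — the whole volume average-pooled by ``loc_downsample`` and
  z-scored; the target is the (hemisphere-union) LC mask dilated by
  ``loc_dilate_vox`` working-grid voxels, max-pooled to the working
  resolution. The dilation stabilizes the tiny target.
* segmentation — a z-scored cubic crop around the LC with small random
  translation jitter at training time; the target is the LC mask crop.

Both stages share the per-patch z-score normalization also applied at
inference, so no global intensity statistics need to be stored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from ..errors import TrainingError
from .folds import make_final_split
from .unet import Adam, UNet3D, dice_bce_loss

__all__ = [
    "NetConfig",
    "TrainingSample",
    "EnsembleModel",
    "train_member",
    "train_ensemble",
]

N_MEMBERS = 5
STAGES = ("localization", "segmentation")


@dataclass(frozen=True)
class NetConfig:
    """Hyperparameters shared by both network stages."""

    depth: int = 2
    base_channels: int = 8
    patch_size_vox: tuple = (64, 64, 64)
    loc_downsample: int = 4
    loc_dilate_vox: int = 2
    train_crop_vox: int = 32
    loss_name: str = "dice_bce"
    lr: float = 2e-3
    max_epochs: int = 12
    patience: int = 3
    batch_size: int = 1
    augment_shift_vox: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        div = 2**self.depth
        for s in self.patch_size_vox:
            if s % div:
                raise ValueError(f"patch_size_vox {self.patch_size_vox} must be divisible by {div}")
        if self.train_crop_vox % div:
            raise ValueError(f"train_crop_vox must be divisible by {div}")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.loss_name != "dice_bce":
            raise ValueError(f"unknown loss {self.loss_name!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        if "patch_size_vox" in d:
            d["patch_size_vox"] = tuple(d["patch_size_vox"])
        return cls(**d)


@dataclass
class TrainingSample:
    """One subject: an intensity grid and its ground-truth LC mask."""

    image: np.ndarray
    lc_mask: np.ndarray
    affine: np.ndarray = None

    @classmethod
    def from_phantom(cls, sample) -> "TrainingSample":
        return cls(
            image=sample.volume.data,
            lc_mask=sample.lc_truth.union.data,
            affine=sample.volume.affine,
        )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise TrainingError("constant input; cannot z-score")
    return ((x - x.mean()) / sd).astype(np.float32)


def block_pool(x: np.ndarray, f: int, reduce: str = "mean") -> np.ndarray:
    """Downsample by integer factor with block mean/max; pads by edge values."""
    if f == 1:
        return x.copy()
    pad = [(0, (-s) % f) for s in x.shape]
    if any(p[1] for p in pad):
        x = np.pad(x, pad, mode="edge")
    view = x.reshape(
        x.shape[0] // f, f, x.shape[1] // f, f, x.shape[2] // f, f
    )
    if reduce == "mean":
        return view.mean(axis=(1, 3, 5))
    return view.max(axis=(1, 3, 5))


def _pad_to_multiple(x: np.ndarray, m: int):
    """Zero-pad at the high end so each dim is a multiple of m."""
    pad = [(0, (-s) % m) for s in x.shape]
    return np.pad(x, pad), [p[1] for p in pad]


def loc_example(sample: TrainingSample, config: NetConfig):
    """(input, target) pair for the localization stage."""
    f = config.loc_downsample
    x = block_pool(sample.image.astype(np.float64), f, "mean")
    x = _zscore(x)
    x, _ = _pad_to_multiple(x, 2**config.depth)
    tgt = sample.lc_mask.astype(bool)
    if config.loc_dilate_vox > 0:
        tgt = binary_dilation(tgt, iterations=config.loc_dilate_vox)
    t = block_pool(tgt.astype(np.float64), f, "max")
    t, _ = _pad_to_multiple(t, 2**config.depth)
    return x, t


def _crop_bounds(center, size, shape):
    start = [int(round(c)) - size // 2 for c in center]
    return [(max(0, s), min(sh, s + size), s) for s, sh in zip(start, shape)]


def seg_crop(sample: TrainingSample, config: NetConfig, jitter=None):
    """Z-scored training crop around the LC centroid and its mask target."""
    size = config.train_crop_vox
    centroid = np.argwhere(sample.lc_mask).mean(axis=0)
    if jitter is not None:
        centroid = centroid + jitter
    x = np.zeros((size,) * 3, dtype=np.float64)
    t = np.zeros((size,) * 3, dtype=np.float64)
    bounds = _crop_bounds(centroid, size, sample.image.shape)
    src = tuple(slice(lo, hi) for lo, hi, _ in bounds)
    dst = tuple(slice(lo - s, hi - s) for lo, hi, s in bounds)
    x[dst] = sample.image[src]
    t[dst] = sample.lc_mask[src]
    return _zscore(x), t


def _stage_examples(stage, samples, config, rng=None, train=False):
    out = []
    for s in samples:
        if stage == "localization":
            out.append(loc_example(s, config))
        else:
            jitter = None
            if train and rng is not None and config.augment_shift_vox > 0:
                jitter = rng.integers(
                    -config.augment_shift_vox, config.augment_shift_vox + 1, size=3
                )
            out.append(seg_crop(s, config, jitter))
    return out


def train_member(stage, train, val, config: NetConfig, member_seed: int = 0):
    """Train one member network; returns (net, log).

    Early stopping: training halts once the validation loss has not
    improved for ``config.patience`` consecutive epochs; the parameters
    of the best validation epoch are restored.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    if not train or not val:
        raise ValueError("train and val sets must be nonempty")
    rng = np.random.default_rng(member_seed)
    net = UNet3D(
        base_channels=config.base_channels, depth=config.depth, seed=member_seed
    )
    opt = Adam(net, lr=config.lr)
    val_examples = _stage_examples(stage, val, config, train=False)
    static_train = None
    if stage == "localization":  # cheap, deterministic: build once
        static_train = _stage_examples(stage, train, config, train=False)

    def val_loss():
        losses = []
        for x, t in val_examples:
            p = net.forward(x, train=False)
            losses.append(dice_bce_loss(p, t)[0])
        return float(np.mean(losses))

    log = []
    best = {"loss": np.inf, "epoch": -1, "state": net.get_state()}
    stall = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        if static_train is None:
            examples = _stage_examples(stage, train, config, rng=rng, train=True)
        else:
            examples = static_train
        train_losses = []
        for i in order:
            x, t = examples[i]
            p = net.forward(x, train=True)
            loss, gz = dice_bce_loss(p, t)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            net.backward(gz)
            opt.step()
            train_losses.append(loss)
        vl = val_loss()
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(train_losses)), "val_loss": vl}
        )
        if vl < best["loss"] - 1e-6:
            best = {"loss": vl, "epoch": epoch, "state": net.get_state()}
            stall = 0
        else:
            stall += 1
            if stall > config.patience:
                break
    net.set_state(best["state"])
    log_summary = {"best_epoch": best["epoch"], "best_val_loss": best["loss"], "epochs": log}
    return net, log_summary


@dataclass
class EnsembleModel:
    """Five trained members per stage plus their shared configuration."""

    loc_members: list
    seg_members: list
    config: NetConfig
    train_norm_stats: dict = field(
        default_factory=lambda: {"scheme": "per_patch_zscore"}
    )
    version: str = "lcseg-1"
    training_logs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.loc_members) != N_MEMBERS or len(self.seg_members) != N_MEMBERS:
            raise ValueError(f"ensemble requires exactly {N_MEMBERS} members per stage")

    def save(self, path) -> None:
        """Single npz archive plus a JSON sidecar (config + version)."""
        arrays = {}
        for stage, members in (("loc", self.loc_members), ("seg", self.seg_members)):
            for i, net in enumerate(members):
                for key, arr in net.get_state().items():
                    arrays[f"{stage}{i}_{key}"] = arr
        np.savez_compressed(str(path), **arrays)
        sidecar = {
            "version": self.version,
            "config": dataclasses.asdict(self.config),
            "train_norm_stats": self.train_norm_stats,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        config = NetConfig.from_dict(sidecar["config"])
        npzpath = str(path)
        if not npzpath.endswith(".npz"):
            npzpath += ".npz"
        try:
            data = np.load(npzpath)
        except FileNotFoundError:
            data = np.load(str(path))
        members = {"loc": [], "seg": []}
        for stage in ("loc", "seg"):
            for i in range(N_MEMBERS):
                prefix = f"{stage}{i}_"
                state = {
                    k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)
                }
                net = UNet3D(
                    base_channels=config.base_channels, depth=config.depth, seed=0
                )
                net.set_state(state)
                members[stage].append(net)
        return cls(
            loc_members=members["loc"],
            seg_members=members["seg"],
            config=config,
            train_norm_stats=sidecar.get("train_norm_stats", {}),
            version=sidecar.get("version", "lcseg-1"),
        )


def train_ensemble(dataset, config: NetConfig) -> EnsembleModel:
    """Train the full two-stage five-member ensemble.

    ``dataset`` is a list of :class:`TrainingSample` (or objects accepted
    by ``TrainingSample.from_phantom``). Uses :func:`make_final_split` to
    derive the five train/validation partitions.
    """
    samples = [
        s if isinstance(s, TrainingSample) else TrainingSample.from_phantom(s)
        for s in dataset
    ]
    if len(samples) < N_MEMBERS:
        raise ValueError(f"need at least {N_MEMBERS} samples, got {len(samples)}")
    splits = make_final_split(len(samples), N_MEMBERS, seed=config.seed)
    members = {"localization": [], "segmentation": []}
    logs = {"localization": [], "segmentation": []}
    for stage in STAGES:
        for i, (tr_idx, va_idx) in enumerate(splits):
            net, log = train_member(
                stage,
                [samples[j] for j in tr_idx],
                [samples[j] for j in va_idx],
                config,
                member_seed=config.seed * 1000 + i + (0 if stage == "localization" else 500),
            )
            members[stage].append(net)
            logs[stage].append(log)
    return EnsembleModel(
        loc_members=members["localization"],
        seg_members=members["segmentation"],
        config=config,
        training_logs=logs,
    )
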