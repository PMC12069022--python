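import numpy as np
import pytest

from lcseg.errors import TrainingError
from lcseg.nets import (
    NetConfig,
    TrainingSample,
    UNet3D,
    dice_bce_loss,
    majority_vote,
    segment_patch,
    train_member,
)
from lcseg.nets.inference import localize
from lcseg.nets.training import EnsembleModel
from lcseg.nets.unet import Adam
from lcseg.phantom import PhantomSpec, generate_dataset
from lcseg.volio import BinaryMask, Volume

from conftest import centered_affine


class TestUNetCore:
    def test_gradient_check(self, rng):
        """Analytic backprop against central finite differences."""
        net = UNet3D(base_channels=2, depth=2, seed=3)
        x = rng.standard_normal((8, 8, 8)).astype(np.float32)
        t = (rng.random((8, 8, 8)) < 0.1).astype(np.float64)
        p = net.forward(x, train=True)
        _, gz = dice_bce_loss(p, t)
        net.backward(gz)
        params, grads = net.parameters(), net.gradients()

        def loss():
            return dice_bce_loss(net.forward(x, train=False), t)[0]

        check_rng = np.random.default_rng(0)
        checked = 0
        for pi in (0, 5, 10, len(params) - 2, len(params) - 1):
            flat, gflat = params[pi].reshape(-1), grads[pi].reshape(-1)
            for j in check_rng.integers(0, flat.size, size=3):
                eps = 1e-3
                old = flat[j]
                flat[j] = old + eps
                lp = loss()
                flat[j] = old - eps
                lm = loss()
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                # float32 forward passes limit attainable agreement
                assert num == pytest.approx(gflat[j], rel=5e-2, abs=5e-4)
                checked += 1
        assert checked == 15

    def test_shape_divisibility_enforced(self):
        net = UNet3D(base_channels=2, depth=2, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((10, 10, 10), np.float32))

    def test_state_round_trip(self, rng):
        net = UNet3D(base_channels=2, depth=1, seed=5)
        x = rng.standard_normal((8, 8, 8)).astype(np.float32)
        p1 = net.forward(x, train=False)
        other = UNet3D(base_channels=2, depth=1, seed=99)
        other.set_state(net.get_state())
        assert np.array_equal(other.forward(x, train=False), p1)

    def test_adam_reduces_loss(self, rng):
        net = UNet3D(base_channels=2, depth=1, seed=2)
        opt = Adam(net, lr=5e-3)
        x = rng.standard_normal((8, 8, 8)).astype(np.float32)
        t = np.zeros((8, 8, 8))
        t[2:5, 2:5, 2:5] = 1
        first = None
        for _ in range(30):
            p = net.forward(x)
            loss, gz = dice_bce_loss(p, t)
            if first is None:
                first = loss
            net.backward(gz)
            opt.step()
        assert loss < first * 0.5


class TestNetConfig:
    def test_patch_divisibility(self):
        with pytest.raises(ValueError):
            NetConfig(patch_size_vox=(30, 32, 32), depth=2)

    def test_patience_bound(self):
        with pytest.raises(ValueError):
            NetConfig(max_epochs=5, patience=5)


class TestMajorityVote:
    def _masks(self, arrays):
        return [BinaryMask(np.asarray(a, np.uint8), np.eye(4)) for a in arrays]

    def test_identical_masks_identity(self, rng):
        m = (rng.random((5, 5, 5)) < 0.4).astype(np.uint8)
        out = majority_vote(self._masks([m] * 5))
        assert np.array_equal(out.data, m)

    def test_vote_threshold(self):
        z = np.zeros((1, 1, 1))
        o = np.ones((1, 1, 1))
        assert majority_vote(self._masks([o, o, o, z, z])).data[0, 0, 0] == 1
        assert majority_vote(self._masks([o, o, z, z, z])).data[0, 0, 0] == 0

    def test_permutation_invariant(self, rng):
        arrays = [(rng.random((4, 4, 4)) < 0.5) for _ in range(5)]
        a = majority_vote(self._masks(arrays))
        b = majority_vote(self._masks(arrays[::-1]))
        assert np.array_equal(a.data, b.data)

    def test_counting_oracle(self, rng):
        arrays = [(rng.random((10, 10, 10)) < 0.5) for _ in range(5)]
        out = majority_vote(self._masks(arrays))
        stack = np.stack(arrays)
        for idx in zip(*np.unravel_index(range(0, 1000, 37), (10, 10, 10))):
            votes = int(stack[(slice(None),) + tuple(idx)].sum())
            assert out.data[tuple(idx)] == (1 if votes >= 3 else 0)

    def test_wrong_count(self, rng):
        with pytest.raises(ValueError):
            majority_vote(self._masks([np.zeros((2, 2, 2))] * 4))

    def test_grid_mismatch(self):
        masks = self._masks([np.zeros((2, 2, 2))] * 5)
        masks[3] = BinaryMask(np.zeros((3, 3, 3), np.uint8), np.eye(4))
        with pytest.raises(ValueError):
            majority_vote(masks)


def _tiny_dataset(n, seed=0):
    spec = PhantomSpec(grid_shape=(48, 48, 48), lc_length_mm=7.0,
                       inter_lc_distance_mm=6.0, ref_offset_frame=(0.0, -4.5, 1.5),
                       ref_region_shape_mm=(3.0, 2.0, 2.0), seed=seed)
    return [TrainingSample.from_phantom(s)
            for s in generate_dataset(n, spec, seed=seed, jitter=0.05)]


def _tiny_config(**kw):
    defaults = dict(train_crop_vox=24, patch_size_vox=(32, 32, 32),
                    max_epochs=6, patience=2, lr=3e-3, seed=1)
    defaults.update(kw)
    return NetConfig(**defaults)


class TestTrainMember:
    def test_early_stopping_halts(self):
        data = _tiny_dataset(3, seed=4)
        cfg = _tiny_config(max_epochs=50, patience=2)
        net, log = train_member("segmentation", data[:1], data[1:2], cfg, member_seed=1)
        n_epochs = len(log["epochs"])
        assert n_epochs < 50
        assert n_epochs >= log["best_epoch"] + 1

    def test_learning_sanity(self):
        data = _tiny_dataset(4, seed=5)
        cfg = _tiny_config(max_epochs=6, patience=3)
        net, log = train_member("segmentation", data[:3], data[3:], cfg, member_seed=2)
        assert log["epochs"][-1]["val_loss"] < log["epochs"][0]["val_loss"]
        assert log["best_val_loss"] <= log["epochs"][0]["val_loss"]

    def test_seeded_reproducibility(self):
        data = _tiny_dataset(3, seed=6)
        cfg = _tiny_config(max_epochs=3, patience=1)
        a = train_member("segmentation", data[:2], data[2:], cfg, member_seed=7)
        b = train_member("segmentation", data[:2], data[2:], cfg, member_seed=7)
        assert a[1]["best_epoch"] == b[1]["best_epoch"]
        assert a[1]["epochs"] == b[1]["epochs"]
        x = np.random.default_rng(0).standard_normal((24, 24, 24)).astype(np.float32)
        assert np.array_equal(a[0].forward(x, train=False), b[0].forward(x, train=False))

    def test_empty_sets_rejected(self):
        data = _tiny_dataset(2, seed=8)
        with pytest.raises(ValueError):
            train_member("segmentation", [], data, _tiny_config(), 0)
        with pytest.raises(ValueError):
            train_member("bogus_stage", data, data, _tiny_config(), 0)


class TestEnsemble:
    def test_member_count_and_split_contract(self, tiny_ensemble):
        model, _, _ = tiny_ensemble
        assert len(model.loc_members) == 5
        assert len(model.seg_members) == 5

    def test_serialization_round_trip(self, tiny_ensemble, tmp_path, rng):
        model, holdout, cfg = tiny_ensemble
        path = tmp_path / "model.lcseg"
        model.save(path)
        back = EnsembleModel.load(path)
        vol = holdout[0].volume
        from lcseg.pipeline import run_inference

        r1 = run_inference(model, vol)
        r2 = run_inference(back, vol)
        assert np.array_equal(r1.masks.left.data, r2.masks.left.data)
        assert np.array_equal(r1.masks.right.data, r2.masks.right.data)

    def test_too_few_samples(self):
        from lcseg.nets import train_ensemble

        with pytest.raises(ValueError):
            train_ensemble(_tiny_dataset(3, seed=1), _tiny_config())


class TestLocalize:
    def test_trained_centers_near_truth(self, tiny_ensemble):
        model, holdout, _ = tiny_ensemble
        for sample in holdout:
            loc = localize(model, sample.volume)
            for center, mask in (
                (loc.center_left, sample.lc_truth.left),
                (loc.center_right, sample.lc_truth.right),
            ):
                truth = np.argwhere(mask.data).mean(axis=0)
                assert np.linalg.norm(center - truth) <= 4.0

    def test_synthetic_probability_blobs(self):
        """Averaging identity: all members agree -> centers at blob centroids."""
        cfg = NetConfig(patch_size_vox=(16, 16, 16), train_crop_vox=16,
                        loc_downsample=1, max_epochs=2, patience=1)
        shape = (16, 16, 16)

        class _Stub:
            def __init__(self, logit_map):
                self._z = logit_map

            def forward(self, x, train=False):
                return 1.0 / (1.0 + np.exp(-self._z))

        z = np.full(shape, -10.0)
        z[4:7, 8, 8] = 10.0   # left blob (low x)
        z[11:14, 8, 8] = 10.0  # right blob
        members = [_Stub(z)] * 5
        model = EnsembleModel.__new__(EnsembleModel)
        model.loc_members = members
        model.seg_members = members
        model.config = cfg
        vol = Volume(np.random.default_rng(1).random(shape) + 1.0,
                     centered_affine(shape, 1.0))
        loc = localize(model, vol)
        assert not loc.used_fallback
        assert np.allclose(loc.center_left, [5, 8, 8], atol=0.5)
        assert np.allclose(loc.center_right, [12, 8, 8], atol=0.5)

    def test_three_of_five_survive_threshold(self):
        cfg = NetConfig(patch_size_vox=(16, 16, 16), train_crop_vox=16,
                        loc_downsample=1)
        shape = (16, 16, 16)

        class _Const:
            def __init__(self, p):
                self._p = np.asarray(p, dtype=float)

            def forward(self, x, train=False):
                return self._p

        on = np.full(shape, 1e-6)
        on[4:7, 8, 8] = 1.0
        on[11:14, 8, 8] = 1.0
        off = np.full(shape, 1e-6)
        members = [_Const(on)] * 3 + [_Const(off)] * 2  # average 0.6 at blobs
        model = EnsembleModel.__new__(EnsembleModel)
        model.loc_members = members
        model.seg_members = members
        model.config = cfg
        vol = Volume(np.random.default_rng(2).random(shape) + 1.0,
                     centered_affine(shape, 1.0))
        loc = localize(model, vol)
        assert not loc.used_fallback


class TestSegmentPatch:
    def test_all_agree_returns_member_mask(self, tiny_ensemble):
        model, holdout, cfg = tiny_ensemble
        from lcseg.nets.training import seg_crop, TrainingSample
        from lcseg.pipeline import extract_patch, normalize_patch

        sample = holdout[0]
        centroid = np.argwhere(sample.lc_truth.union.data).mean(axis=0)
        patch, _ = extract_patch(sample.volume, centroid, cfg.patch_size_vox)
        patch = normalize_patch(patch)
        voted, members = segment_patch(model, patch, return_members=True)
        votes = np.sum([m.data for m in members], axis=0)
        assert np.array_equal(voted.data, (votes >= 3).astype(np.uint8))

    def test_empty_probability_patch(self, tiny_ensemble):
        model, _, cfg = tiny_ensemble
        import copy

        cold = copy.deepcopy(model)
        for net in cold.seg_members:
            net.head.b[:] = -50.0  # force probabilities ~ 0
        patch = Volume(
            np.random.default_rng(3).standard_normal(cfg.patch_size_vox),
            centered_affine(cfg.patch_size_vox, 0.375),
        )
        out = segment_patch(cold, patch)
        assert out.n_voxels == 0

    def test_shape_mismatch(self, tiny_ensemble):
        model, _, _ = tiny_ensemble
        bad = Volume(np.zeros((16, 16, 16)), np.eye(4))
        with pytest.raises(ValueError):
            segment_patch(model, bad)
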