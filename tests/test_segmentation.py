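"""Mini-CT extraction, clip ranges, augmentation, stacks, post-processing."""

import numpy as np
import pytest

from csiseg.io_preproc import CTVolume
from csiseg.localization import ROI3D
from csiseg.segmentation import (
    ClipRange,
    HEAD_CLIP,
    ModelVariant,
    TrainConfig,
    aggregate_clip_range,
    augment_pair,
    build_model,
    compute_clip_range,
    crop_mask_to_mini,
    extract_mini_ct,
    head_clip_range,
    largest_component,
    load_checkpoint,
    make_2p5d_stacks,
    paste_back,
    predict_mask,
    save_checkpoint,
    train_segmenter,
)

from conftest import random_mask


def _flood_fill_26(mask: np.ndarray) -> list[set]:
    """Independent exhaustive flood fill under 26-connectivity."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    Z, Y, X = mask.shape
    nbrs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
            for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            comp.add((z, y, x))
            for dz, dy, dx in nbrs:
                q = (z + dz, y + dy, x + dx)
                if (0 <= q[0] < Z and 0 <= q[1] < Y and 0 <= q[2] < X
                        and mask[q] and not seen[q]):
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


class TestClipRange:
    def test_percentiles_match_direct_computation(self):
        """Inside values span 0..99, the rim 50..149; the rule takes the
        lower P10 and the higher P90."""
        arr = np.zeros((1, 20, 20), dtype=np.float32)
        mask = np.zeros_like(arr, dtype=bool)
        mask[0, 5:15, 5:15] = True  # 100 voxels
        arr[mask] = np.arange(100)
        rim_box = np.zeros_like(mask)
        rim_box[0, 3:17, 3:17] = True
        rim = rim_box & ~mask
        arr[rim] = np.linspace(50, 149, rim.sum())
        vol = CTVolume(arr, (5.0, 1.0, 1.0))  # large dz keeps the rim in-plane
        cr = compute_clip_range(vol, mask, rim_mm=2.0)
        inside = arr[mask]
        assert cr.lo == pytest.approx(np.percentile(inside, 10), abs=2.0)
        assert cr.hi >= np.percentile(inside, 90)

    def test_constant_input_widened(self):
        arr = np.full((3, 8, 8), 40.0, dtype=np.float32)
        mask = np.zeros_like(arr, dtype=bool)
        mask[1, 2:6, 2:6] = True
        cr = compute_clip_range(CTVolume(arr, (1, 1, 1)), mask)
        assert cr.lo == 39.0 and cr.hi == 41.0

    def test_mask_filling_volume_uses_inside_only(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 100, size=(4, 4, 4)).astype(np.float32)
        cr = compute_clip_range(CTVolume(arr, (1, 1, 1)), np.ones_like(arr, bool))
        assert cr.lo == pytest.approx(np.percentile(arr, 10), abs=1e-4)
        assert cr.hi == pytest.approx(np.percentile(arr, 90), abs=1e-4)

    def test_head_window_is_fixed(self):
        cr = head_clip_range("lens_l")
        assert (cr.lo, cr.hi) == HEAD_CLIP and cr.source == "head_fixed"

    def test_aggregate_is_the_median(self):
        cases = [ClipRange(10, 100), ClipRange(20, 110), ClipRange(30, 120)]
        agg = aggregate_clip_range(cases)
        assert agg.lo == 20 and agg.hi == 110
        single = aggregate_clip_range([ClipRange(5, 50, "k")])
        assert (single.lo, single.hi) == (5, 50)
        with pytest.raises(ValueError):
            aggregate_clip_range([])

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            ClipRange(10, 10)


class TestMiniCT:
    def _vol(self, rng):
        return CTVolume(rng.uniform(-200, 300, (20, 24, 28)).astype(np.float32),
                        (1, 1, 1), "P")

    def test_exact_size_roi_no_padding_unit_range(self, rng):
        vol = self._vol(rng)
        roi = ROI3D((2, 10), (4, 12), (6, 14))
        mini = extract_mini_ct(vol, roi, "k", (8, 8, 8), ClipRange(-100, 100))
        assert mini.pad_before == (0, 0, 0)
        assert mini.voxels.min() >= 0.0 and mini.voxels.max() <= 1.0

    def test_all_lo_crop_is_zero(self):
        vol = CTVolume(np.full((6, 6, 6), -500.0), (1, 1, 1))
        mini = extract_mini_ct(vol, ROI3D((0, 4), (0, 4), (0, 4)), "k",
                               (6, 6, 6), ClipRange(-100, 100))
        assert (mini.voxels == 0).all()

    def test_normalization_is_monotone(self, rng):
        vol = self._vol(rng)
        roi = ROI3D((0, 8), (0, 8), (0, 8))
        mini = extract_mini_ct(vol, roi, "k", (8, 8, 8), ClipRange(-100, 100))
        crop = np.clip(vol.voxels[roi.slices()], -100, 100)
        order = np.argsort(crop.ravel(), kind="stable")
        normd = mini.voxels.ravel()[order]
        assert (np.diff(normd) >= -1e-7).all()

    def test_roi_exceeding_uniform_size_rejected(self, rng):
        vol = self._vol(rng)
        with pytest.raises(ValueError, match="exceeds"):
            extract_mini_ct(vol, ROI3D((0, 10), (0, 10), (0, 10)), "k",
                            (8, 12, 12), ClipRange(0, 1))

    def test_extract_paste_round_trip(self, rng):
        """extract -> identity model -> paste_back reproduces the reference
        mask exactly when the ROI contains it."""
        vol = self._vol(rng)
        mask = np.zeros(vol.shape, bool)
        mask[5:9, 7:12, 9:15] = True
        roi = ROI3D((4, 10), (6, 13), (8, 16))
        mini = extract_mini_ct(vol, roi, "k", (10, 12, 12), ClipRange(-100, 100))
        mini_mask = crop_mask_to_mini(mask, mini)
        back = paste_back(mini_mask, mini, vol.shape)
        np.testing.assert_array_equal(back, mask)

    def test_empty_mini_mask_pastes_empty(self, rng):
        vol = self._vol(rng)
        roi = ROI3D((0, 4), (0, 4), (0, 4))
        mini = extract_mini_ct(vol, roi, "k", (6, 8, 8), ClipRange(0, 1))
        back = paste_back(np.zeros(mini.voxels.shape, bool), mini, vol.shape)
        assert not back.any()


class TestAugment:
    CFG = TrainConfig(seed=0, augment_prob=0.5)

    def test_probability_zero_is_identity(self, rng):
        cfg = TrainConfig(augment_prob=0.0)
        img = rng.uniform(size=(4, 12, 12)).astype(np.float32)
        msk = random_mask(rng, (4, 12, 12))
        out_i, out_m = augment_pair(img, msk, cfg, rng)
        np.testing.assert_array_equal(out_i, img)
        np.testing.assert_array_equal(out_m, msk)

    def test_fixed_seed_reproducible(self):
        rng_a = np.random.default_rng(9)
        rng_b = np.random.default_rng(9)
        base = np.random.default_rng(0)
        img = base.uniform(size=(4, 16, 16)).astype(np.float32)
        msk = base.uniform(size=(4, 16, 16)) > 0.6
        a = augment_pair(img, msk, self.CFG, rng_a)
        b = augment_pair(img, msk, self.CFG, rng_b)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_mask_stays_binary_and_shapes_match(self, rng):
        img = rng.uniform(size=(3, 20, 20)).astype(np.float32)
        msk = random_mask(rng, (3, 20, 20))
        for _ in range(6):
            oi, om = augment_pair(img, msk, self.CFG, rng)
            assert oi.shape == img.shape and om.dtype == bool

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_pair(np.zeros((2, 4, 4), np.float32),
                         np.zeros((2, 4, 5), bool), self.CFG, rng)


class TestStacks:
    def test_single_slice_replicates_three_times(self):
        v = np.random.default_rng(0).uniform(size=(1, 4, 4))
        s = make_2p5d_stacks(v)
        assert s.shape == (1, 3, 4, 4)
        np.testing.assert_array_equal(s[0, 0], s[0, 1])
        np.testing.assert_array_equal(s[0, 1], s[0, 2])

    def test_interior_slice_sandwich(self):
        v = np.random.default_rng(1).uniform(size=(5, 3, 3))
        s = make_2p5d_stacks(v)
        for k in range(1, 4):
            np.testing.assert_array_equal(s[k, 0], v[k - 1])
            np.testing.assert_array_equal(s[k, 1], v[k])
            np.testing.assert_array_equal(s[k, 2], v[k + 1])
        np.testing.assert_array_equal(s[0, 0], v[0])
        np.testing.assert_array_equal(s[-1, 2], v[-1])


class TestBuildModel:
    def test_variant_channel_contracts(self):
        cfg = TrainConfig(widths=(4, 8))
        assert build_model("basic_unet", cfg).in_channels == 1
        assert build_model("unet_2p5d", cfg).in_channels == 3
        attn = build_model("attention_unet", cfg)
        basic = build_model("basic_unet", cfg)
        assert attn.n_parameters() > basic.n_parameters()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model("resnet")


class TestPredictMask:
    def test_threshold_agrees_with_elementwise_oracle(self, rng):
        model = build_model("basic_unet", TrainConfig(widths=(4, 8), seed=2))
        vol = CTVolume(rng.uniform(-50, 50, (4, 16, 16)).astype(np.float32), (1, 1, 1))
        mini = extract_mini_ct(vol, ROI3D((0, 4), (0, 16), (0, 16)), "k",
                               (4, 16, 16), ClipRange(-50, 50))
        pred = predict_mask(model, mini, 0.5)
        probs = np.concatenate([
            model.predict_proba(mini.voxels[k][None, None])[:, 0]
            for k in range(4)])
        np.testing.assert_array_equal(pred, probs > 0.5)


class TestLargestComponent:
    def test_corner_touching_voxels_are_one_component(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = m[1, 1, 1] = True  # touch only at a corner
        out = largest_component(m)
        assert out.sum() == 2

    def test_keeps_the_larger_blob(self):
        m = np.zeros((10, 10, 10), bool)
        m[0:1, 0:2, 0:5] = True  # 10 voxels
        m[5:6, 5:6, 5:8] = True  # 3 voxels
        out = largest_component(m)
        assert out.sum() == 10 and not out[5, 5, 5]

    def test_empty_in_empty_out(self):
        out = largest_component(np.zeros((3, 3, 3), bool))
        assert not out.any()

    def test_idempotent_and_never_grows(self, rng):
        for _ in range(10):
            m = random_mask(rng, (12, 12, 12), p=0.2)
            once = largest_component(m)
            assert once.sum() <= m.sum()
            np.testing.assert_array_equal(largest_component(once), once)

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            m = random_mask(rng, (8, 8, 8), p=float(rng.uniform(0.05, 0.4)))
            comps = _flood_fill_26(m)
            out = largest_component(m)
            if not comps:
                assert not out.any()
                continue
            best = max(len(c) for c in comps)
            winners = [c for c in comps if len(c) == best]
            expected = min(winners, key=lambda c: min(c))
            assert set(map(tuple, np.argwhere(out))) == expected

    def test_equal_size_tie_breaks_lexicographically(self):
        m = np.zeros((5, 5, 5), bool)
        m[0, 0, 0] = True
        m[4, 4, 4] = True
        out = largest_component(m)
        assert out[0, 0, 0] and not out[4, 4, 4]


class TestTrainSegmenter:
    def _toy_dataset(self, rng, n=4):
        data = []
        for _ in range(n):
            img = rng.normal(0.3, 0.05, size=(4, 16, 16)).astype(np.float32)
            msk = np.zeros((4, 16, 16), bool)
            cy, cx = rng.integers(5, 11, 2)
            yy, xx = np.mgrid[:16, :16]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 < 16
            img[:, disk] += 0.5
            msk[:, disk] = True
            vol = CTVolume(img, (1, 1, 1))
            mini = extract_mini_ct(vol, ROI3D((0, 4), (0, 16), (0, 16)), "t",
                                   (4, 16, 16), ClipRange(0.0, 1.0))
            data.append((mini, msk))
        return data

    def test_loss_decreases_on_easy_task(self, rng):
        data = self._toy_dataset(rng)
        res = train_segmenter("basic_unet",
                              data, TrainConfig(seed=4, epochs=8, widths=(4, 8),
                                                augment_prob=0.0))
        assert np.isfinite(res.loss_trace).all()
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_segmenter("basic_unet", [], TrainConfig())

    def test_training_is_deterministic(self, rng):
        data = self._toy_dataset(rng, n=2)
        cfg = TrainConfig(seed=6, epochs=3, widths=(4, 8))
        a = train_segmenter("basic_unet", data, cfg)
        b = train_segmenter("basic_unet", data, cfg)
        for pa, pb in zip(a.model.parameters(), b.model.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        data = self._toy_dataset(rng, n=2)
        res = train_segmenter("unet_2p5d", data,
                              TrainConfig(seed=6, epochs=2, widths=(4, 8)))
        save_checkpoint(tmp_path / "m.npz", res, "kidney_l",
                        ClipRange(-100, 100, "kidney_l"), (4, 16, 16))
        model, variant, organ, clip, uniform, thr = load_checkpoint(tmp_path / "m.npz")
        assert variant == ModelVariant.unet_2p5d and organ == "kidney_l"
        assert (clip.lo, clip.hi) == (-100, 100) and uniform == (4, 16, 16)
        mini = data[0][0]
        np.testing.assert_array_equal(
            predict_mask(model, mini, thr, variant),
            predict_mask(res.model, mini, thr, res.variant))
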