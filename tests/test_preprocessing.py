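"""Intensity chain, 2.5D stacking, augmentation, splits, and NIfTI I/O."""

import numpy as np
import pytest

from hepaseg.preprocessing import (Slice25DSample, augment, clahe_equalize,
                                   load_nifti, masks_from_labels,
                                   minmax_normalize, preprocess_volume,
                                   save_nifti, select_slice_indices,
                                   split_volumes, stack_25d, window_bounds,
                                   window_clip)


class TestWindowing:
    def test_soft_tissue_bounds(self):
        assert window_bounds() == (-60.0, 140.0)

    def test_clip_values(self):
        v = np.array([-500.0, -60.0, 40.0, 140.0, 300.0])
        np.testing.assert_array_equal(window_clip(v),
                                      [-60.0, -60.0, 40.0, 140.0, 140.0])

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            window_clip(np.zeros(3), width=0.0)

    def test_minmax_uses_fixed_window_bounds(self):
        v = np.array([-60.0, 40.0, 140.0])
        np.testing.assert_allclose(minmax_normalize(v), [0.0, 0.5, 1.0])

    def test_chain_output_range(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(40.0, 300.0, size=(4, 64, 64)).astype(np.float32)
        out = preprocess_volume(vol)
        assert out.shape == vol.shape and out.dtype == np.float32
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestCLAHE:
    def test_constant_slice_passthrough(self):
        flat = np.full((32, 32), 0.7, dtype=np.float32)
        np.testing.assert_array_equal(clahe_equalize(flat), flat)

    def test_increases_local_contrast_of_low_contrast_detail(self):
        rng = np.random.default_rng(0)
        img = 0.5 + 0.02 * rng.standard_normal((64, 64))
        img[24:40, 24:40] += 0.03
        out = clahe_equalize(np.clip(img, 0, 1).astype(np.float32))
        assert out.std() > img.std()


class TestStacking:
    VOL = np.arange(5 * 4 * 4, dtype=np.float32).reshape(5, 4, 4) / 80.0
    LAB = np.zeros((5, 4, 4), dtype=np.uint8)
    LAB[2, 1:3, 1:3] = 1
    LAB[2, 2, 2] = 2

    def test_masks_from_labels(self):
        m = masks_from_labels(self.LAB[2])
        assert m.shape == (2, 4, 4)
        assert m[0].sum() == 4, "liver mask must include tumor voxels"
        assert m[1].sum() == 1

    def test_interior_slice_neighbors(self):
        s = stack_25d(self.VOL, self.LAB, 2)
        np.testing.assert_array_equal(
            s.image, np.stack([self.VOL[1], self.VOL[2], self.VOL[3]]))

    def test_edge_replication(self):
        first = stack_25d(self.VOL, self.LAB, 0)
        np.testing.assert_array_equal(first.image[0], first.image[1])
        last = stack_25d(self.VOL, self.LAB, 4)
        np.testing.assert_array_equal(last.image[1], last.image[2])

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            stack_25d(self.VOL, self.LAB, 5)

    def test_sample_validation(self):
        with pytest.raises(ValueError):
            Slice25DSample(image=np.zeros((2, 4, 4)),
                           target=np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            Slice25DSample(image=np.zeros((3, 4, 4)),
                           target=np.zeros((2, 5, 5)))


class TestAugmentation:
    def _sample(self, rng, hw=32):
        img = rng.random((3, hw, hw)).astype(np.float32)
        tgt = (rng.random((2, hw, hw)) > 0.7).astype(np.float32)
        return Slice25DSample(image=img, target=tgt)

    def test_deterministic_for_fixed_state(self, rng):
        s = self._sample(rng)
        a = augment(s, np.random.default_rng(7), crop_size=16)
        b = augment(s, np.random.default_rng(7), crop_size=16)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.target, b.target)

    def test_crop_shape_and_geometry_consistency(self, rng):
        s = self._sample(rng)
        out = augment(s, np.random.default_rng(3), crop_size=16)
        assert out.image.shape == (3, 16, 16)
        assert out.target.shape == (2, 16, 16)
        # masks stay binary and co-transformed values stay drawn from source
        assert set(np.unique(out.target)) <= {0.0, 1.0}

    def test_crop_pads_small_inputs(self, rng):
        s = self._sample(rng, hw=8)
        out = augment(s, np.random.default_rng(0), crop_size=16)
        assert out.image.shape == (3, 16, 16)

    def test_preserves_foreground_fraction_without_crop(self, rng):
        s = self._sample(rng)
        out = augment(s, np.random.default_rng(11), crop_size=None)
        assert out.target.sum() == s.target.sum()


class TestSlicePoolAndSplit:
    def test_select_keeps_all_liver_slices(self):
        lab = np.zeros((6, 8, 8), dtype=np.uint8)
        lab[1, 2, 2] = 1
        lab[4, 3, 3] = 2
        idx = select_slice_indices(lab, np.random.default_rng(0),
                                   empty_keep_fraction=0.0)
        assert idx == [1, 4]

    def test_empty_keep_fraction_one_keeps_everything(self):
        lab = np.zeros((6, 8, 8), dtype=np.uint8)
        idx = select_slice_indices(lab, np.random.default_rng(0),
                                   empty_keep_fraction=1.0)
        assert idx == list(range(6))

    def test_split_partition(self):
        tr, va = split_volumes(10, seed=0, val_fraction=0.2)
        assert len(tr) == 8 and len(va) == 2
        assert sorted(tr + va) == list(range(10))

    def test_split_deterministic(self):
        assert split_volumes(20, 3) == split_volumes(20, 3)
        assert split_volumes(20, 3) != split_volumes(20, 4)


class TestNiftiIO:
    def test_roundtrip(self, tmp_path):
        vol = np.random.default_rng(0).normal(
            size=(3, 5, 7)).astype(np.float32)
        path = tmp_path / "vol.nii.gz"
        save_nifti(path, vol)
        back = load_nifti(path)
        assert back.shape == (3, 5, 7)
        np.testing.assert_allclose(back, vol, rtol=1e-6)
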