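import numpy as np
import pytest

from hemiclass import (BrainVolume, flip_lr, make_common_mask, read_volume,
                       split_hemispheres, write_volume)
from conftest import make_pair


def canonical_whole(values):
    """Whole-brain volume whose x axis is centred on the midplane x=0."""
    values = np.asarray(values, float)
    aff = np.eye(4)
    aff[0, 3] = -(values.shape[0] / 2 - 0.5)
    return BrainVolume(values, aff, side="whole")


class TestReadWrite:
    def test_round_trip_preserves_values_and_affine(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = BrainVolume(rng.random((4, 4, 4)), np.diag([2.0, 2.0, 2.0, 1.0]))
        write_volume(vol, tmp_path / "v.nii.gz")
        back = read_volume(tmp_path / "v.nii.gz")
        np.testing.assert_allclose(back.values, vol.values, rtol=1e-6)
        np.testing.assert_array_equal(back.affine, vol.affine)
        assert back.side == "whole"

    def test_uniform_image_loads_faithfully(self, tmp_path):
        vol = BrainVolume(np.ones((4, 4, 4)))
        write_volume(vol, tmp_path / "ones.nii")
        back = read_volume(tmp_path / "ones.nii")
        assert back.values.size == 64
        assert np.all(back.values == 1.0)

    def test_4d_series_rejected(self, tmp_path):
        import nibabel as nib
        img = nib.Nifti1Image(np.zeros((3, 3, 3, 5), dtype=np.float32), np.eye(4))
        nib.save(img, str(tmp_path / "series.nii.gz"))
        with pytest.raises(ValueError, match="expected 3-D volume"):
            read_volume(tmp_path / "series.nii.gz")


class TestSplit:
    def test_even_split_shapes(self):
        vol = canonical_whole(np.random.default_rng(1).random((10, 6, 6)))
        left, right = split_hemispheres(vol, 5)
        assert left.values.shape == (5, 6, 6)
        assert right.values.shape == (5, 6, 6)
        assert left.side == "left" and right.side == "right"

    def test_split_then_reassemble(self):
        vals = np.random.default_rng(2).random((8, 4, 4))
        vol = canonical_whole(vals)
        left, right = split_hemispheres(vol, 4)
        re = np.concatenate([left.values, right.values], axis=0)
        np.testing.assert_array_equal(re, vals)

    @pytest.mark.parametrize("midline", [0, 10, -1])
    def test_midline_out_of_range(self, midline):
        vol = canonical_whole(np.zeros((10, 4, 4)))
        with pytest.raises(ValueError, match="midline_index"):
            split_hemispheres(vol, midline)

    def test_unequal_halves_rejected_with_pad_advice(self):
        vol = canonical_whole(np.zeros((10, 4, 4)))
        with pytest.raises(ValueError, match="pad"):
            split_hemispheres(vol, 4)

    def test_whole_required(self):
        hemi = BrainVolume(np.zeros((4, 4, 4)), side="left")
        with pytest.raises(ValueError):
            split_hemispheres(hemi, 2)

    def test_negative_x_storage_order(self):
        """Left/right identification follows world axes, not array order."""
        vals = np.random.default_rng(3).random((10, 4, 4))
        aff = np.eye(4)
        aff[0, 0] = -1.0          # increasing index moves toward world -x
        aff[0, 3] = 10 / 2 - 0.5
        vol = BrainVolume(vals, aff, side="whole")
        left, right = split_hemispheres(vol, 5)
        # world-left half is now stored in the second array block
        np.testing.assert_array_equal(left.values, vals[5:])
        np.testing.assert_array_equal(right.values, vals[:5])


class TestFlip:
    def hemi(self, vals):
        aff = np.eye(4)
        aff[0, 3] = -float(np.asarray(vals).shape[0]) + 0.5
        return BrainVolume(np.asarray(vals, float), aff, side="left")

    def test_double_flip_identity(self):
        h = self.hemi(np.random.default_rng(4).random((5, 3, 3)))
        back = flip_lr(flip_lr(h))
        np.testing.assert_array_equal(back.values, h.values)
        np.testing.assert_array_equal(back.affine, h.affine)

    def test_index_reversal(self):
        vals = np.zeros((6, 2, 2))
        vals[0, 0, 0] = 1.0
        flipped = flip_lr(self.hemi(vals))
        assert flipped.values[5, 0, 0] == 1.0
        assert flipped.values.sum() == 1.0

    def test_symmetric_hemisphere_unchanged(self):
        vals = np.zeros((5, 2, 2))
        vals[[0, 2, 4]] = 1.0     # symmetric about the central x index
        flipped = flip_lr(self.hemi(vals))
        np.testing.assert_array_equal(flipped.values, vals)

    def test_flip_lands_on_right_homologue(self):
        """Flipping the left half of a symmetric-grid volume aligns its voxel
        (i,j,k) with world position of right voxel (i,j,k)."""
        vol_vals = np.random.default_rng(5).random((10, 3, 3))
        vol = canonical_whole(vol_vals)
        left, right = split_hemispheres(vol, 5)
        mirrored = flip_lr(left)
        np.testing.assert_allclose(mirrored.affine, right.affine)
        # value check: mirrored voxel i came from left voxel extent-1-i
        np.testing.assert_array_equal(mirrored.values, left.values[::-1])

    def test_side_contract(self):
        right = BrainVolume(np.zeros((4, 2, 2)), side="right")
        with pytest.raises(ValueError):
            flip_lr(right)


class TestCommonMask:
    def test_all_ones_gives_full_mask(self):
        pairs = [make_pair(np.ones((3, 3, 3)), np.ones((3, 3, 3)), f"s{i}")
                 for i in range(2)]
        mask = make_common_mask(pairs, 0.0)
        assert mask.values.sum() == 27

    def test_zero_hemisphere_empties_mask(self):
        pairs = [make_pair(np.zeros((3, 3, 3)), np.ones((3, 3, 3)))]
        with pytest.raises(ValueError, match="no voxels survive"):
            make_common_mask(pairs, 0.0)

    def test_shared_suprathreshold_voxel(self):
        a = np.zeros((3, 3, 3)); a[1, 1, 1] = 1.0
        b = np.zeros((3, 3, 3)); b[1, 1, 1] = 1.0; b[0, 0, 0] = 1.0
        pairs = [make_pair(a, a, "s0"), make_pair(b, b, "s1")]
        mask = make_common_mask(pairs, 0.5)
        assert mask.values.sum() == 1
        assert mask.values[1, 1, 1] == 1
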