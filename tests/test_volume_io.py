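"""Volume I/O and the preprocessing chain (resample, pad/crop, normalize,
brain mask, restore-to-native)."""

import nibabel as nib
import numpy as np
import pytest

from biasfield.phantom import PhantomSpec, generate_phantom
from biasfield.volume import (Mask, PreprocessRecord, Volume,
                              compute_brain_mask, invert_pad_crop,
                              minmax_normalize, pad_crop_to_shape, preprocess,
                              read_volume, resample_volume, restore_to_native,
                              write_volume)


class TestIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        vol = Volume(rng.random((8, 8, 8)), spacing=(1.0, 1.0, 1.2))
        p = tmp_path / "v.nii.gz"
        write_volume(vol, p)
        back = read_volume(p)
        assert np.max(np.abs(back.data - vol.data)) == 0
        assert back.spacing == pytest.approx(vol.spacing, abs=1e-6)

    def test_ones_round_trip(self, tmp_path):
        vol = Volume(np.ones((16, 16, 16)))
        p = tmp_path / "ones.nii"
        write_volume(vol, p)
        back = read_volume(p)
        assert np.array_equal(back.data, vol.data)

    def test_4d_image_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3)), np.eye(4))
        p = tmp_path / "fourd.nii"
        nib.save(img, str(p))
        with pytest.raises(ValueError, match="3D"):
            read_volume(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii")

    def test_nan_rejected_before_write(self, tmp_path):
        vol = Volume(np.ones((4, 4, 4)))
        vol.data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            write_volume(vol, tmp_path / "bad.nii")

    def test_anisotropic_affine_survives(self, tmp_path, rng):
        aff = np.diag([1.0, 1.0, 1.2, 1.0])
        aff[:3, 3] = [5.0, -3.0, 2.0]
        vol = Volume(rng.random((6, 6, 6)), spacing=(1, 1, 1.2), affine=aff)
        p = tmp_path / "aniso.nii"
        write_volume(vol, p)
        back = read_volume(p)
        # independent header inspection
        hdr = nib.load(str(p))
        assert np.allclose(hdr.affine, aff)
        assert np.allclose(back.affine, aff)
        assert back.spacing == pytest.approx((1, 1, 1.2), abs=1e-6)


class TestResample:
    @pytest.mark.parametrize("n,src,tgt,expected", [
        (128, 1.0, 2.0, 64),   # grid arithmetic round(128*1/2)
        (10, 1.0, 3.0, 3),     # round(3.33)
        (11, 2.0, 1.0, 22),
        (7, 1.0, 2.0, 4),      # round-half-away: round(3.5) = 4
    ])
    def test_output_shape_arithmetic(self, n, src, tgt, expected):
        vol = Volume(np.zeros((n, 4, 4)), spacing=(src, 1, 1))
        out = resample_volume(vol, (tgt, 1, 1))
        assert out.shape[0] == expected

    def test_constant_preserved(self):
        vol = Volume(np.full((12, 12, 12), 3.25), spacing=(1, 1, 1))
        out = resample_volume(vol, (2.5, 1.7, 0.9))
        assert np.allclose(out.data, 3.25)

    def test_identity_spacing(self, rng):
        vol = Volume(rng.random((10, 10, 10)))
        out = resample_volume(vol, (1, 1, 1))
        assert np.allclose(out.data, vol.data, atol=1e-12)

    def test_nearest_keeps_binary(self):
        vol = Volume((np.arange(8 ** 3).reshape(8, 8, 8) % 2).astype(float))
        out = resample_volume(vol, (2, 2, 2), mode="nearest")
        assert set(np.unique(out.data)) <= {0.0, 1.0}

    def test_nonpositive_spacing_rejected(self):
        vol = Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample_volume(vol, (0, 1, 1))


class TestPadCrop:
    def test_pad_centers_content(self):
        vol = Volume(np.ones((64, 64, 64)))
        out, rec = pad_crop_to_shape(vol, (128, 128, 128))
        assert out.shape == (128, 128, 128)
        assert rec.pad_offsets == ((32, 32),) * 3
        assert np.all(out.data[:32] == 0) and np.all(out.data[32:96, 32:96, 32:96] == 1)

    def test_crop_records_offsets(self, rng):
        vol = Volume(rng.random((34, 34, 34)))
        out, rec = pad_crop_to_shape(vol, (32, 32, 32))
        assert out.shape == (32, 32, 32)
        assert rec.crop_offsets == ((1, 1),) * 3

    @pytest.mark.parametrize("shape", [(16, 16, 16), (20, 10, 16), (33, 15, 8)])
    def test_inversion_identity_on_overlap(self, rng, shape):
        vol = Volume(rng.random(shape))
        out, rec = pad_crop_to_shape(vol, (16, 16, 16))
        back = invert_pad_crop(out, rec)
        assert back.shape == vol.shape
        sl = tuple(slice(c0, s - c1) for (c0, c1), s in
                   zip(rec.crop_offsets, shape))
        assert np.array_equal(back.data[sl], vol.data[sl])

    def test_shape_mismatch_raises(self, rng):
        vol = Volume(rng.random((16, 16, 16)))
        _, rec = pad_crop_to_shape(vol, (32, 32, 32))
        with pytest.raises(ValueError, match="inconsistent"):
            invert_pad_crop(Volume(np.zeros((8, 8, 8))), rec)


class TestNormalize:
    def test_all_ones(self):
        out, rec = minmax_normalize(Volume(np.ones((8, 8, 8))))
        assert np.allclose(out.data, 1.0)
        assert rec.norm_xmax == pytest.approx(1.0)

    def test_values_above_p99_clip_to_one(self, rng):
        data = rng.random((10, 10, 10))
        data[0, 0, 0] = 100.0  # far above the 99th percentile
        out, _ = minmax_normalize(Volume(data))
        assert out.data[0, 0, 0] == 1.0
        assert out.data.max() == 1.0 and out.data.min() >= 0.0

    def test_ramp_against_sort_based_percentile(self):
        vals = np.linspace(0, 100, 1000)
        vol = Volume(vals.reshape(10, 10, 10))
        out, rec = minmax_normalize(vol)
        # independent sort-based linear-interpolation percentile
        s = np.sort(vals)
        pos = 0.99 * (len(s) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        p99 = s[lo] + (pos - lo) * (s[hi] - s[lo])
        assert rec.norm_xmax == pytest.approx(p99, rel=1e-12)
        assert np.allclose(out.data, np.clip(vals / p99, 0, 1).reshape(10, 10, 10))

    def test_degenerate_image_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(Volume(np.zeros((6, 6, 6))))


class TestBrainMask:
    def test_covers_phantom_support(self):
        pspec = PhantomSpec(shape=(32, 32, 32), geom_jitter=0.0)
        u, support, _ = generate_phantom(pspec, seed=3)
        mask = compute_brain_mask(u)
        overlap = np.logical_and(mask.data, support.data).sum()
        spill = np.logical_and(mask.data, ~support.data).sum()
        assert overlap / support.count >= 0.95
        assert spill / max(1, (~support.data).sum()) <= 0.05

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            compute_brain_mask(Volume(np.zeros((8, 8, 8))))

    def test_single_ellipsoid_single_component(self):
        from scipy import ndimage

        x, y, z = np.ogrid[:24, :24, :24]
        ell = (((x - 12) / 8.0) ** 2 + ((y - 12) / 6.0) ** 2
               + ((z - 12) / 7.0) ** 2) <= 1
        vol = Volume(ell.astype(float) * 0.8)
        mask = compute_brain_mask(vol)
        _, ncomp = ndimage.label(mask.data)
        assert ncomp == 1


class TestRestoreToNative:
    def test_constant_field_passthrough(self, rng):
        native = Volume(rng.random((20, 22, 18)) + 0.1, spacing=(1, 1, 1))
        norm, mask, rec = preprocess(native, (2, 2, 2), (16, 16, 16))
        field = norm.copy_with(np.ones(norm.shape))
        out = restore_to_native(field, rec, native)
        assert out.shape == native.shape
        assert np.allclose(out.data, 1.0)

    def test_smooth_field_round_trip(self):
        # analytic smooth field evaluated on both grids directly
        def f(x, y, z):  # mm coordinates
            return 1.0 + 0.2 * np.sin(2 * np.pi * x / 90.0) \
                + 0.1 * np.cos(2 * np.pi * (y + z) / 120.0)

        native = Volume(np.ones((40, 40, 40)), spacing=(1, 1, 1))
        # build the preprocessed grid explicitly: 40 voxels at 1 mm resample
        # to 20 at 2 mm, then pad to 32
        res_shape = (20, 20, 20)
        padded, rec = pad_crop_to_shape(
            Volume(np.zeros(res_shape), spacing=(2, 2, 2)), (32, 32, 32))
        pad0 = [p[0] for p in rec.pad_offsets]
        idx = np.meshgrid(*[np.arange(32)] * 3, indexing="ij")
        mm = [(idx[i] - pad0[i] + 0.5) * 2.0 for i in range(3)]
        field_pp = Volume(f(*mm), spacing=(2, 2, 2))
        out = restore_to_native(field_pp, rec, native)
        nidx = np.meshgrid(*[np.arange(40)] * 3, indexing="ij")
        truth = f(*[(nidx[i] + 0.5) * 1.0 for i in range(3)])
        rel = np.abs(out.data - truth) / np.abs(truth)
        assert rel.max() < 0.05

    def test_shape_mismatch_raises(self):
        vol = Volume(np.zeros((16, 16, 16)))
        _, rec = pad_crop_to_shape(vol, (32, 32, 32))
        with pytest.raises(ValueError):
            restore_to_native(Volume(np.ones((8, 8, 8))), rec, vol)


def test_full_preprocess_contract(rng):
    native = Volume(rng.random((40, 44, 38)) * 50 + 1, spacing=(1, 1, 1.2))
    norm, mask, rec = preprocess(native, (2, 2, 2), (32, 32, 32))
    assert norm.shape == (32, 32, 32)
    assert norm.data.min() >= 0 and norm.data.max() <= 1
    assert mask.count >= 1
    assert rec.norm_xmax > 0
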