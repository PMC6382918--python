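"""Volume model, NIfTI I/O, cropping, median preprocessing, SUV conversion."""

import numpy as np
import pytest

import sirtplan as sp
from sirtplan.core import CropBox, Modality, SuvParams, Volume


def ramp_volume(n=8, spacing=(1.0, 1.0, 1.0)):
    data = np.arange(n ** 3, dtype=float).reshape(n, n, n)
    return Volume(data, spacing, (0.0, 0.0, 0.0), Modality.CT_MAA)


class TestIO:
    def test_roundtrip_identity(self, tmp_path):
        vol = ramp_volume()
        path = sp.write_volume(vol, tmp_path / "ramp.nii.gz")
        back = sp.read_volume(path)
        np.testing.assert_array_equal(back.data, vol.data)

    def test_anisotropic_spacing_survives(self, tmp_path):
        # CT of the FDG study: 0.98 mm in plane, 1.5 mm slices
        vol = ramp_volume(spacing=(0.98, 0.98, 1.5))
        back = sp.read_volume(sp.write_volume(vol, tmp_path / "v.nii"))
        np.testing.assert_allclose(back.spacing, (0.98, 0.98, 1.5), atol=1e-6)
        np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)

    def test_2d_data_rejected(self, tmp_path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)), tmp_path / "flat.nii")
        with pytest.raises(ValueError, match="3D"):
            sp.read_volume(tmp_path / "flat.nii")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sp.read_volume(tmp_path / "nope.nii")


class TestCrop:
    def test_full_extent_is_identity(self):
        vol = ramp_volume()
        out = sp.crop(vol, CropBox((0, 0, 0), (8, 8, 8)))
        np.testing.assert_array_equal(out.data, vol.data)
        assert out.origin == vol.origin

    def test_index_arithmetic(self):
        vol = ramp_volume()
        out = sp.crop(vol, CropBox((2, 2, 2), (6, 6, 6)))
        assert out.shape == (4, 4, 4)
        assert out.data[0, 0, 0] == vol.data[2, 2, 2]

    def test_origin_shift_affine_composition(self):
        # world coordinate of retained voxels must not change
        vol = ramp_volume()
        out = sp.crop(vol, CropBox((2, 2, 2), (6, 6, 6)))
        assert out.origin == (2.0, 2.0, 2.0)
        np.testing.assert_allclose(out.index_to_world([0, 0, 0]),
                                   vol.index_to_world([2, 2, 2]))

    def test_out_of_range_box(self):
        with pytest.raises(ValueError):
            sp.crop(ramp_volume(), CropBox((0, 0, 0), (9, 8, 8)))

    def test_invalid_box(self):
        with pytest.raises(ValueError):
            CropBox((3, 0, 0), (3, 8, 8))

    def test_uncrop_restores_region(self):
        vol = ramp_volume()
        box = CropBox((1, 2, 3), (5, 6, 7))
        restored = sp.uncrop(sp.crop(vol, box), box, vol.shape)
        np.testing.assert_array_equal(restored.data[box.slices], vol.data[box.slices])
        assert restored.origin == vol.origin


def _median_pass_oracle(data):
    """Brute-force one orientation triple of 3x3 slice-wise medians."""
    from itertools import product
    out = np.asarray(data, float)
    sizes = [(3, 3, 1), (3, 1, 3), (1, 3, 3)]
    for size in sizes:
        nxt = np.empty_like(out)
        padded = np.pad(out, [(s // 2,) * 2 for s in size], mode="edge")
        for i, j, k in product(*map(range, out.shape)):
            block = padded[i:i + size[0], j:j + size[1], k:k + size[2]]
            nxt[i, j, k] = np.median(block)
        out = nxt
    return out


class TestMedianFilter:
    def test_constant_unchanged(self):
        vol = Volume(np.full((6, 6, 6), 42.0))
        np.testing.assert_array_equal(sp.median_filter_stack(vol).data, 42.0)

    def test_impulse_removed_matches_bruteforce(self):
        data = np.full((7, 7, 7), 50.0)
        data[3, 3, 3] += 1000.0
        vol = Volume(data)
        got = sp.median_filter_stack(vol, passes=1)
        np.testing.assert_allclose(got.data, _median_pass_oracle(data))
        assert got.data[3, 3, 3] == 50.0  # impulse gone after one pass

    def test_matches_bruteforce_on_random_volume(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 20, (6, 7, 8))
        got = sp.median_filter_stack(Volume(data), passes=1)
        np.testing.assert_allclose(got.data, _median_pass_oracle(data))

    def test_selection_property_no_new_values(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 30, (8, 8, 8))
        out = sp.median_filter_stack(Volume(data), passes=3).data
        assert out.min() >= data.min() and out.max() <= data.max()

    def test_piecewise_constant_stable_away_from_interface(self):
        data = np.full((10, 8, 8), 20.0)
        data[5:] = 60.0
        once = sp.median_filter_stack(Volume(data), passes=1).data
        twice = sp.median_filter_stack(Volume(data), passes=2).data
        # at least two voxels from the interface nothing may change
        np.testing.assert_array_equal(once[:3], data[:3])
        np.testing.assert_array_equal(twice[7:], data[7:])


class TestSuv:
    def test_definition_unit_suv(self):
        # concentration equal to decay-corrected activity per gram -> SUV 1
        params = SuvParams(injected_activity=200.0, injection_to_scan=60.0,
                           half_life=109.77, body_weight=70.0)
        conc = params.decay_corrected_activity_mbq * 1000.0 / (70.0 * 1000.0)
        vol = Volume(np.full((4, 4, 4), conc), modality=Modality.PET_FDG)
        out = sp.to_suv(vol, params)
        np.testing.assert_allclose(out.data, 1.0, rtol=1e-12)
        assert out.modality is Modality.PET_FDG

    def test_zero_concentration(self):
        params = SuvParams(100.0, 60.0)
        out = sp.to_suv(Volume(np.zeros((4, 4, 4))), params)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_one_half_life_doubles_suv(self):
        vol = Volume(np.full((4, 4, 4), 5.0))
        early = sp.to_suv(vol, SuvParams(100.0, 1e-9, half_life=109.77))
        late = sp.to_suv(vol, SuvParams(100.0, 109.77, half_life=109.77))
        np.testing.assert_allclose(late.data, 2.0 * early.data, rtol=1e-9)

    def test_linearity(self):
        params = SuvParams(150.0, 45.0)
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 10, (4, 4, 4))
        one = sp.to_suv(Volume(data), params).data
        three = sp.to_suv(Volume(3 * data), params).data
        np.testing.assert_allclose(three, 3 * one, rtol=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(injected_activity=-1.0, injection_to_scan=60.0),
        dict(injected_activity=100.0, injection_to_scan=60.0, body_weight=0.0),
    ])
    def test_invalid_params(self, bad):
        with pytest.raises(ValueError):
            SuvParams(**bad)
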