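"""Rigid/deformable registration, meta-CBCT, warping and Jacobian QC."""

import numpy as np
import pytest
from scipy import ndimage

import sirtplan as sp
from sirtplan.core import Mask, Volume
from sirtplan.registration import (DeformationField, RegistrationError,
                                   RigidTransform, build_meta_cbct,
                                   classify_tissue, jacobian_determinant,
                                   jacobian_stats, register_deformable,
                                   register_rigid, warp)
from .conftest import noiseless_spec, small_spec


@pytest.fixture(scope="module")
def cbct_pair():
    st = sp.generate_phantom(noiseless_spec())
    return st


class TestRigid:
    def test_identity_on_identical_images(self, cbct_pair):
        vol = cbct_pair.cbct_late_left
        tr = register_rigid(vol, vol, levels=2)
        assert np.abs(tr.translation_mm).max() < 0.1 * min(vol.spacing)

    def test_translation_recovery(self, cbct_pair):
        fixed = cbct_pair.cbct_late_left
        s = np.array([4.0, -3.0, 2.0])
        moving = Volume(ndimage.shift(fixed.data, s / np.asarray(fixed.spacing),
                                      order=1, mode="nearest"),
                        fixed.spacing, fixed.origin)
        tr = register_rigid(moving, fixed, levels=3)
        err = np.linalg.norm(np.asarray(tr.translation_mm) - s)
        assert err < 0.5 * min(fixed.spacing)

    def test_inplane_rotation_recovery(self, cbct_pair):
        fixed = cbct_pair.cbct_late_left
        center = tuple(np.asarray(fixed.origin)
                       + 0.5 * (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing))
        true = RigidTransform((0.0, 0.0, 5.0), (0.0, 0.0, 0.0), center)
        moving = sp.resample_rigid(fixed, fixed, true, cval=float(fixed.data.min()))
        tr = register_rigid(moving, fixed, levels=3)
        # moving = fixed∘T, so registration recovers the inverse rotation
        assert tr.rotation_deg[2] == pytest.approx(-5.0, abs=1.0)

    def test_non_overlapping_grids_rejected(self, cbct_pair):
        vol = cbct_pair.cbct_late_left
        far = Volume(vol.data, vol.spacing, (1e4, 1e4, 1e4))
        with pytest.raises(RegistrationError):
            register_rigid(far, vol)


class TestMetaCbct:
    def test_self_average_identity(self, cbct_pair):
        vol = cbct_pair.cbct_late_left
        meta = build_meta_cbct([vol, vol])
        np.testing.assert_allclose(meta.data[1:-1, 1:-1, 1:-1],
                                   vol.data[1:-1, 1:-1, 1:-1], atol=1e-6)

    def test_enhancement_suppressed_by_averaging(self, cbct_pair):
        # {left-enhanced +80, right-enhanced} average to +40 in the left lobe
        st = cbct_pair
        t = st.truth
        meta = build_meta_cbct([st.cbct_late_left, st.cbct_late_right])
        base = noiseless_spec().hu_liver
        left_mean = meta.data[t.left_lobe.data].mean()
        assert left_mean - base == pytest.approx(40.0, abs=3.0)
        single = st.cbct_late_left.data[t.left_lobe.data].mean()
        assert left_mean < single  # suppression vs the enhanced CBCT

    def test_union_field_of_view(self, cbct_pair):
        a = cbct_pair.cbct_early_left
        b = sp.crop(a, sp.CropBox((8, 8, 8), (56, 56, 56)))
        meta = build_meta_cbct([b, a])
        for ax in range(3):
            assert meta.shape[ax] * meta.spacing[ax] >= b.shape[ax] * b.spacing[ax]
            assert meta.shape[ax] * meta.spacing[ax] >= a.shape[ax] * a.spacing[ax] - meta.spacing[ax]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_meta_cbct([])


class TestClassifyTissue:
    def test_noiseless_phantom_classes(self, cbct_pair):
        st = cbct_pair
        cm = classify_tissue(st.ct_maa, st.truth.liver)
        labels = cm.labels
        hu = st.ct_maa.data
        assert (labels[hu == -1000.0] == 0).all()      # air
        assert (labels[hu == 700.0] == 3).all()        # bone
        assert (labels[st.truth.liver.data] == 2).all()  # liver (incl. lesions)

    def test_all_air_single_class(self):
        vol = Volume(np.full((8, 8, 8), -1000.0))
        cm = classify_tissue(vol)
        assert set(np.unique(cm.labels)) == {0}

    def test_rigidity_defaults_propagate(self, cbct_pair):
        cm = classify_tissue(cbct_pair.ct_maa, cbct_pair.truth.liver)
        rig = cm.rigidity_map()
        assert cm.rigidity["liver"] == pytest.approx(10 * cm.rigidity["soft"])
        assert rig[cm.labels == 2].max() == pytest.approx(10.0)

    def test_liver_must_be_stiffest(self):
        with pytest.raises(ValueError):
            sp.TissueClassMap(np.zeros((4, 4, 4), dtype=np.uint8),
                              rigidity={"air": 0.2, "soft": 1.0,
                                        "liver": 1.0, "bone": 5.0})


class TestWarp:
    def test_zero_field_identity(self, cbct_pair):
        vol = cbct_pair.ct_maa
        field = DeformationField(np.zeros(vol.shape + (3,)), vol.spacing, vol.origin)
        out = warp(vol, field)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-9)

    def test_translation_field_index_shift(self, cbct_pair):
        vol = cbct_pair.ct_maa
        disp = np.zeros(vol.shape + (3,))
        disp[..., 0] = vol.spacing[0]  # sample one voxel further in +x
        out = warp(vol, DeformationField(disp, vol.spacing, vol.origin))
        np.testing.assert_allclose(out.data[:-1], vol.data[1:], atol=1e-9)

    def test_mask_linear_interpolation_rejected(self, cbct_pair):
        t = cbct_pair.truth
        with pytest.raises(ValueError, match="nearest"):
            warp(t.liver, t.field, "linear")


class TestJacobian:
    def test_identity_field(self):
        field = DeformationField(np.zeros((8, 8, 8, 3)), (1.0, 1.0, 1.0))
        np.testing.assert_allclose(jacobian_determinant(field), 1.0, atol=1e-12)

    def test_uniform_scaling_cubed(self):
        s = 1.1
        shape = (12, 12, 12)
        spacing = (2.0, 2.0, 2.0)
        idx = np.indices(shape, dtype=float)
        disp = np.stack([(s - 1) * idx[i] * spacing[i] for i in range(3)], axis=-1)
        jac = jacobian_determinant(DeformationField(disp, spacing))
        np.testing.assert_allclose(jac[1:-1, 1:-1, 1:-1], s ** 3, atol=1e-6)

    def test_random_smooth_field_vs_bruteforce(self):
        d = sp.DeformationSpec(amplitude_mm=5.0, wavelength_mm=60.0)
        shape = (16, 16, 16)
        spacing = (2.0, 2.5, 3.0)
        idx = np.indices(shape, dtype=float)
        pts = np.stack([idx[i] * spacing[i] for i in range(3)], axis=-1)
        jac = jacobian_determinant(DeformationField(d.displacement(pts), spacing))
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = tuple(rng.integers(1, n - 1) for n in shape)
            # independent central-difference oracle at this voxel
            J = np.zeros((3, 3))
            disp = d.displacement(pts)
            for j in range(3):
                lo = list(v); hi = list(v)
                lo[j] -= 1; hi[j] += 1
                J[:, j] = (disp[tuple(hi)] - disp[tuple(lo)]) / (2 * spacing[j])
            assert jac[v] == pytest.approx(np.linalg.det(np.eye(3) + J), abs=1e-8)

    def test_stats_identity_field(self, cbct_pair):
        field = DeformationField(np.zeros(cbct_pair.ct_maa.shape + (3,)),
                                 cbct_pair.ct_maa.spacing)
        st = jacobian_stats(jacobian_determinant(field), cbct_pair.truth.liver)
        for key in ("min", "q1", "median", "q3", "max", "mean"):
            assert st.entire[key] == pytest.approx(1.0)
        assert st.nonpositive_fraction == 0.0

    def test_voi_set_algebra(self, cbct_pair):
        from sirtplan.core import erode_mm
        liver = cbct_pair.truth.liver
        eroded = erode_mm(liver.data, 10.0, liver.spacing)
        excluded = np.logical_and(liver.data, ~eroded)
        assert not np.logical_and(eroded, excluded).any()
        np.testing.assert_array_equal(np.logical_or(eroded, excluded), liver.data)

    def test_quartiles_match_sorted_oracle(self):
        rng = np.random.default_rng(7)
        patch = rng.uniform(0.5, 1.5, (3, 3, 3))
        liver = Mask(np.ones((3, 3, 3), dtype=bool), (1.0, 1.0, 1.0))
        with pytest.warns(UserWarning):  # eroded VOI empty on a 3mm cube
            st = jacobian_stats(patch, liver, erosion_mm=10.0)
        vals = np.sort(patch.ravel())
        # linear-interpolation (type-7) quantile oracle
        def q(p):
            h = p * (len(vals) - 1)
            lo = int(np.floor(h))
            return vals[lo] + (h - lo) * (vals[min(lo + 1, len(vals) - 1)] - vals[lo])
        assert st.entire["q1"] == pytest.approx(q(0.25), abs=1e-12)
        assert st.entire["median"] == pytest.approx(q(0.5), abs=1e-12)
        assert st.entire["q3"] == pytest.approx(q(0.75), abs=1e-12)


class TestDeformable:
    def test_identity_when_aligned(self):
        st = sp.generate_phantom(small_spec(seed=3,
                                            deformation=sp.DeformationSpec(amplitude_mm=0.0)))
        fixed = sp.median_filter_stack(st.ct_maa, 1)
        classes = classify_tissue(fixed, st.truth.liver)
        field = register_deformable(fixed, fixed, classes, iterations=15)
        assert field.magnitude().max() < 0.25 * min(fixed.spacing)

    def test_recovers_alignment_and_topology(self, deformable_result):
        st, field = deformable_result
        t = st.truth
        pre = sp.overlap_metrics(t.liver_fdg, t.liver).dice
        warped = warp(t.liver_fdg, field, "nearest")
        post = sp.overlap_metrics(warped, t.liver).dice
        assert post >= 0.95
        assert post > pre
        # PET warped with the CT field keeps each tumor a single component
        pet_w = warp(st.pet_fdg, field, "linear")
        hot = pet_w.data >= 5.0
        _, n = ndimage.label(hot, ndimage.generate_binary_structure(3, 1))
        assert n == len(t.tumors)

    def test_no_folding_in_liver(self, deformable_result):
        st, field = deformable_result
        jac = jacobian_determinant(field)
        stats = jacobian_stats(jac, st.truth.liver)
        assert stats.nonpositive_fraction == 0.0
        assert stats.eroded is not None
        for voi in (stats.entire, stats.eroded, stats.excluded):
            assert voi["min"] <= voi["q1"] <= voi["median"] <= voi["q3"] <= voi["max"]

    def test_liver_rigidity_damps_jacobian_variance(self):
        """Doubling the liver spring rigidity must not raise the Jacobian
        variance inside the eroded liver (regularisation monotonicity)."""
        st = sp.generate_phantom(small_spec(seed=4))
        fixed = sp.median_filter_stack(st.ct_maa, 1)
        moving = sp.median_filter_stack(st.ct_fdg, 1)
        variances = []
        for liver_rig in (20.0, 40.0):
            rig = {"air": 0.2, "soft": 1.0, "liver": liver_rig, "bone": 5.0}
            classes = classify_tissue(fixed, st.truth.liver, rigidity=rig)
            field = register_deformable(moving, fixed, classes, iterations=40)
            jac = jacobian_determinant(field)
            from sirtplan.core import erode_mm
            eroded = erode_mm(st.truth.liver.data, 10.0, fixed.spacing)
            variances.append(float(np.var(jac[eroded])))
        assert variances[1] <= variances[0] * 1.05
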