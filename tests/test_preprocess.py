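"""Lung-field extraction: HU calibration, masking, windowing, bone removal."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis.extra import numpy as hnp

from lungrpn import preprocess as pre
from lungrpn import synthdata
from lungrpn.preprocess import (
    Calibration,
    LungMask,
    Uint8Image,
    apply_mask,
    binarize_lungs,
    extract_lung_mask,
    hu_to_uint8,
    preprocess_slice,
    remove_bone,
    to_hu,
)


class TestToHU:
    def test_identity_calibration(self, rng):
        raw = rng.randint(0, 4096, (8, 8))
        np.testing.assert_array_equal(to_hu(raw, 1.0, 0.0).values, raw)

    def test_standard_ct_rescale(self):
        assert to_hu(np.array([[1000]]), 1.0, -1024.0).values[0, 0] == -24.0

    def test_constant_in_constant_out(self):
        out = to_hu(np.full((4, 4), 100), 2.0, -50.0).values
        assert np.all(out == 150.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            to_hu(np.zeros((2, 2)), 0.0, 0.0)


class TestBinarize:
    def test_soft_tissue_never_air_like(self):
        img = synthdata.HUImage(np.full((5, 5), 40.0), 1.0)
        assert not binarize_lungs(img, -400.0).any()

    def test_phantom_air_set_matches_compartment_map(self, phantom_spec):
        img, _ = synthdata.make_phantom_slice(phantom_spec, [])
        comp = synthdata.compartment_map(phantom_spec)
        binary = binarize_lungs(img, -400.0)
        np.testing.assert_array_equal(binary, (comp == 0) | (comp == 2))

    def test_threshold_below_minimum_gives_empty(self, phantom_spec):
        img, _ = synthdata.make_phantom_slice(phantom_spec, [])
        assert not binarize_lungs(img, img.values.min() - 1).any()


class TestExtractLungMask:
    def test_mask_area_close_to_true_lung_area(self, phantom_spec):
        img, _ = synthdata.make_phantom_slice(phantom_spec, [])
        mask = extract_lung_mask(binarize_lungs(img))
        true_area = phantom_spec.left_lung_ellipse.area + phantom_spec.right_lung_ellipse.area
        assert 1.0 <= mask.area / true_area <= 1.3

    def test_only_border_connected_air_gives_empty_mask(self):
        binary = np.zeros((20, 20), dtype=bool)
        binary[:3, :] = True  # touches the border everywhere
        with pytest.warns(UserWarning, match="empty"):
            mask = extract_lung_mask(binary)
        assert mask.area == 0

    def test_flip_equivariance(self, phantom_slice):
        img, _ = phantom_slice
        binary = binarize_lungs(img)
        mirrored = extract_lung_mask(binary[:, ::-1])
        np.testing.assert_array_equal(mirrored.values, extract_lung_mask(binary).values[:, ::-1])

    def test_two_lung_components(self, phantom_spec):
        img, _ = synthdata.make_phantom_slice(phantom_spec, [])
        assert extract_lung_mask(binarize_lungs(img)).n_components == 2


class TestHuToUint8:
    @pytest.mark.parametrize(
        "hu,expected",
        [(-1200.0, 0), (600.0, 255), (-300.0, 128), (-5000.0, 0), (5000.0, 255)],
    )
    def test_window_endpoints_midpoint_and_clipping(self, hu, expected):
        img = synthdata.HUImage(np.array([[hu]]), 1.0)
        assert hu_to_uint8(img, (-1200.0, 600.0)).values[0, 0] == expected

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            hu_to_uint8(synthdata.HUImage(np.zeros((2, 2)), 1.0), (100.0, 100.0))


class TestApplyMask:
    def test_all_true_identity(self, rng):
        img = Uint8Image(rng.randint(0, 256, (6, 6)))
        mask = LungMask(np.ones((6, 6), dtype=bool))
        np.testing.assert_array_equal(apply_mask(img, mask).values, img.values)

    def test_all_false_zero(self, rng):
        img = Uint8Image(rng.randint(0, 256, (6, 6)))
        assert not apply_mask(img, LungMask(np.zeros((6, 6), dtype=bool))).values.any()

    @given(
        data=hnp.arrays(np.uint8, (7, 9)),
        mask=hnp.arrays(np.bool_, (7, 9)),
    )
    def test_idempotence(self, data, mask):
        img, m = Uint8Image(data), LungMask(mask)
        once = apply_mask(img, m)
        np.testing.assert_array_equal(apply_mask(once, m).values, once.values)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_mask(Uint8Image(np.zeros((3, 3))), LungMask(np.zeros((4, 4), dtype=bool)))


class TestRemoveBone:
    def test_no_bone_is_identity(self, rng):
        img = Uint8Image(rng.randint(0, 256, (10, 10)))
        hu = synthdata.HUImage(np.full((10, 10), -500.0), 1.0)
        np.testing.assert_array_equal(remove_bone(img, hu, 300.0).values, img.values)

    def test_all_bone_blanks_everything(self):
        img = Uint8Image(np.full((5, 5), 200))
        hu = synthdata.HUImage(np.full((5, 5), 700.0), 1.0)
        assert not remove_bone(img, hu, 300.0).values.any()

    def test_bone_outside_mask_leaves_lung_interior_untouched(self, phantom_spec):
        img, _ = synthdata.make_phantom_slice(phantom_spec, [])
        comp = synthdata.compartment_map(phantom_spec)
        u8 = hu_to_uint8(img)
        out = remove_bone(u8, img, 300.0)
        changed = out.values != u8.values
        # the phantom's bone arc lives in the body wall, far from the lungs
        assert not changed[comp == 2].any()
        assert changed[comp == 3].all()


class TestFullPipeline:
    def test_nodule_boxes_inside_mask(self, phantom_slice):
        img, gt_boxes = phantom_slice
        _, mask = preprocess_slice(img.values, Calibration(), spacing=img.spacing)
        for b in gt_boxes:
            region = mask.values[int(b.y_min) : int(b.y_max), int(b.x_min) : int(b.x_max)]
            assert region.all()

    def test_deterministic(self, phantom_slice):
        img, _ = phantom_slice
        a_img, a_mask = preprocess_slice(img.values)
        b_img, b_mask = preprocess_slice(img.values)
        np.testing.assert_array_equal(a_img.values, b_img.values)
        np.testing.assert_array_equal(a_mask.values, b_mask.values)

    def test_output_nonzero_only_inside_mask(self, phantom_slice):
        img, _ = phantom_slice
        out, mask = preprocess_slice(img.values)
        assert not out.values[~mask.values].any()

    def test_flip_equivariance_of_composite(self, phantom_slice):
        img, _ = phantom_slice
        out, mask = preprocess_slice(img.values)
        out_f, mask_f = preprocess_slice(img.values[:, ::-1])
        np.testing.assert_array_equal(out_f.values, out.values[:, ::-1])
        np.testing.assert_array_equal(mask_f.values, mask.values[:, ::-1])


class TestLungPreprocessor:
    def test_sklearn_params_roundtrip(self):
        est = pre.LungPreprocessor(bone_threshold_hu=250.0)
        assert est.get_params()["bone_threshold_hu"] == 250.0
        est.set_params(closing_radius_px=3)
        assert est._config().closing_radius_px == 3

    def test_transform_matches_function(self, phantom_slice):
        img, _ = phantom_slice
        (u8_est, mask_est), = pre.LungPreprocessor().fit().transform([img])
        u8_fn, mask_fn = preprocess_slice(img.values, spacing=img.spacing)
        np.testing.assert_array_equal(u8_est.values, u8_fn.values)
        np.testing.assert_array_equal(mask_est.values, mask_fn.values)

    def test_invalid_config_rejected_at_fit(self):
        with pytest.raises(ValueError):
            pre.LungPreprocessor(window_hu=(600.0, -1200.0)).fit()
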