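"""Section-stack reconstruction, B-spline fill, slice-wise correction, mapping."""

import numpy as np
import pytest
from scipy import ndimage

from atlasforge.registration import RegistrationConfig
from atlasforge.sections import (
    apply_slicewise,
    fill_missing_bspline,
    map_expression_to_atlas,
    reconstruct_stack,
    slicewise_correct,
)
from atlasforge.synthetic import PhantomSpec, make_phantom, make_section_stack
from atlasforge.volume import (
    DisplacementField,
    TransformChain,
    Volume3D,
    apply_transform,
    invert,
)


@pytest.fixture(scope="module")
def phantom_stack():
    """Section stack with slowly varying anatomy.

    Physical sections are far closer together than the scale on which
    anatomy changes, so the stack is an extrusion of one phantom slice
    with a gentle per-slice intensity modulation (staining variability).
    """
    spec = PhantomSpec(seed=23, shape=(32, 48, 48), n_regions=3)
    inten, annot, mask = make_phantom(spec)
    mid = inten.values[16]
    gains = 1.0 + 0.02 * np.sin(np.arange(32) / 5.0)
    extruded = inten.like(np.stack([mid * g for g in gains]))
    mask_ex = mask.like(np.stack([mask.values[16]] * 32))
    return extruded, annot, mask_ex, make_section_stack(extruded, n_channels=4)


class TestReconstruct:
    def test_ownership_counts(self, phantom_stack):
        inten, _, _, stack = phantom_stack
        rec = reconstruct_stack(stack, channel=0, in_plane_size=(48, 48))
        assert (~rec.missing_mask).sum() == 8
        assert rec.missing_mask.sum() == 24
        assert np.all(rec.volume.values[rec.missing_mask] == 0)

    def test_single_channel_has_no_missing_slices(self, phantom_stack):
        inten, _, _, _ = phantom_stack
        stack = make_section_stack(inten, n_channels=1)
        rec = reconstruct_stack(stack, channel=0, in_plane_size=(48, 48))
        assert rec.missing_mask.sum() == 0

    def test_intensity_inversion_is_involution_given_stored_max(self, phantom_stack):
        inten, _, _, stack = phantom_stack
        rec = reconstruct_stack(stack, channel=0, in_plane_size=(48, 48),
                                invert_intensity=True)
        owned = ~rec.missing_mask
        restored = rec.inversion_max - rec.volume.values[owned]
        np.testing.assert_allclose(restored, inten.values[owned], atol=1e-9)

    def test_background_is_zero_after_inversion(self, phantom_stack):
        _, _, _, stack = phantom_stack
        rec = reconstruct_stack(stack, channel=0, in_plane_size=(48, 48))
        owned = np.where(~rec.missing_mask)[0]
        # histology background is the brightest value; inverted -> 0 somewhere
        assert rec.volume.values[owned].min() >= 0

    def test_too_few_owned_slices_rejected(self, phantom_stack):
        inten, _, _, _ = phantom_stack
        stack = make_section_stack(inten.like(inten.values[:2]), n_channels=2)
        with pytest.raises(ValueError, match="fewer than 2"):
            reconstruct_stack(stack, channel=1)


class TestBsplineFill:
    def test_no_missing_slices_is_identity(self, phantom32):
        inten = phantom32[0]
        missing = np.zeros(inten.shape[0], dtype=bool)
        out = fill_missing_bspline(inten, missing)
        np.testing.assert_array_equal(out.values, inten.values)

    def test_constant_volume_filled_exactly(self):
        vol = Volume3D(np.full((24, 24, 24), 7.5), (1, 1, 1))
        missing = np.zeros(24, dtype=bool)
        missing[::4] = True
        missing[0] = False  # keep the outermost slices known
        out = fill_missing_bspline(vol, missing)
        np.testing.assert_allclose(out.values, 7.5, atol=0.01)

    def test_linear_ramp_filled_within_five_percent(self):
        z = np.indices((32, 32, 32))[0].astype(float)
        vol = Volume3D(3.0 * z + 5.0, (1, 1, 1))
        missing = np.zeros(32, dtype=bool)
        missing[1::4] = True
        out = fill_missing_bspline(vol, missing)
        err = np.abs(out.values - vol.values)[missing].max()
        assert err <= 0.05 * np.ptp(vol.values)

    def test_filled_values_bounded_by_bracketing_neighbourhoods(self):
        # smooth separable field: fill should stay inside the local envelope
        z, y, x = np.indices((24, 24, 24), dtype=float)
        vol = Volume3D(np.sin(z / 6) * 40 + np.cos(y / 8) * 20 + x, (1, 1, 1))
        missing = np.zeros(24, dtype=bool)
        missing[3:21:4] = True  # interior slices with bracketing neighbours
        out = fill_missing_bspline(vol, missing)
        for i in np.where(missing)[0]:
            lo = np.minimum(ndimage.minimum_filter(vol.values[i - 1], 5),
                            ndimage.minimum_filter(vol.values[i + 1], 5))
            hi = np.maximum(ndimage.maximum_filter(vol.values[i - 1], 5),
                            ndimage.maximum_filter(vol.values[i + 1], 5))
            slack = 0.05 * np.ptp(vol.values)
            assert np.all(out.values[i] >= lo - slack)
            assert np.all(out.values[i] <= hi + slack)

    def test_all_slices_missing_rejected(self, phantom32):
        inten = phantom32[0]
        with pytest.raises(ValueError, match="all slices"):
            fill_missing_bspline(inten, np.ones(inten.shape[0], dtype=bool))


class TestSlicewiseCorrect:
    def test_aligned_stack_gets_near_identity_transforms(self, phantom_stack):
        inten, _, mask, stack = phantom_stack
        rec = reconstruct_stack(stack, channel=0, in_plane_size=(48, 48),
                                invert_intensity=False)
        tmask = rec.volume.like(mask.values.astype(float))
        chains = slicewise_correct(
            rec.volume, rec.missing_mask, inten, tmask,
            RegistrationConfig(metric="msd", levels=2, max_iters=8))
        pts = np.array([[0.0, 24 * inten.spacing[1], 24 * inten.spacing[2]]])
        for i in np.where(~rec.missing_mask)[0]:
            disp = np.abs(chains[i].apply_points(pts) - pts).max()
            assert disp / min(inten.spacing[1:]) < 0.3

    def test_injected_shift_corrected_within_one_pixel(self, phantom_stack):
        inten, _, mask, stack = phantom_stack
        rec = reconstruct_stack(stack, channel=0, in_plane_size=(48, 48),
                                invert_intensity=False)
        vol = rec.volume
        i = 16
        shifted = vol.values.copy()
        shifted[i] = np.roll(vol.values[i], 5, axis=1)
        sv = vol.like(shifted)
        tmask = vol.like(mask.values.astype(float))
        chains = slicewise_correct(
            sv, rec.missing_mask, inten, tmask,
            RegistrationConfig(metric="msd", levels=2, max_iters=15))
        center = np.array([[0.0, 24 * vol.spacing[1], 24 * vol.spacing[2]]])
        moved = chains[i].apply_points(center)[0] - center[0]
        rec_px = moved[2] / vol.spacing[2]
        assert rec_px == pytest.approx(5.0, abs=1.0)

    def test_zero_mask_weight_reduces_to_neighbour_alignment(self, phantom_stack):
        inten, _, mask, stack = phantom_stack
        rec = reconstruct_stack(stack, channel=0, in_plane_size=(48, 48),
                                invert_intensity=False)
        tmask = rec.volume.like(mask.values.astype(float))
        cfg = RegistrationConfig(metric="msd", levels=2, max_iters=6)
        a = slicewise_correct(rec.volume, rec.missing_mask, inten, tmask, cfg,
                              neighbor_weight=1.0, mask_weight=0.0)
        junk = rec.volume.like(np.zeros(rec.volume.shape))
        b = slicewise_correct(rec.volume, rec.missing_mask, inten,
                              junk.like(np.ones(junk.shape)), cfg,
                              neighbor_weight=1.0, mask_weight=0.0)
        pts = np.array([[0.0, 480.0, 480.0]])
        for ca, cb in zip(a, b):
            np.testing.assert_allclose(ca.apply_points(pts),
                                       cb.apply_points(pts), atol=1e-9)

    def test_missing_slices_get_identity_chains(self, phantom_stack):
        inten, _, mask, stack = phantom_stack
        rec = reconstruct_stack(stack, channel=0, in_plane_size=(48, 48))
        tmask = rec.volume.like(mask.values.astype(float))
        chains = slicewise_correct(
            rec.volume, rec.missing_mask, inten, tmask,
            RegistrationConfig(metric="msd", levels=2, max_iters=4))
        for i in np.where(rec.missing_mask)[0]:
            assert chains[i].steps == []


class TestMapExpression:
    def test_identity_transforms_preserve_expression(self, phantom32):
        inten = phantom32[0]
        expr = inten.like(np.clip(inten.values, 0.0, None))  # non-negative signal
        ident = [TransformChain.identity() for _ in range(inten.shape[0])]
        out = map_expression_to_atlas([expr], ident, TransformChain.identity(),
                                      inten)
        np.testing.assert_allclose(out[0].values, expr.values, atol=1e-9)

    def test_all_zero_expression_stays_zero(self, phantom32):
        inten = phantom32[0]
        zero = inten.like(np.zeros(inten.shape))
        ident = [TransformChain.identity() for _ in range(inten.shape[0])]
        out = map_expression_to_atlas([zero], ident, TransformChain.identity(),
                                      inten)
        assert np.all(out[0].values == 0)

    def test_warped_blob_maps_back_into_source_region(self, phantom48):
        inten, annot, _ = phantom48
        region = 2
        blob = inten.like(np.where(annot.values == region, 50.0, 0.0))
        blob = inten.like(ndimage.gaussian_filter(blob.values, 1.0))
        # perturb with a known smooth warp, then map back with its inverse
        shape = inten.shape
        sp = np.asarray(inten.spacing)
        z, y, x = np.indices(shape, dtype=float)
        vec = np.zeros(shape + (3,))
        vec[..., 1] = 2 * sp[1] * np.sin(2 * np.pi * x / shape[2])
        field = DisplacementField(vec, inten.like(np.zeros(shape)))
        fwd = TransformChain([field])
        warped = apply_transform(blob, fwd, inten, "linear")
        ident = [TransformChain.identity() for _ in range(shape[0])]
        back = map_expression_to_atlas([warped], ident, invert(fwd), inten)[0]
        region_mask = ndimage.binary_dilation(annot.values == region,
                                              iterations=1)
        frac = back.values[region_mask].sum() / back.values.sum()
        assert frac >= 0.90
        assert np.all(back.values >= 0)

    def test_round_trip_correlation(self, phantom48):
        inten = phantom48[0]
        shape = inten.shape
        sp = np.asarray(inten.spacing)
        z, y, x = np.indices(shape, dtype=float)
        vec = np.zeros(shape + (3,))
        vec[..., 2] = 2 * sp[2] * np.sin(2 * np.pi * y / shape[1])
        field = DisplacementField(vec, inten.like(np.zeros(shape)))
        fwd = TransformChain([field])
        smooth = inten.like(ndimage.gaussian_filter(inten.values, 1.5))
        warped = apply_transform(smooth, fwd, inten, "linear")
        back = apply_transform(warped, invert(fwd), inten, "linear")
        core = (slice(4, -4),) * 3
        r = np.corrcoef(back.values[core].ravel(),
                        smooth.values[core].ravel())[0, 1]
        assert r >= 0.95

    def test_missing_transforms_rejected(self, phantom32):
        inten = phantom32[0]
        with pytest.raises(ValueError, match="transforms"):
            map_expression_to_atlas([inten], None, TransformChain.identity(),
                                    inten)
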