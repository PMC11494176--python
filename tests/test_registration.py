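"""Registration engine: metrics, linear recovery, deformable recovery."""

import numpy as np
import pytest

from atlasforge.registration import (
    RegistrationConfig,
    histogram_entropy,
    jacobian_determinant,
    register_deformable,
    register_linear,
    register_multichannel,
    similarity,
)
from atlasforge.volume import (
    AffineTransform3D,
    DisplacementField,
    TransformChain,
    Volume3D,
    apply_transform,
)


def _sinusoid_field(vol, amplitude_vox):
    shape = vol.shape
    sp = np.asarray(vol.spacing)
    z, y, x = np.indices(shape, dtype=float)
    vec = np.zeros(shape + (3,))
    vec[..., 0] = amplitude_vox * np.sin(2 * np.pi * y / shape[1])
    vec[..., 1] = amplitude_vox * np.sin(2 * np.pi * x / shape[2])
    vec[..., 2] = amplitude_vox * np.sin(2 * np.pi * z / shape[0])
    return DisplacementField(vec * sp, vol.like(np.zeros(shape)))


class TestSimilarity:
    def test_msd_zero_iff_identical(self, phantom32):
        inten = phantom32[0]
        assert similarity(inten, inten, "msd") == 0.0
        other = inten.like(inten.values + 1.0)
        assert similarity(inten, other, "msd") > 0

    def test_mi_of_image_with_itself_is_marginal_entropy(self, phantom32):
        inten = phantom32[0]
        mi = similarity(inten, inten, "mi", mi_bins=32)
        assert mi == pytest.approx(histogram_entropy(inten.values, 32), abs=1e-12)

    def test_ncc_invariant_to_affine_intensity_change(self, phantom32):
        inten = phantom32[0]
        rescaled = inten.like(2.0 * inten.values + 5.0)
        assert similarity(inten, rescaled, "ncc") == pytest.approx(1.0, abs=1e-9)

    def test_shape_mismatch_rejected(self, phantom32):
        inten = phantom32[0]
        small = Volume3D(inten.values[:16], inten.spacing)
        with pytest.raises(ValueError, match="shape"):
            similarity(inten, small, "msd")

    def test_empty_mask_rejected(self, phantom32):
        inten = phantom32[0]
        empty = inten.like(np.zeros(inten.shape, dtype=np.uint8))
        with pytest.raises(ValueError, match="mask"):
            similarity(inten, inten, "msd", mask=empty)


class TestLinear:
    def test_self_registration_is_identity(self, phantom32):
        inten = phantom32[0]
        aff = register_linear(inten, inten,
                              RegistrationConfig(model="rigid", levels=2,
                                                 metric="msd"))
        assert np.linalg.norm(aff.translation) / min(inten.spacing) < 0.1
        angle = np.degrees(np.arccos(np.clip((np.trace(aff.matrix) - 1) / 2,
                                             -1, 1)))
        assert angle < 0.5

    def test_translation_recovered_within_half_voxel(self, phantom48):
        inten = phantom48[0]
        shift_vox = np.array([0.0, 4.0, 0.0])
        t_world = shift_vox * np.asarray(inten.spacing)
        moving = apply_transform(
            inten, TransformChain([AffineTransform3D(np.eye(3), t_world)]),
            inten, "linear")
        # Exhaustive integer-shift oracle for the best alignment:
        best = None
        for d in range(-6, 7):
            cand = np.roll(moving.values, d, axis=1)
            err = np.mean((cand - inten.values) ** 2)
            if best is None or err < best[1]:
                best = (d, err)
        assert best[0] == 4  # moving content sits 4 voxels toward -axis1
        aff = register_linear(inten, moving,
                              RegistrationConfig(model="translation", levels=3))
        rec_vox = aff.translation / np.asarray(inten.spacing)
        np.testing.assert_allclose(rec_vox, -shift_vox, atol=0.5)

    def test_inplane_rotation_recovered_within_one_degree(self, phantom48):
        inten = phantom48[0]
        ang = np.deg2rad(5.0)
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        center = inten.index_to_world([np.array(inten.shape) / 2])[0]
        fwd = AffineTransform3D(rot, center - rot @ center)
        moving = apply_transform(inten, TransformChain([fwd]), inten, "linear")
        aff = register_linear(inten, moving,
                              RegistrationConfig(model="rigid", levels=3))
        rec_deg = np.degrees(np.arccos(np.clip((np.trace(aff.matrix) - 1) / 2,
                                               -1, 1)))
        assert rec_deg == pytest.approx(5.0, abs=1.0)

    def test_constant_volume_rejected(self, phantom32):
        inten = phantom32[0]
        flat = inten.like(np.zeros(inten.shape))
        with pytest.raises(ValueError, match="constant"):
            register_linear(inten, flat)


class TestDeformable:
    def test_self_registration_field_is_tiny(self, phantom32):
        inten = phantom32[0]
        chain = register_deformable(inten, inten,
                                    RegistrationConfig(levels=2, max_iters=10))
        max_vox = np.max(np.abs(chain.steps[0].vectors)) / min(inten.spacing)
        assert max_vox < 0.2

    def test_sinusoidal_warp_recovered(self, phantom64):
        inten, _, mask = phantom64
        true = _sinusoid_field(inten, 3.0)
        moving = apply_transform(inten, TransformChain([true]), inten, "linear")
        msd0 = similarity(inten, moving, "msd")
        chain = register_deformable(
            inten, moving,
            RegistrationConfig(metric="msd", levels=3, smoothing_sigma=2.0,
                               max_iters=30))
        warped = apply_transform(moving, chain, inten, "linear")
        msd1 = similarity(inten, warped, "msd")
        assert msd1 <= 0.2 * msd0  # >= 80% reduction
        inv = true.inverted()
        resid = np.linalg.norm(
            (chain.steps[0].vectors - inv.vectors) / np.asarray(inten.spacing),
            axis=-1)
        assert resid[mask.values > 0].mean() <= 1.0

    def test_field_is_diffeomorphic_in_practice(self, phantom48):
        inten = phantom48[0]
        true = _sinusoid_field(inten, 2.0)
        moving = apply_transform(inten, TransformChain([true]), inten, "linear")
        chain = register_deformable(inten, moving,
                                    RegistrationConfig(levels=2, max_iters=20))
        jd = jacobian_determinant(chain.steps[0])
        assert (jd > 0).mean() >= 0.99

    def test_metric_never_worse_than_identity(self, phantom48):
        inten = phantom48[0]
        rng = np.random.default_rng(0)
        moving = inten.like(np.roll(inten.values, 3, axis=2)
                            + rng.normal(0, 5, inten.shape))
        msd0 = similarity(inten, moving, "msd")
        chain = register_deformable(inten, moving,
                                    RegistrationConfig(levels=2, max_iters=8))
        warped = apply_transform(moving, chain, inten, "linear")
        assert similarity(inten, warped, "msd") <= msd0

    def test_halving_smoothing_does_not_increase_final_msd(self, phantom48):
        inten = phantom48[0]
        true = _sinusoid_field(inten, 2.0)
        moving = apply_transform(inten, TransformChain([true]), inten, "linear")
        out = {}
        for sigma in (2.0, 1.0):
            chain = register_deformable(
                inten, moving, RegistrationConfig(levels=2, max_iters=15,
                                                  smoothing_sigma=sigma))
            warped = apply_transform(moving, chain, inten, "linear")
            out[sigma] = similarity(inten, warped, "msd")
        assert out[1.0] <= out[2.0] * (1 + 1e-9)


class TestMultichannel:
    def test_single_channel_matches_deformable(self, phantom32):
        inten = phantom32[0]
        true = _sinusoid_field(inten, 1.5)
        moving = apply_transform(inten, TransformChain([true]), inten, "linear")
        cfg = RegistrationConfig(levels=2, max_iters=10)
        a = register_deformable(inten, moving, cfg)
        b = register_multichannel([inten], [moving], cfg)
        np.testing.assert_array_equal(a.steps[0].vectors, b.steps[0].vectors)

    def test_duplicated_channels_match_single(self, phantom32):
        inten = phantom32[0]
        true = _sinusoid_field(inten, 1.5)
        moving = apply_transform(inten, TransformChain([true]), inten, "linear")
        cfg1 = RegistrationConfig(levels=2, max_iters=10)
        cfg2 = RegistrationConfig(levels=2, max_iters=10,
                                  channel_weights=(0.5, 0.5))
        a = register_multichannel([inten], [moving], cfg1)
        b = register_multichannel([inten, inten], [moving, moving], cfg2)
        np.testing.assert_allclose(a.steps[0].vectors, b.steps[0].vectors,
                                   atol=1e-9)

    def test_zero_weight_channel_is_ignored(self, phantom32):
        inten, _, mask = phantom32
        true = _sinusoid_field(inten, 1.5)
        moving = apply_transform(inten, TransformChain([true]), inten, "linear")
        junk = inten.like(np.random.default_rng(1).random(inten.shape))
        cfg1 = RegistrationConfig(levels=2, max_iters=10)
        cfg2 = RegistrationConfig(levels=2, max_iters=10,
                                  channel_weights=(1.0, 0.0))
        a = register_multichannel([inten], [moving], cfg1)
        b = register_multichannel([inten, junk], [moving, junk], cfg2)
        pts = inten.grid_world_points()[::53]
        diff = np.abs(a.apply_points(pts) - b.apply_points(pts))
        assert diff.max() / min(inten.spacing) < 0.1

    def test_channel_count_mismatch_rejected(self, phantom32):
        inten = phantom32[0]
        with pytest.raises(ValueError, match="channel count"):
            register_multichannel([inten, inten], [inten])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="channel_weights"):
            RegistrationConfig(channel_weights=(0.0, 0.0))
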