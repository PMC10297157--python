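"""Registration: resampling, header-offset alignment, cropping, mosaic, composite."""

import numpy as np
import pytest

from srbpmri.io import CHANNELS, SequenceImage
from srbpmri.registration import (
    align_by_offsets,
    build_hypercube,
    color_composite,
    crop_and_stack,
    detection_centroid,
    mask_centroid,
    resample_to_reference,
    select_reference,
    stitch_mosaic,
)
from srbpmri.synthetic import PhantomSpec, generate_phantom


def seq(arr, spacing=(3.0, 2.0, 2.0), origin=(0.0, 0.0, 0.0), channel="ADC"):
    return SequenceImage(np.asarray(arr, float), spacing, origin, channel)


class TestResample:
    def test_identity_on_reference_grid(self, rng):
        ref = seq(rng.standard_normal((4, 8, 8)))
        out, valid = resample_to_reference(ref, ref)
        assert np.array_equal(out.array, ref.array)
        assert valid.all()

    def test_constant_volume_stays_constant(self, rng):
        src = seq(np.full((4, 16, 16), 3.7), spacing=(3.0, 1.0, 1.0), channel="T2")
        ref = seq(np.zeros((4, 8, 8)), spacing=(3.0, 2.0, 2.0))
        out, valid = resample_to_reference(src, ref)
        assert np.allclose(out.array[valid], 3.7)

    def test_linear_ramp_downsampled_matches_analytic(self):
        # I(x) = x on a 1 mm grid; sampling at 2 mm centers must return
        # the analytic ramp exactly (bilinear is exact for linear fields)
        n = 16
        ramp = np.tile(np.arange(n, dtype=float), (1, n, 1))
        src = seq(ramp, spacing=(3.0, 1.0, 1.0), channel="HBV")
        ref = seq(np.zeros((1, 8, 8)), spacing=(3.0, 2.0, 2.0))
        out, valid = resample_to_reference(src, ref)
        expected = np.arange(8) * 2.0
        assert np.allclose(out.array[0, 0][valid[0, 0]], expected[valid[0, 0]])


class TestAlign:
    def test_identical_origins_no_shift(self, rng):
        ref = seq(rng.standard_normal((3, 8, 8)))
        out, valid = align_by_offsets(ref, np.ones(ref.array.shape, bool), ref)
        assert np.array_equal(out.array, ref.array)
        assert valid.all()

    def test_impulse_displaced_by_two_voxels(self):
        arr = np.zeros((1, 9, 9))
        arr[0, 4, 4] = 1.0
        # origin offset of exactly +2 reference voxels in the column axis
        moving = seq(arr, origin=(0.0, 0.0, 2 * 2.0), channel="HBV")
        ref = seq(np.zeros((1, 9, 9)))
        out, _ = align_by_offsets(moving, np.ones(arr.shape, bool), ref)
        assert out.array[0, 4, 6] == 1.0
        assert out.array.sum() == 1.0

    def test_extra_manual_shift_applies(self):
        arr = np.zeros((1, 9, 9))
        arr[0, 4, 4] = 1.0
        ref = seq(np.zeros((1, 9, 9)))
        out, _ = align_by_offsets(seq(arr), np.ones(arr.shape, bool), ref, extra_shift=(1, -2))
        assert out.array[0, 5, 2] == 1.0

    def test_axial_slice_selection_by_world_z(self, rng):
        vals = rng.standard_normal((4, 4, 4))
        moving = seq(vals, origin=(3.0, 0, 0))  # one slice later in z
        ref = seq(np.zeros((4, 4, 4)))
        out, valid = align_by_offsets(moving, np.ones(vals.shape, bool), ref)
        # ref slice k sits at z=3k; moving slice j at z=3(j+1) -> out[k]=vals[k-1]
        assert np.array_equal(out.array[1], vals[0])
        assert not valid[0].any()  # no moving data at z=0

    def test_disjoint_axial_ranges_rejected(self, rng):
        moving = seq(rng.standard_normal((2, 4, 4)), origin=(100.0, 0, 0))
        ref = seq(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError, match="disjoint"):
            align_by_offsets(moving, np.ones((2, 4, 4), bool), ref)


class TestCropAndStack:
    @staticmethod
    def _triple(rng, shape=(3, 8, 8)):
        return {ch: seq(rng.standard_normal(shape), channel=ch) for ch in CHANNELS}

    def test_identical_extents_nothing_cropped(self, rng):
        seqs = self._triple(rng)
        valids = {ch: np.ones((3, 8, 8), bool) for ch in CHANNELS}
        cube = crop_and_stack(
            seqs, valids, np.ones((3, 8, 8), bool), np.zeros((3, 8, 8), bool),
            (3.0, 2.0, 2.0), (0, 0, 0),
        )
        assert cube.grid_shape == (3, 8, 8)

    def test_missing_columns_dropped(self, rng):
        seqs = self._triple(rng)
        valids = {ch: np.ones((3, 8, 8), bool) for ch in CHANNELS}
        valids["T2"][:, :, -4:] = False
        cube = crop_and_stack(
            seqs, valids, np.ones((3, 8, 8), bool), np.zeros((3, 8, 8), bool),
            (3.0, 2.0, 2.0), (0, 0, 0),
        )
        assert cube.grid_shape == (3, 8, 4)

    def test_empty_intersection_rejected(self, rng):
        seqs = self._triple(rng)
        valids = {ch: np.zeros((3, 8, 8), bool) for ch in CHANNELS}
        with pytest.raises(ValueError, match="empty intersection"):
            crop_and_stack(
                seqs, valids, np.ones((3, 8, 8), bool), np.zeros((3, 8, 8), bool),
                (3.0, 2.0, 2.0), (0, 0, 0),
            )

    def test_misaligned_trio_all_finite(self, small_spec, rng):
        spec = small_spec
        spec.channel_offset_mm = {"ADC": (0, 0, 0), "HBV": (0, 4.8, -2.4), "T2": (0, -2.4, 4.8)}
        seqs, prostate, tumor = generate_phantom(spec, 3)
        cube = build_hypercube(seqs, prostate, tumor)
        assert np.isfinite(cube.channels[:, cube.valid]).all()
        assert cube.valid.all()  # valid mask trims to the common FOV box


class TestMosaic:
    @staticmethod
    def _cube(rng, shape=(8, 16, 16)):
        from tests_util_cube import make_simple_cube

        return make_simple_cube(rng, shape)

    def test_single_slice_equals_slice(self, rng):
        cube = self._cube(rng, (1, 6, 6))
        mos = stitch_mosaic(cube)
        assert np.array_equal(mos.mosaic[:, :, :6], cube.channels[:, 0])

    def test_shape_arithmetic(self, rng):
        cube = self._cube(rng, (8, 64, 64))
        mos = stitch_mosaic(cube)
        assert mos.mosaic.shape == (3, 64, 8 * 64)

    def test_round_trip_bijection_exhaustive(self, rng):
        cube = self._cube(rng, (3, 4, 5))
        mos = stitch_mosaic(cube)
        seen = set()
        for s in range(3):
            for r in range(4):
                for c in range(5):
                    rr, col = mos.to_mosaic(s, r, c)
                    assert mos.to_volume(rr, col) == (s, r, c)
                    assert mos.mosaic[0, rr, col] == cube.channels[0, s, r, c]
                    seen.add((rr, col))
        assert len(seen) == 3 * 4 * 5


class TestComposite:
    def test_green_tumor_convention(self, rng):
        from tests_util_cube import make_simple_cube

        cube = make_simple_cube(rng, (2, 6, 6))
        # voxel at channel-min ADC, channel-max HBV, channel-min T2
        sel = cube.prostate_mask & cube.valid
        cube.channels[0][1, 3, 3] = cube.channels[0][sel].min()
        cube.channels[1][1, 3, 3] = cube.channels[1][sel].max()
        cube.channels[2][1, 3, 3] = cube.channels[2][sel].min()
        rgb = color_composite(cube)
        assert np.allclose(rgb[1, 3, 3], [0.0, 1.0, 0.0])

    def test_all_channels_max_is_white(self, rng):
        from tests_util_cube import make_simple_cube

        cube = make_simple_cube(rng, (2, 6, 6))
        sel = cube.prostate_mask & cube.valid
        for i in range(3):
            cube.channels[i][0, 2, 2] = cube.channels[i][sel].max()
        rgb = color_composite(cube)
        assert np.allclose(rgb[0, 2, 2], [1.0, 1.0, 1.0])

    def test_constant_channel_zeroed_with_warning(self, rng, caplog):
        from tests_util_cube import make_simple_cube

        cube = make_simple_cube(rng, (2, 6, 6))
        cube.channels[2][:] = 5.0
        with caplog.at_level("WARNING"):
            rgb = color_composite(cube)
        assert np.all(rgb[..., 2] == 0.0)
        assert any("zero dynamic range" in r.message for r in caplog.records)

    def test_synthetic_tumor_is_green_dominant(self, small_spec):
        spec = small_spec
        spec.contrast_scale = 1.0
        seqs, prostate, tumor = generate_phantom(spec, 5)
        cube = build_hypercube(seqs, prostate, tumor)
        rgb = color_composite(cube)
        tm = cube.tumor_mask & cube.valid
        mean_rgb = rgb[tm].mean(axis=0)
        assert mean_rgb[1] > mean_rgb[0] and mean_rgb[1] > mean_rgb[2]


class TestRegistrationFidelity:
    @pytest.mark.parametrize("off_vox", [(0, 1, -2), (1, 5, 5), (0, -4, 3)])
    def test_tumor_centroid_recovered_within_one_voxel(self, off_vox, small_spec):
        # known injected offsets up to 5 voxels plus resolution mismatch;
        # after registration each channel's detection blob must sit on the
        # tumor mask centroid
        spec = small_spec
        spec.ref_shape = (8, 40, 40)
        spec.prostate_semiaxes = (3.0, 12.0, 12.0)
        spec.contrast_scale = 1.2  # 6 sigma-steps at grade 5: clean blobs
        spec.channel_spacing = {
            "ADC": (3.6, 2.4, 2.4),
            "HBV": (3.6, 1.2, 1.2),
            "T2": (3.6, 0.8, 0.8),
        }
        dz, dy, dx = off_vox
        spec.channel_offset_mm = {
            "ADC": (0.0, 0.0, 0.0),
            "HBV": (dz * 3.6, dy * 2.4, dx * 2.4),
            "T2": (-dz * 3.6, -dy * 2.4, -dx * 2.4),
        }
        seqs, prostate, tumor = generate_phantom(spec, 5)
        cube = build_hypercube(seqs, prostate, tumor)
        ref_centroid = mask_centroid(cube.tumor_mask)
        signs = (-1.0, +1.0, -1.0)
        region = cube.prostate_mask & cube.valid
        for i, sign in enumerate(signs):
            blob = detection_centroid(cube.channels[i], region, sign, nsigma=3.0)
            assert np.abs(blob - ref_centroid).max() < 1.0


def test_reference_is_coarsest_channel(rng):
    seqs = {
        "ADC": seq(rng.standard_normal((2, 4, 4)), spacing=(3.0, 2.0, 2.0), channel="ADC"),
        "HBV": seq(rng.standard_normal((2, 8, 8)), spacing=(3.0, 1.0, 1.0), channel="HBV"),
        "T2": seq(rng.standard_normal((2, 16, 16)), spacing=(3.0, 0.5, 0.5), channel="T2"),
    }
    assert select_reference(seqs) == "ADC"
    # tie on coarseness breaks toward ADC
    seqs["HBV"] = seq(rng.standard_normal((2, 4, 4)), spacing=(3.0, 2.0, 2.0), channel="HBV")
    assert select_reference(seqs) == "ADC"
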