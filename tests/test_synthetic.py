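"""Phantom generation and the LSFM degradation forward model."""

import warnings

import numpy as np
import pytest

from uitrans import synthetic as syn
from uitrans.metrics import compute_snr_db, michelson_contrast, otsu_masks
from uitrans.volume import Volume3D


class TestHeartPhantom:
    def test_seeded_determinism_bitwise(self):
        a = syn.generate_heart_phantom((16, 20, 24), seed=7)
        b = syn.generate_heart_phantom((16, 20, 24), seed=7)
        assert np.array_equal(a.values, b.values)
        c = syn.generate_heart_phantom((16, 20, 24), seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_zero_wall_thickness_gives_empty_foreground(self):
        geom = syn.HeartGeometry(wall_sigma=0.0, background=0.02)
        ph = syn.generate_heart_phantom((16, 16, 16), geom, seed=0)
        assert np.all(ph.values <= geom.background + 1e-6)

    def test_foreground_fraction_default_geometry(self):
        ph = syn.generate_heart_phantom((64, 64, 64), seed=1)
        frac = float((ph.values > 0.1).mean())
        assert 0.02 <= frac <= 0.30

    def test_values_bounded_and_finite(self):
        ph = syn.generate_heart_phantom((16, 16, 16), seed=2)
        assert np.all(np.isfinite(ph.values))
        assert ph.values.min() >= 0 and ph.values.max() <= 1

    @pytest.mark.parametrize("shape", [(0, 16, 16), (16, -1, 16), (7, 16, 16)])
    def test_invalid_shapes_rejected(self, shape):
        with pytest.raises(ValueError):
            syn.generate_heart_phantom(shape, seed=0)


class TestBeating:
    def test_zero_amplitude_freezes_all_frames(self, phantom32):
        beat = syn.deform_beating(phantom32, 8, 4, amplitude=0.0)
        for f in beat.frames:
            assert np.array_equal(f.values, phantom32.values)

    def test_periodicity_by_construction(self, phantom32):
        beat = syn.deform_beating(phantom32, 12, 5, amplitude=0.1)
        for t in range(12 - 5):
            assert np.array_equal(beat.frames[t].values,
                                  beat.frames[t + 5].values)

    def test_phase0_is_a_cyclic_shift(self, phantom32):
        a = syn.deform_beating(phantom32, 10, 8, phase0=0, amplitude=0.1)
        b = syn.deform_beating(phantom32, 10, 8, phase0=5, amplitude=0.1)
        for k in range(8):
            assert np.array_equal(b.frames[k].values,
                                  a.frames[(k + 5) % 8].values)

    def test_excessive_amplitude_clipped_with_warning(self, phantom32):
        with pytest.warns(UserWarning, match="clipped"):
            syn.deform_beating(phantom32, 4, 4, amplitude=5.0)

    def test_preconditions(self, phantom32):
        with pytest.raises(ValueError):
            syn.deform_beating(phantom32, 3, 4)
        with pytest.raises(ValueError):
            syn.deform_beating(phantom32, 8, 4, phase0=4)


class TestPSF:
    def test_constant_volume_unchanged(self):
        vol = Volume3D(np.full((16, 16, 16), 0.7, np.float32))
        out = syn.apply_psf(vol, syn.DegradationParams())
        np.testing.assert_allclose(out.values, 0.7, rtol=1e-5)

    def test_impulse_second_moments_match_sigma(self):
        # voxel size 1 um so sigma_um == sigma_vox: (z, y, x) = (2, 1, 1)
        v = np.zeros((33, 33, 33), np.float32)
        v[16, 16, 16] = 1.0
        params = syn.DegradationParams(lateral_sigma_um=1.0, axial_sigma_um=2.0)
        out = syn.apply_psf(Volume3D(v, (1.0, 1.0, 1.0)), params).values
        coords = np.arange(33) - 16.0
        total = out.sum()
        for axis, sigma in zip(range(3), (2.0, 1.0, 1.0)):
            marg = out.sum(axis=tuple(i for i in range(3) if i != axis))
            second = float((marg * coords ** 2).sum() / total)
            assert abs(second - sigma ** 2) / sigma ** 2 < 0.05

    def test_intensity_conserved_within_one_percent(self, phantom32):
        vol = phantom32.as_volume()
        out = syn.apply_psf(vol, syn.economy_input_params())
        assert abs(out.values.sum() - vol.values.sum()) / vol.values.sum() < 0.01


class TestHaze:
    def test_zero_strength_adds_only_offset(self, phantom32):
        params = syn.DegradationParams(haze_strength=0.0, background_offset=0.03)
        out = syn.add_scatter_haze(phantom32.as_volume(), params)
        np.testing.assert_allclose(out.values,
                                   phantom32.values + 0.03, atol=1e-6)

    def test_perfect_confocal_rejection_equals_no_haze(self, phantom32):
        rej0 = syn.DegradationParams(haze_strength=0.7, confocal_rejection=0.0,
                                     background_offset=0.02)
        none = syn.DegradationParams(haze_strength=0.0, background_offset=0.02)
        a = syn.add_scatter_haze(phantom32.as_volume(), rej0)
        b = syn.add_scatter_haze(phantom32.as_volume(), none)
        np.testing.assert_allclose(a.values, b.values, atol=1e-7)

    def test_intensity_budget_with_normalized_kernel(self):
        # content away from boundaries; kernel 4 voxels wide in a 32^3 grid
        ph = syn.generate_heart_phantom((32, 32, 32), seed=4)
        vol = Volume3D(ph.values, (1.0, 1.0, 1.0))
        params = syn.DegradationParams(haze_strength=0.5, confocal_rejection=1.0,
                                       background_offset=0.0,
                                       haze_kernel_sigma_um=4.0)
        out = syn.add_scatter_haze(vol, params)
        ratio = out.values.sum() / vol.values.sum()
        assert abs(ratio - 1.5) < 0.02 * 1.5


class TestNoise:
    def test_zero_signal_zero_read_noise_is_zero(self):
        vol = Volume3D(np.zeros((8, 8, 8), np.float32))
        params = syn.DegradationParams(read_sigma=0.0)
        out = syn.add_noise(vol, params, seed=0)
        assert np.all(out.values == 0)

    def test_poisson_gaussian_variance(self):
        # var = v/gain + read^2 = 0.5/100 + 0.02^2 = 0.0054 on 10^6 voxels
        vol = Volume3D(np.full((100, 100, 100), 0.5, np.float32))
        params = syn.DegradationParams(photon_gain=100.0, read_sigma=0.02)
        out = syn.add_noise(vol, params, seed=1)
        var = float(out.values.var())
        assert abs(var - 0.0054) / 0.0054 < 0.03

    def test_seeded_determinism(self, phantom32):
        params = syn.economy_input_params()
        a = syn.add_noise(phantom32.as_volume(), params, seed=9)
        b = syn.add_noise(phantom32.as_volume(), params, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_negative_intensities_clamped_with_warning(self):
        vol = Volume3D(np.full((8, 8, 8), -0.1, np.float32))
        with pytest.warns(UserWarning, match="clamped"):
            out = syn.add_noise(vol, syn.DegradationParams(read_sigma=0.0), 0)
        assert np.all(out.values == 0)


class TestTrainingPairs:
    def test_clean_gt_params_give_blurred_phantom(self, phantom32):
        gt_params = syn.DegradationParams(haze_strength=0.0,
                                          background_offset=0.0,
                                          photon_gain=1e12, read_sigma=0.0,
                                          confocal_rejection=0.0)
        pair = syn.make_training_pair(phantom32, gt_params=gt_params, seed=0)
        blurred = syn.apply_psf(phantom32.as_volume(), gt_params)
        np.testing.assert_allclose(pair.ground_truth.values, blurred.values,
                                   atol=1e-4)

    def test_pair_reproducible_and_aligned(self, phantom32):
        a = syn.make_training_pair(phantom32, seed=5)
        b = syn.make_training_pair(phantom32, seed=5)
        assert np.array_equal(a.input.values, b.input.values)
        assert np.array_equal(a.ground_truth.values, b.ground_truth.values)
        assert a.input.shape == a.ground_truth.shape

    def test_gt_quality_exceeds_input_quality(self):
        """SNR and contrast ordering holds across seeds (economy vs quality)."""
        wins_snr = wins_contrast = 0
        n = 20
        for seed in range(n):
            ph = syn.generate_heart_phantom((24, 24, 24), seed=seed)
            pair = syn.make_training_pair(ph, seed=seed)
            fg, bg = otsu_masks(pair.ground_truth)
            wins_snr += (compute_snr_db(pair.input, fg, bg)
                         < compute_snr_db(pair.ground_truth, fg, bg))
            wins_contrast += (michelson_contrast(pair.input, fg, bg)
                              < michelson_contrast(pair.ground_truth, fg, bg))
        assert wins_snr >= 0.95 * n
        assert wins_contrast >= 0.95 * n

    def test_inverted_quality_params_warn(self, phantom32):
        with pytest.warns(UserWarning):
            syn.make_training_pair(phantom32,
                                   input_params=syn.quality_gt_params(),
                                   gt_params=syn.economy_input_params(),
                                   seed=0)


def test_snr_monotone_in_noise_parameters(phantom32):
    """SNR non-increasing in read noise, non-decreasing in photon budget."""
    fgbg = None
    snrs_read, snrs_gain = [], []
    for read in (0.01, 0.05, 0.15):
        params = syn.economy_input_params(read_sigma=read)
        vol = syn.degrade(phantom32, params, seed=2)
        if fgbg is None:
            clean = syn.quality_gt_params(photon_gain=1e9, read_sigma=0.0)
            fgbg = otsu_masks(syn.degrade(phantom32, clean, seed=2))
        snrs_read.append(compute_snr_db(vol, *fgbg))
    for gain in (5.0, 50.0, 500.0):
        params = syn.economy_input_params(photon_gain=gain)
        vol = syn.degrade(phantom32, params, seed=2)
        snrs_gain.append(compute_snr_db(vol, *fgbg))
    assert snrs_read[0] >= snrs_read[1] >= snrs_read[2]
    assert snrs_gain[0] <= snrs_gain[1] <= snrs_gain[2]


def test_dataset_generation_deterministic():
    a = syn.generate_pair_dataset(3, (16, 16, 16), seed=2)
    b = syn.generate_pair_dataset(3, (16, 16, 16), seed=2)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.input.values, pb.input.values)
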