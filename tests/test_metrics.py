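"""Image-quality metrics against brute-force definitional oracles, and
the acquisition-economy arithmetic."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from uitrans import metrics as M


@pytest.fixture
def small_pair(rng):
    a = rng.random((6, 16, 16)).astype(np.float32)
    b = np.clip(a + 0.05 * rng.standard_normal(a.shape), 0, 1).astype(np.float32)
    return a, b


class TestNRMSE:
    def test_identity(self, small_pair):
        a, _ = small_pair
        assert M.compute_nrmse(a, a) == 0.0

    def test_constant_offset_closed_form(self, rng):
        ref = rng.random((4, 4, 4)).astype(np.float32)
        ref = (ref - ref.min()) / (ref.max() - ref.min())  # range exactly 1
        assert M.compute_nrmse(ref + 0.1, ref) == pytest.approx(0.1, abs=1e-6)

    def test_matches_definitional_oracle(self, rng):
        t = rng.random((2, 2, 2)).astype(np.float64)
        r = rng.random((2, 2, 2)).astype(np.float64)
        oracle = np.sqrt(((t - r) ** 2).sum() / 8) / (r.max() - r.min())
        assert M.compute_nrmse(t, r) == pytest.approx(oracle, abs=1e-10)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            M.compute_nrmse(np.ones((4, 4, 4)), np.ones((4, 4, 4)))


class TestPearson:
    def test_identity_and_anticorrelation(self, small_pair):
        a, _ = small_pair
        assert M.compute_pearson(a, a) == pytest.approx(1.0)
        assert M.compute_pearson(a, -a + 3.0) == pytest.approx(-1.0)

    def test_matches_oracle_on_eight_voxels(self):
        a = np.array([0., 1., 2., 3., 4., 5., 6., 7.]).reshape(2, 2, 2)
        b = np.array([1., 0., 3., 2., 5., 4., 7., 8.]).reshape(2, 2, 2)
        am, bm = a.mean(), b.mean()
        oracle = (((a - am) * (b - bm)).sum()
                  / np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum()))
        assert M.compute_pearson(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            M.compute_pearson(np.ones((2, 2, 2)), np.zeros((2, 2, 2)))


class TestPSNR:
    def test_closed_form_20db(self, rng):
        r = rng.random((8, 8, 8))
        t = r + 0.1  # MSE = 0.01, range 1 -> 20 dB
        assert M.compute_psnr(t, r, 1.0) == pytest.approx(20.0, abs=1e-6)

    def test_identical_volumes_capped(self, small_pair):
        a, _ = small_pair
        assert M.compute_psnr(a, a) == M.PSNR_CAP_DB

    def test_matches_definitional_oracle(self, rng):
        t = rng.random((3, 3, 3))
        r = rng.random((3, 3, 3))
        oracle = 10 * np.log10(1.0 / ((t - r) ** 2).mean())
        assert M.compute_psnr(t, r) == pytest.approx(oracle, rel=1e-9)


class TestSSIM:
    def test_identity_is_one(self, small_pair):
        a, _ = small_pair
        assert M.compute_ssim(a, a) == pytest.approx(1.0)

    def test_noise_strictly_degrades(self, small_pair, rng):
        a, b = small_pair
        noisier = np.clip(b + 0.3 * rng.standard_normal(b.shape), 0, 1)
        assert M.compute_ssim(noisier, a) < M.compute_ssim(b, a)

    def test_single_slice_matches_independent_formula(self, rng):
        x = rng.random((1, 24, 24)).astype(np.float64)
        y = np.clip(x + 0.1 * rng.standard_normal(x.shape), 0, 1)

        def oracle(a, b, drange=1.0, sigma=1.5, K1=0.01, K2=0.03):
            filt = lambda im: gaussian_filter(im, sigma, truncate=3.5,
                                              mode="nearest")
            ua, ub = filt(a), filt(b)
            va = filt(a * a) - ua * ua
            vb = filt(b * b) - ub * ub
            vab = filt(a * b) - ua * ub
            C1, C2 = (K1 * drange) ** 2, (K2 * drange) ** 2
            s = (((2 * ua * ub + C1) * (2 * vab + C2))
                 / ((ua ** 2 + ub ** 2 + C1) * (va + vb + C2)))
            pad = int(3.5 * sigma + 0.5)
            return s[pad:-pad, pad:-pad].mean()

        assert M.compute_ssim(y, x) == pytest.approx(
            oracle(x[0], y[0]), abs=1e-6)

    def test_too_small_slices_rejected(self):
        with pytest.raises(ValueError, match="window"):
            M.compute_ssim(np.zeros((2, 8, 8)), np.ones((2, 8, 8)))


class TestSNR:
    def test_closed_form_20db(self):
        v = np.zeros((10, 10, 10))
        fg = np.zeros_like(v, bool)
        fg[:5] = True
        rng = np.random.default_rng(0)
        v[~fg] = rng.normal(0, 1.0, size=int((~fg).sum()))
        v[~fg] -= v[~fg].mean()
        v[~fg] /= v[~fg].std()          # mu_bg = 0, sigma_bg = 1 exactly
        v[fg] = 10.0                     # mu_fg - mu_bg = 10 -> 20 dB
        assert M.compute_snr_db(v, fg, ~fg) == pytest.approx(20.0, abs=1e-9)

    def test_no_contrast_reports_floor(self):
        # exact mu_fg == mu_bg: background alternates +-1 (mean exactly 0)
        v = np.zeros((6, 6, 6))
        fg = np.zeros_like(v, bool)
        fg[:3] = True
        bgvals = np.ones(int((~fg).sum()))
        bgvals[::2] = -1.0
        v[~fg] = bgvals
        assert M.compute_snr_db(v, fg, ~fg) == M.SNR_FLOOR_DB
        # and a clearly inverted foreground also reports the floor
        v[fg] = -5.0
        assert M.compute_snr_db(v, fg, ~fg) == M.SNR_FLOOR_DB

    def test_masks_validated(self):
        v = np.zeros((4, 4, 4))
        full = np.ones_like(v, bool)
        with pytest.raises(ValueError):
            M.compute_snr_db(v, full, full)  # not disjoint
        with pytest.raises(ValueError):
            M.compute_snr_db(v, np.zeros_like(full), ~full)  # empty


class TestContrast:
    def test_self_enhancement_is_one(self, small_pair):
        a, _ = small_pair
        fg = a > np.median(a)
        assert M.compute_contrast_enhancement(a, a, fg, ~fg) == pytest.approx(1.0)

    def test_removing_uniform_haze_raises_contrast(self, rng):
        clean = rng.random((8, 8, 8)).astype(np.float64) + 0.1
        fg = clean > np.median(clean)
        hazy = clean + 0.5
        enh = M.compute_contrast_enhancement(clean, hazy, fg, ~fg)
        assert enh > 1.0

    def test_simulator_haze_contrast_matches_closed_form(self):
        """Uniform haze b scales Michelson contrast by a closed-form factor."""
        from uitrans import synthetic as syn
        ph = syn.generate_heart_phantom((24, 24, 24), seed=2)
        fg, bg = M.otsu_masks(ph.values)
        b = 0.3
        hazy = ph.values + b
        mu_fg, mu_bg = ph.values[fg].mean(), ph.values[bg].mean()
        # dehazing a uniform offset b enhances Michelson contrast by
        # (S + 2b) / S with S = mu_fg + mu_bg
        S = mu_fg + mu_bg
        assert M.compute_contrast_enhancement(ph.values, hazy, fg, bg) \
            == pytest.approx((S + 2 * b) / S, rel=1e-5)


class TestEconomy:
    def test_gt_versus_training_input(self):
        gt = M.AcquisitionSpec(10.0, 300.0)
        inp = M.AcquisitionSpec(0.1, 10.0)
        dose, t = M.economy_ratios(gt, inp)
        assert dose == pytest.approx(3000.0)
        assert t == pytest.approx(30.0)

    def test_identical_specs(self):
        a = M.AcquisitionSpec(1.0, 5.0, 100)
        assert M.economy_ratios(a, a) == (1.0, 1.0)

    def test_in_vivo_exposure_fraction(self):
        invivo = M.AcquisitionSpec(0.1, 3.0)
        gt = M.AcquisitionSpec(10.0, 300.0)
        dose, t = M.economy_ratios(invivo, gt)
        assert dose == pytest.approx(1e-4)   # 0.01% < 0.03% bound
        assert t == pytest.approx(0.01)      # 1% < 3.3% bound


class TestReports:
    def test_triplet_report_and_mask_independence(self, rng):
        from uitrans import synthetic as syn
        ph = syn.generate_heart_phantom((16, 16, 16), seed=1)
        pair = syn.make_training_pair(ph, seed=1)
        reports = M.evaluate_triplet(pair.input.values,
                                     pair.ground_truth.values,
                                     pair.ground_truth.values)
        r = reports["restored"]
        assert r.nrmse == 0.0 and r.ssim == pytest.approx(1.0)
        assert r.psnr_capped
        # reference metrics ignore masks entirely
        fg, bg = M.otsu_masks(pair.ground_truth.values)
        alt = M.evaluate_triplet(pair.input.values, pair.ground_truth.values,
                                 pair.ground_truth.values,
                                 fg_mask=np.roll(fg, 3, 0),
                                 bg_mask=np.roll(bg, 3, 0))
        for key in ("nrmse", "pearson", "psnr_db", "ssim"):
            assert getattr(alt["input"], key) == getattr(reports["input"], key)

    def test_noise_monotonically_degrades_reference_metrics(self, rng):
        base = rng.random((8, 16, 16)).astype(np.float64)
        levels = [0.02, 0.1, 0.3]
        psnr, ssim, nrmse = [], [], []
        for s in levels:
            noisy = base + s * np.random.default_rng(5).standard_normal(base.shape)
            psnr.append(M.compute_psnr(noisy, base))
            ssim.append(M.compute_ssim(noisy, base))
            nrmse.append(M.compute_nrmse(noisy, base))
        assert psnr[0] > psnr[1] > psnr[2]
        assert ssim[0] > ssim[1] > ssim[2]
        assert nrmse[0] < nrmse[1] < nrmse[2]

    def test_pearson_affine_invariance(self, small_pair):
        a, b = small_pair
        assert M.compute_pearson(2.0 * a + 1.0, b) == pytest.approx(
            M.compute_pearson(a, b), abs=1e-6)
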