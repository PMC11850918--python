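"""Quantitative evaluation of restored volumes.

Six metrics are reported for (input, restored, ground-truth) triplets:
NRMSE, Pearson correlation, PSNR, SSIM, SNR and contrast enhancement,
plus the acquisition-economy ratios (light dose, acquisition time)
between two acquisition settings.

Definitions used here (reference-based metrics follow the standard
formulas; SNR and contrast, whose exact formulas vary across the
literature, are fixed as):

    SNR  = 10 log10( (mu_fg - mu_bg)^2 / sigma_bg^2 )    [dB]
    C    = (mu_fg - mu_bg) / (mu_fg + mu_bg)             (Michelson)
    contrast enhancement = C_test / C_input

with foreground/background masks obtained by Otsu thresholding of the
ground-truth volume (or supplied by the caller), so that input, restored
and ground truth are compared over identical regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity

from .volume import Volume3D

#: PSNR reported when MSE == 0 (identical volumes), flagged in reports.
PSNR_CAP_DB = 200.0
#: SNR floor reported when the foreground mean does not exceed background.
SNR_FLOOR_DB = -200.0


def _vals(v) -> np.ndarray:
    # keep the caller's precision: oracle comparisons are done in float64
    if isinstance(v, Volume3D):
        return v.values
    return np.asarray(v)


def _check_same_shape(a: np.ndarray, b: np.ndarray):
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")


def compute_nrmse(test, reference) -> float:
    """RMSE normalized by the reference intensity range (max - min)."""
    t, r = _vals(test), _vals(reference)
    _check_same_shape(t, r)
    rng = float(r.max() - r.min())
    if rng == 0:
        raise ValueError("reference volume is constant; NRMSE undefined")
    rmse = float(np.sqrt(np.mean((t.astype(np.float64) - r) ** 2)))
    return rmse / rng


def compute_pearson(a, b) -> float:
    """Product-moment correlation over all voxels (computed in float64)."""
    _check_same_shape(_vals(a), _vals(b))
    x = _vals(a).ravel().astype(np.float64)
    y = _vals(b).ravel().astype(np.float64)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input; Pearson undefined")
    return float(stats.pearsonr(x, y).statistic)


def compute_psnr(test, reference, data_range: float = 1.0) -> float:
    """10 log10(range^2 / MSE) in dB, capped at PSNR_CAP_DB when MSE = 0."""
    t, r = _vals(test), _vals(reference)
    _check_same_shape(t, r)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((t.astype(np.float64) - r) ** 2))
    if mse == 0:
        return PSNR_CAP_DB
    return float(10.0 * np.log10(data_range ** 2 / mse))


def compute_ssim(test, reference, data_range: float = 1.0) -> float:
    """Mean SSIM over z-slices (Gaussian window sigma=1.5, K1=0.01, K2=0.03)."""
    t, r = _vals(test), _vals(reference)
    _check_same_shape(t, r)
    if min(t.shape[1], t.shape[2]) < 11:
        raise ValueError("slices smaller than the 11-pixel SSIM window")
    vals = [structural_similarity(r[z], t[z], data_range=data_range,
                                  gaussian_weights=True, sigma=1.5,
                                  use_sample_covariance=False,
                                  K1=0.01, K2=0.03)
            for z in range(t.shape[0])]
    return float(np.mean(vals))


def otsu_masks(reference) -> tuple[np.ndarray, np.ndarray]:
    """Foreground/background masks by Otsu thresholding of ``reference``."""
    r = _vals(reference)
    thr = threshold_otsu(r)
    fg = r > thr
    if not fg.any() or fg.all():
        raise ValueError("Otsu threshold produced an empty mask")
    return fg, ~fg


def compute_snr_db(volume, fg_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """10 log10((mu_fg - mu_bg)^2 / sigma_bg^2), in dB."""
    v = _vals(volume)
    fg_mask, bg_mask = np.asarray(fg_mask, bool), np.asarray(bg_mask, bool)
    if fg_mask.shape != v.shape or bg_mask.shape != v.shape:
        raise ValueError("mask shape must match the volume")
    if not fg_mask.any() or not bg_mask.any():
        raise ValueError("masks must be non-empty")
    if (fg_mask & bg_mask).any():
        raise ValueError("foreground and background masks must be disjoint")
    mu_fg = float(v[fg_mask].mean())
    mu_bg = float(v[bg_mask].mean())
    sigma_bg = float(v[bg_mask].std())
    if sigma_bg == 0:
        raise ValueError("background is constant; SNR undefined")
    diff = mu_fg - mu_bg
    if diff <= 0:
        return SNR_FLOOR_DB
    return float(10.0 * np.log10(diff ** 2 / sigma_bg ** 2))


def michelson_contrast(volume, fg_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    v = _vals(volume)
    mu_fg = float(v[fg_mask].mean())
    mu_bg = float(v[bg_mask].mean())
    if mu_fg + mu_bg <= 0:
        raise ValueError(
            f"non-positive contrast denominator (mu_fg={mu_fg:.4g}, "
            f"mu_bg={mu_bg:.4g})")
    return (mu_fg - mu_bg) / (mu_fg + mu_bg)


def compute_contrast_enhancement(test, reference_input,
                                 fg_mask: np.ndarray,
                                 bg_mask: np.ndarray) -> float:
    """Ratio of Michelson contrasts, test relative to the raw input."""
    c_test = michelson_contrast(test, fg_mask, bg_mask)
    c_in = michelson_contrast(reference_input, fg_mask, bg_mask)
    if c_in == 0:
        raise ValueError("input contrast is zero; enhancement undefined")
    return float(c_test / c_in)


@dataclass
class MetricReport:
    """All metrics for one volume against a reference, JSON-serializable."""

    snr_db: float
    contrast: float
    contrast_enhancement: float
    nrmse: float
    pearson: float
    psnr_db: float
    ssim: float
    masks_provenance: str = "otsu(ground_truth)"
    psnr_capped: bool = False

    def to_dict(self) -> dict[str, Any]:
        return dict(self.__dict__)


def evaluate_triplet(input_volume, restored, ground_truth,
                     fg_mask: np.ndarray | None = None,
                     bg_mask: np.ndarray | None = None,
                     data_range: float = 1.0) -> dict[str, MetricReport]:
    """Metric reports for the input and the restored volume against GT.

    Masks default to Otsu thresholding of the ground truth so that all
    three volumes are scored over the same regions.
    """
    provenance = "user-supplied"
    if fg_mask is None or bg_mask is None:
        fg_mask, bg_mask = otsu_masks(ground_truth)
        provenance = "otsu(ground_truth)"
    out = {}
    for name, vol in (("input", input_volume), ("restored", restored)):
        psnr = compute_psnr(vol, ground_truth, data_range)
        out[name] = MetricReport(
            snr_db=compute_snr_db(vol, fg_mask, bg_mask),
            contrast=michelson_contrast(vol, fg_mask, bg_mask),
            contrast_enhancement=compute_contrast_enhancement(
                vol, input_volume, fg_mask, bg_mask),
            nrmse=compute_nrmse(vol, ground_truth),
            pearson=compute_pearson(vol, ground_truth),
            psnr_db=psnr,
            ssim=compute_ssim(vol, ground_truth, data_range),
            masks_provenance=provenance,
            psnr_capped=(psnr == PSNR_CAP_DB),
        )
    return out


# -- acquisition economy ------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionSpec:
    """One acquisition setting: laser power, per-plane exposure, plane count."""

    illumination_power_mw: float
    exposure_per_plane_ms: float
    planes: int = 1

    def __post_init__(self):
        if (self.illumination_power_mw <= 0 or self.exposure_per_plane_ms <= 0
                or self.planes <= 0):
            raise ValueError("acquisition parameters must be positive")

    @property
    def light_dose(self) -> float:
        return (self.illumination_power_mw * self.exposure_per_plane_ms
                * self.planes)

    @property
    def acquisition_time_ms(self) -> float:
        return self.exposure_per_plane_ms * self.planes


def economy_ratios(a: AcquisitionSpec, b: AcquisitionSpec) -> tuple[float, float]:
    """(light-dose ratio, acquisition-time ratio) of setting a over b."""
    return (a.light_dose / b.light_dose,
            a.acquisition_time_ms / b.acquisition_time_ms)
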