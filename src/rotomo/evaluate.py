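"""Volumetric reconstruction quality metrics and comparison reports.

Five metrics compare a reconstruction against the known ground-truth
phantom, each computed on min-max normalized volumes: voxelwise MSE, MAE and
RMSE; multiscale structural similarity (MS-SSIM, computed per axial slice
and averaged); and PSNR with data range 1.  The comparison report sets the
full-angle rotation-tomography reconstruction against the limited-angle
baseline and states the relative change per metric — a decrease for error
metrics, an increase for similarity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .phantom import Volume3D
from .rotation_tracking import AngleSeries, mean_angle_error

__all__ = [
    "MetricsReport",
    "ComparisonReport",
    "TrackingReport",
    "ms_ssim_2d",
    "volume_metrics",
    "compare_methods",
    "tracking_report",
]

# Standard per-scale weights of the multiscale SSIM (5 scales).
_MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
_PSNR_CAP = 100.0  # dB reported for identical volumes


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    mae: float
    rmse: float
    ms_ssim: float
    psnr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "rmse": self.rmse,
            "ms_ssim": self.ms_ssim,
            "psnr": self.psnr,
        }


@dataclass(frozen=True)
class ComparisonReport:
    conventional: MetricsReport
    proposed: MetricsReport
    relative_change: dict[str, float]  # percent per metric


@dataclass(frozen=True)
class TrackingReport:
    mean_error: float  # degrees
    max_error: float
    residuals: np.ndarray  # signed, degrees, per frame


def _normalize(vol: np.ndarray) -> np.ndarray:
    lo, hi = float(vol.min()), float(vol.max())
    if hi - lo == 0:
        return np.zeros_like(vol, dtype=float)
    return (vol.astype(float) - lo) / (hi - lo)


def _ssim_maps(
    x: np.ndarray, y: np.ndarray, data_range: float, sigma: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel luminance and contrast-structure SSIM components."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    blur = lambda im: ndimage.gaussian_filter(im, sigma, truncate=3.5)
    mu_x, mu_y = blur(x), blur(y)
    var_x = blur(x * x) - mu_x**2
    var_y = blur(y * y) - mu_y**2
    cov = blur(x * y) - mu_x * mu_y
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    cs = (2 * cov + c2) / (var_x + var_y + c2)
    return lum, cs


def ms_ssim_2d(
    x: np.ndarray,
    y: np.ndarray,
    data_range: float = 1.0,
    weights: tuple[float, ...] = _MSSSIM_WEIGHTS,
    min_size: int = 11,
) -> float:
    """Multiscale SSIM of two 2D images.

    Contrast-structure terms are accumulated over dyadic scales (2x average
    pooling between scales) and the luminance term enters at the coarsest
    scale; the per-scale exponents are the standard weights.  When the image
    is too small for all 5 scales (needs ``min_size`` pixels at the coarsest),
    the scale count is reduced and the weights renormalized.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("image shapes differ")
    max_scales = 1
    while (
        max_scales < len(weights)
        and min(x.shape) // (2**max_scales) >= min_size
    ):
        max_scales += 1
    w = np.asarray(weights[:max_scales])
    w = w / w.sum()

    value = 1.0
    for level in range(max_scales):
        lum, cs = _ssim_maps(x, y, data_range)
        if level == max_scales - 1:
            value *= float(np.mean(lum * cs)) ** w[level] if np.mean(lum * cs) > 0 else 0.0
        else:
            mean_cs = float(np.mean(cs))
            value *= max(mean_cs, 0.0) ** w[level]
            x = ndimage.uniform_filter(x, 2)[::2, ::2]
            y = ndimage.uniform_filter(y, 2)[::2, ::2]
    return float(np.clip(value, 0.0, 1.0))


def volume_metrics(
    recon: Volume3D | np.ndarray,
    truth: Volume3D | np.ndarray,
    normalize: bool = True,
) -> MetricsReport:
    """The five volumetric comparison metrics of a reconstruction vs truth.

    Both volumes are min-max normalized to [0, 1] (each by its own extrema)
    unless ``normalize=False``; PSNR uses data range 1 and is capped at
    100 dB for identical volumes.  MS-SSIM is computed per axial (vertical-
    axis) slice and averaged.
    """
    r = recon.data if isinstance(recon, Volume3D) else np.asarray(recon, float)
    t = truth.data if isinstance(truth, Volume3D) else np.asarray(truth, float)
    if r.shape != t.shape:
        raise ValidationError(f"volume shapes differ: {r.shape} vs {t.shape}")
    if normalize:
        r, t = _normalize(r), _normalize(t)

    diff = r - t
    mse = float(np.mean(diff**2))
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(mse))
    psnr = _PSNR_CAP if mse == 0 else min(_PSNR_CAP, float(10 * np.log10(1.0 / mse)))
    if r.ndim == 3:
        ms = float(np.mean([ms_ssim_2d(r[i], t[i]) for i in range(r.shape[0])]))
    else:
        ms = ms_ssim_2d(r, t)
    return MetricsReport(mse=mse, mae=mae, rmse=rmse, ms_ssim=ms, psnr=psnr)


def relative_changes(
    conventional: MetricsReport, proposed: MetricsReport
) -> dict[str, float]:
    """Percent improvement of the proposed method over the conventional one.

    Error metrics report the decrease ``100·(conv − prop)/conv``; similarity
    metrics report the increase ``100·(prop − conv)/conv``.
    """
    conv, prop = conventional.as_dict(), proposed.as_dict()
    out = {}
    for key in ("mse", "mae", "rmse"):
        out[key] = 100.0 * (conv[key] - prop[key]) / conv[key]
    for key in ("ms_ssim", "psnr"):
        out[key] = 100.0 * (prop[key] - conv[key]) / conv[key]
    return out


def compare_methods(
    full: Volume3D | MetricsReport,
    limited: Volume3D | MetricsReport,
    truth: Volume3D | None = None,
) -> ComparisonReport:
    """Compare full-angle and limited-angle reconstructions against truth.

    Accepts either volumes (metrics are computed against ``truth``) or
    precomputed :class:`MetricsReport` objects — the latter allows checking
    published metric tables for arithmetic consistency.
    """
    if isinstance(full, MetricsReport) and isinstance(limited, MetricsReport):
        prop, conv = full, limited
    else:
        if truth is None:
            raise ValidationError("truth volume required when passing volumes")
        prop = volume_metrics(full, truth)
        conv = volume_metrics(limited, truth)
    return ComparisonReport(
        conventional=conv,
        proposed=prop,
        relative_change=relative_changes(conv, prop),
    )


def tracking_report(
    fused: AngleSeries | np.ndarray, truth: np.ndarray
) -> TrackingReport:
    """Angle-tracking error summary: mean/max absolute error and residuals."""
    est = fused.fused if isinstance(fused, AngleSeries) else np.asarray(fused, float)
    truth = np.asarray(truth, dtype=float)
    if len(est) != len(truth):
        raise ValidationError("angle series lengths differ")
    residuals = est - truth
    return TrackingReport(
        mean_error=float(np.mean(np.abs(residuals))),
        max_error=float(np.max(np.abs(residuals))),
        residuals=residuals,
    )
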