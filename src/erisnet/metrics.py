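"""Paired image-quality metrics for denoising evaluation.

Six metrics on 8-bit images (peak value L = 255): MSE, PSNR, SSIM, VIF,
EPI and noise variance (NV), plus dataset-level aggregation into a report
with mean/SD/median/min/max per metric and arm (low-dose input vs network
output, both against the full-dose reference).

Two of the printed formulations admit more than one reading, so both are
implemented and the mode is always recorded:

* **SSIM** — ``global`` evaluates the single-statistic formula over whole
  images; ``windowed`` (default for reports) is the standard sliding
  Gaussian-window SSIM (11x11, sigma 1.5), delegated to scikit-image.
* **EPI** — ``paper`` is the literal quotient of squared gradient
  differences over squared reference gradients, which is 0 for perfect
  edge preservation; ``correlation`` (default for reports) is the
  normalised cross-correlation of gradient magnitudes, 1 for perfect
  preservation, matching the scale on which edge preservation is usually
  reported.

VIF is the pixel-domain multi-scale realisation with Gaussian local
statistics (scales by 2x smoothing/decimation); the wavelet-domain GSM
variant is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.metrics import structural_similarity as _sk_ssim

from .dicom_io import Image8, ImagePair, hu_to_uint8

__all__ = [
    "MetricParams",
    "MetricReport",
    "mse",
    "psnr",
    "ssim",
    "vif",
    "epi",
    "noise_variance",
    "evaluate_dataset",
]

METRIC_NAMES = ("MSE", "PSNR", "SSIM", "VIF", "EPI", "NV")


@dataclass(frozen=True)
class MetricParams:
    """Shared constants.

    ssim_c1/c2 default to (0.01 L)^2 and (0.03 L)^2; vif_noise_var is the
    HVS noise variance of the pixel-domain VIF channel model.
    """

    L: int = 255
    ssim_c1: float | None = None
    ssim_c2: float | None = None
    ssim_mode: str = "windowed"  # or "global"
    epi_mode: str = "correlation"  # or "paper"
    vif_scales: int = 4
    vif_noise_var: float = 2.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if self.vif_scales < 1:
            raise ValueError("vif_scales must be >= 1")
        if self.vif_noise_var <= 0:
            raise ValueError("vif_noise_var must be > 0")
        if self.ssim_c1 is None:
            object.__setattr__(self, "ssim_c1", (0.01 * self.L) ** 2)
        if self.ssim_c2 is None:
            object.__setattr__(self, "ssim_c2", (0.03 * self.L) ** 2)
        if self.ssim_mode not in ("global", "windowed"):
            raise ValueError(f"unknown ssim_mode {self.ssim_mode!r}")
        if self.epi_mode not in ("paper", "correlation"):
            raise ValueError(f"unknown epi_mode {self.epi_mode!r}")


def _as_float(img) -> np.ndarray:
    if isinstance(img, Image8):
        img = img.pixels
    return np.asarray(img, dtype=float)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def mse(a, b) -> float:
    """Mean squared difference (1/mn) * sum (a - b)^2."""
    a, b = _as_float(a), _as_float(b)
    _check_same_shape(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, params: MetricParams = MetricParams()) -> float:
    """10 log10(L^2 / MSE) in dB; identical images give +inf."""
    m = mse(a, b)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(params.L**2 / m)


def ssim(a, b, params: MetricParams = MetricParams()) -> float:
    """Structural similarity.

    ``global`` mode is the single luminance/contrast/structure statistic
    over whole images (population moments); ``windowed`` is mean local
    SSIM over 11x11 Gaussian windows (sigma 1.5).
    """
    x, y = _as_float(a), _as_float(b)
    _check_same_shape(x, y)
    c1, c2 = params.ssim_c1, params.ssim_c2
    if params.ssim_mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - mx) * (y - my)).mean()
        return float(((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2)))
    win = 11
    if min(x.shape) < win:
        raise ValueError(f"windowed SSIM needs images at least {win}x{win}, got {x.shape}")
    return float(
        _sk_ssim(
            x,
            y,
            data_range=float(params.L),
            gaussian_weights=True,
            sigma=1.5,
            win_size=win,
            use_sample_covariance=False,
        )
    )


def _vif_stats(ref: np.ndarray, dist: np.ndarray, sd: float):
    mu1 = ndimage.gaussian_filter(ref, sd)
    mu2 = ndimage.gaussian_filter(dist, sd)
    s1_sq = ndimage.gaussian_filter(ref * ref, sd) - mu1 * mu1
    s2_sq = ndimage.gaussian_filter(dist * dist, sd) - mu2 * mu2
    s12 = ndimage.gaussian_filter(ref * dist, sd) - mu1 * mu2
    return np.maximum(s1_sq, 0.0), np.maximum(s2_sq, 0.0), s12


def vif(ref, dist, params: MetricParams = MetricParams()) -> float:
    """Pixel-domain visual information fidelity.

    Per scale, models the distortion as a local gain g plus additive
    noise, and forms the ratio of mutual information passed through the
    distortion channel to that of the reference channel, both under HVS
    noise ``vif_noise_var``.  Equals 1 when dist == ref; decreases with
    distortion strength.
    """
    x, y = _as_float(ref), _as_float(dist)
    _check_same_shape(x, y)
    if x.var() == 0:
        raise ValueError("VIF undefined for a constant reference image")
    sigma_n = params.vif_noise_var
    eps = 1e-10
    num = den = 0.0
    for scale in range(1, params.vif_scales + 1):
        if scale > 1:
            x = ndimage.gaussian_filter(x, 1.0)[::2, ::2]
            y = ndimage.gaussian_filter(y, 1.0)[::2, ::2]
            if min(x.shape) < 2:
                break
        sd = (2 ** (params.vif_scales - scale + 1) + 1) / 5.0
        s1_sq, s2_sq, s12 = _vif_stats(x, y, sd)
        g = s12 / (s1_sq + eps)
        sv_sq = s2_sq - g * s12
        g = np.where(s1_sq < eps, 0.0, g)
        sv_sq = np.where(s1_sq < eps, s2_sq, sv_sq)
        sv_sq = np.where(g < 0, s2_sq, sv_sq)
        g = np.maximum(g, 0.0)
        sv_sq = np.maximum(sv_sq, eps)
        num += float(np.log10(1.0 + g * g * s1_sq / (sv_sq + sigma_n)).sum())
        den += float(np.log10(1.0 + s1_sq / sigma_n).sum())
    return num / den


def _gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # forward differences with edge replication (last row/col difference 0)
    gx = np.zeros_like(img)
    gy = np.zeros_like(img)
    gx[:, :-1] = img[:, 1:] - img[:, :-1]
    gy[:-1, :] = img[1:, :] - img[:-1, :]
    return gx, gy


def epi(ref, out, params: MetricParams = MetricParams()) -> float:
    """Edge preservation index.

    ``paper`` mode: sum of squared gradient differences over sum of
    squared reference gradients (0 = perfect preservation).
    ``correlation`` mode: normalised cross-correlation of gradient
    magnitudes (1 = perfect preservation).
    """
    x, y = _as_float(ref), _as_float(out)
    _check_same_shape(x, y)
    if min(x.shape) < 2:
        raise ValueError("EPI needs images at least 2x2")
    gx_r, gy_r = _gradients(x)
    gx_o, gy_o = _gradients(y)
    if params.epi_mode == "paper":
        den = float((gx_r**2 + gy_r**2).sum())
        if den == 0.0:
            raise ValueError("EPI undefined for a flat reference (zero gradients)")
        return float(((gx_r - gx_o) ** 2 + (gy_r - gy_o) ** 2).sum()) / den
    g_r = np.hypot(gx_r, gy_r)
    g_o = np.hypot(gx_o, gy_o)
    dr = g_r - g_r.mean()
    do = g_o - g_o.mean()
    den = math.sqrt(float((dr**2).sum()) * float((do**2).sum()))
    if den == 0.0:
        raise ValueError("EPI correlation undefined: a gradient field is constant")
    return float((dr * do).sum()) / den


def noise_variance(img) -> float:
    """Population variance (1/mn) * sum (I - mu)^2 of a single image."""
    x = _as_float(img)
    if x.size == 0:
        raise ValueError("empty image")
    return float(x.var())


# ---------------------------------------------------------------------------
# Dataset-level reporting


@dataclass
class MetricReport:
    """Per-pair metric records plus recomputable aggregates."""

    records: pd.DataFrame  # columns: pair, arm, metric columns
    failures: list[dict] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        """Mean/SD/median/min/max per (metric, arm)."""
        rows = []
        for arm, grp in self.records.groupby("arm", sort=False):
            for metric in METRIC_NAMES:
                vals = grp[metric].dropna()
                vals = vals[np.isfinite(vals)]
                rows.append(
                    {
                        "metric": metric,
                        "arm": arm,
                        "mean": vals.mean(),
                        "sd": vals.std(ddof=1),
                        "median": vals.median(),
                        "min": vals.min(),
                        "max": vals.max(),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _pair_metrics(ref: np.ndarray, img: np.ndarray, params: MetricParams) -> dict:
    return {
        "MSE": mse(ref, img),
        "PSNR": psnr(ref, img, params),
        "SSIM": ssim(ref, img, params),
        "VIF": vif(ref, img, params),
        "EPI": epi(ref, img, params),
        "NV": noise_variance(img),
    }


def evaluate_dataset(
    pairs: list[ImagePair],
    model=None,
    outputs: list[Image8] | None = None,
    params: MetricParams = MetricParams(),
    window: tuple[float, float] | None = None,
) -> MetricReport:
    """Score (LQ vs HQ) and (output vs HQ) over a dataset.

    Outputs come either from ``model`` (run through :func:`~erisnet.model.denoise`)
    or a precomputed list.  A pair failing a metric precondition is recorded
    under ``failures`` with the reason, never silently dropped.
    """
    if not pairs:
        raise ValueError("no pairs to evaluate")
    if (model is None) == (outputs is None):
        raise ValueError("provide exactly one of model or outputs")
    from .dicom_io import SOFT_TISSUE_WINDOW
    from .model import denoise as _denoise

    window = window or SOFT_TISSUE_WINDOW
    rows, failures = [], []
    for i, pair in enumerate(pairs):
        hq8 = hu_to_uint8(pair.hq, window).pixels.astype(float)
        lq8_img = hu_to_uint8(pair.lq, window)
        out8 = outputs[i].pixels.astype(float) if outputs else _denoise(model, lq8_img).pixels.astype(float)
        for arm, img in (("LQ", lq8_img.pixels.astype(float)), ("output", out8)):
            try:
                row = _pair_metrics(hq8, img, params)
            except ValueError as exc:
                failures.append({"pair": i, "arm": arm, "reason": str(exc)})
                row = {m: np.nan for m in METRIC_NAMES}
            rows.append({"pair": i, "arm": arm, **row})
    return MetricReport(records=pd.DataFrame(rows), failures=failures)
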