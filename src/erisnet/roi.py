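"""Circular-ROI noise analysis in Hounsfield units.

ROIs are circles of fixed *physical* radius (default 8 mm) placed at pixel
coordinates; a pixel belongs to the ROI iff its center lies within the
radius.  Statistics are always computed on HU values, never on windowed
8-bit data.  The headline quantity is the percent reduction in the HU
standard deviation between the low-dose input and the denoised output,
100 * (SD_lq - SD_out) / SD_lq.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dicom_io import CTImage, GeometryError

__all__ = ["ROISpec", "ROIStats", "circular_mask", "roi_stats", "sd_reduction_pct", "roi_table"]


@dataclass(frozen=True)
class ROISpec:
    """A named circular region: center in (row, col) pixels, radius in mm."""

    name: str
    center: tuple[float, float]
    radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"{self.name}: radius must be > 0")


@dataclass(frozen=True)
class ROIStats:
    name: str
    n_pixels: int
    mean_hu: float
    sd_hu: float  # sample SD (n - 1 denominator)


def circular_mask(
    center: tuple[float, float],
    radius_mm: float,
    pixel_spacing: tuple[float, float],
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within radius_mm of center.

    Distances are physical: anisotropic spacing turns the circle into an
    ellipse in pixel space.  The circle must lie fully inside the image.
    """
    m, n = shape
    cr, cc = center
    sr, sc = pixel_spacing
    if (
        cr * sr - radius_mm < -sr / 2
        or cc * sc - radius_mm < -sc / 2
        or cr * sr + radius_mm > (m - 0.5) * sr
        or cc * sc + radius_mm > (n - 0.5) * sc
    ):
        raise GeometryError(
            f"ROI (center {center}, radius {radius_mm} mm) exceeds image bounds {shape}"
        )
    rows, cols = np.mgrid[0:m, 0:n]
    d2 = ((rows - cr) * sr) ** 2 + ((cols - cc) * sc) ** 2
    return d2 <= radius_mm**2


def roi_stats(img: CTImage, roi: ROISpec) -> ROIStats:
    """Mean and sample SD of HU inside the ROI."""
    mask = circular_mask(roi.center, roi.radius_mm, img.pixel_spacing, (img.m, img.n))
    vals = img.pixels[mask]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.name!r} covers no pixels")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ROIStats(name=roi.name, n_pixels=int(vals.size), mean_hu=float(vals.mean()), sd_hu=sd)


def sd_reduction_pct(sd_lq: float, sd_out: float) -> float:
    """Percent noise reduction: 100 * (sd_lq - sd_out) / sd_lq."""
    if sd_lq <= 0:
        raise ValueError(f"sd_lq must be > 0, got {sd_lq}")
    return 100.0 * (sd_lq - sd_out) / sd_lq


def roi_table(
    lq: CTImage, out: CTImage, rois: list[ROISpec]
) -> "pd.DataFrame":  # noqa: F821 - imported lazily
    """Organ-level attenuation/noise table: per ROI, mean and SD in both
    arms plus the percent SD reduction."""
    import pandas as pd

    rows = []
    for roi in rois:
        s_lq = roi_stats(lq, roi)
        s_out = roi_stats(out, roi)
        rows.append(
            {
                "organ": roi.name,
                "n_pixels": s_lq.n_pixels,
                "mean_lq": s_lq.mean_hu,
                "sd_lq": s_lq.sd_hu,
                "mean_out": s_out.mean_hu,
                "sd_out": s_out.sd_hu,
                "sd_reduction_pct": sd_reduction_pct(s_lq.sd_hu, s_out.sd_hu),
            }
        )
    return pd.DataFrame(rows)
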