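"""Synthetic paired high/low-dose CT slices.

Real paired acquisitions — a full-dose reference and a reduced-dose rescan
of the same (post-mortem) subject — are rarely shareable, so this module
generates a statistical stand-in: slices with organ-like elliptical regions
at realistic soft-tissue attenuation levels, plus dose-dependent additive
noise.  It emulates the *statistics* downstream stages care about (mean HU
per region, noise SD as a function of dose) and makes no attempt at CT
physics: noise is stationary additive Gaussian in HU with

    sigma(f) = sigma_full / sqrt(f)

for dose fraction f, the quantum-noise heuristic.  Streaks, beam hardening
and metal artifacts are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dicom_io import CTImage, DoseTag, GeometryError, ImagePair

__all__ = [
    "OrganSpec",
    "NoiseModel",
    "DEFAULT_ORGANS",
    "default_organs",
    "make_phantom",
    "simulate_low_dose",
    "make_paired_dataset",
    "organ_centers_px",
]

#: Air background of a CT slice.
BACKGROUND_HU = -1000.0
#: Soft-tissue disk the organs sit in (water-equivalent).
BODY_HU = 0.0


@dataclass(frozen=True)
class OrganSpec:
    """An elliptical organ-like region.

    center is given as (row, col) fractions of the image extent; semi-axes
    in millimetres; rotation in degrees (counter-clockwise in row/col
    space).  ``texture_sd`` is the within-organ HU variation present even at
    full dose (parenchymal texture, not quantum noise).
    """

    name: str
    center_frac: tuple[float, float]
    semi_axes_mm: tuple[float, float]
    mean_hu: float
    rotation_deg: float = 0.0
    texture_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.semi_axes_mm) <= 0:
            raise ValueError(f"{self.name}: semi-axes must be > 0")
        if self.texture_sd < 0:
            raise ValueError(f"{self.name}: texture_sd must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise whose SD scales with the inverse square root
    of the dose fraction.

    ``sigma_full`` is the noise SD in HU at full dose.  The default (13.5 HU)
    puts low-dose ROI noise near 17-26 HU at the typical ~55% dose
    reduction, the regime reported for soft-tissue CT reconstructions.
    """

    sigma_full: float = 13.5

    def __post_init__(self) -> None:
        if self.sigma_full <= 0:
            raise ValueError("sigma_full must be > 0")

    def sigma(self, dose_fraction: float) -> float:
        if not (0.0 < dose_fraction <= 1.0):
            raise ValueError(f"dose fraction must be in (0, 1], got {dose_fraction}")
        return self.sigma_full / math.sqrt(dose_fraction)


def default_organs() -> tuple[OrganSpec, ...]:
    """Five-organ layout with mean attenuations typical of vitreous body,
    brain, liver, spleen and paravertebral muscle."""
    return (
        OrganSpec("vitreous", (0.28, 0.30), (22.0, 22.0), 18.75),
        OrganSpec("brain", (0.28, 0.68), (30.0, 24.0), 45.50, rotation_deg=20.0),
        OrganSpec("liver", (0.66, 0.30), (34.0, 26.0), 59.00, rotation_deg=-15.0),
        OrganSpec("spleen", (0.66, 0.70), (24.0, 20.0), 54.61, rotation_deg=30.0),
        OrganSpec("muscle", (0.49, 0.50), (20.0, 26.0), 52.12, rotation_deg=75.0),
    )


DEFAULT_ORGANS = default_organs()


def _ellipse_mask(
    organ: OrganSpec, shape: tuple[int, int], spacing_mm: tuple[float, float]
) -> np.ndarray:
    m, n = shape
    cr = organ.center_frac[0] * (m - 1)
    cc = organ.center_frac[1] * (n - 1)
    rows, cols = np.mgrid[0:m, 0:n]
    # physical offsets of pixel centers from the ellipse center
    dy = (rows - cr) * spacing_mm[0]
    dx = (cols - cc) * spacing_mm[1]
    th = math.radians(organ.rotation_deg)
    u = dy * math.cos(th) + dx * math.sin(th)
    v = -dy * math.sin(th) + dx * math.cos(th)
    a, b = organ.semi_axes_mm
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def organ_centers_px(
    organs: tuple[OrganSpec, ...], shape: tuple[int, int]
) -> dict[str, tuple[int, int]]:
    """Canonical per-organ ROI centers in pixel coordinates."""
    m, n = shape
    return {
        o.name: (int(round(o.center_frac[0] * (m - 1))), int(round(o.center_frac[1] * (n - 1))))
        for o in organs
    }


def make_phantom(
    size_px: tuple[int, int] = (512, 512),
    spacing_mm: tuple[float, float] | None = None,
    organs: tuple[OrganSpec, ...] | None = None,
    background_hu: float = BACKGROUND_HU,
    body_hu: float | None = BODY_HU,
    patient_id: str = "phantom",
    slice_index: int = 0,
    seed: int | None = 0,
) -> tuple[CTImage, np.ndarray]:
    """Build a noiseless full-dose reference slice and its organ label map.

    A soft-tissue disk (``body_hu``) covering 90% of the smaller image
    extent sits on an air background; organs are painted on top in order,
    the later organ winning on overlap.  Label 0 is background/body; organ
    k (1-based) marks pixels of ``organs[k-1]``.  Per-organ texture is
    zero-mean Gaussian with SD ``texture_sd``, so each organ's expected
    pixel value is exactly its ``mean_hu``.
    """
    if spacing_mm is None:
        # keep a 512 mm field of view at any resolution
        spacing_mm = (512.0 / size_px[0], 512.0 / size_px[1])
    organs = default_organs() if organs is None else tuple(organs)
    if not organs:
        raise ValueError("organs must be non-empty")
    m, n = size_px
    rng = np.random.default_rng(seed)
    img = np.full((m, n), background_hu, dtype=float)

    if body_hu is not None:
        body = OrganSpec(
            "body",
            (0.5, 0.5),
            (0.45 * m * spacing_mm[0], 0.45 * n * spacing_mm[1]),
            body_hu,
        )
        img[_ellipse_mask(body, (m, n), spacing_mm)] = body_hu

    labels = np.zeros((m, n), dtype=np.int32)
    for k, organ in enumerate(organs, start=1):
        mask = _ellipse_mask(organ, (m, n), spacing_mm)
        if not mask.any():
            raise GeometryError(f"organ {organ.name!r} covers no pixels")
        edge = np.zeros((m, n), bool)
        edge[[0, -1], :] = True
        edge[:, [0, -1]] = True
        if (mask & edge).any():
            raise GeometryError(f"organ {organ.name!r} touches the image boundary")
        img[mask] = organ.mean_hu
        if organ.texture_sd > 0:
            img[mask] += rng.normal(0.0, organ.texture_sd, size=int(mask.sum()))
        labels[mask] = k

    ct = CTImage(
        img,
        pixel_spacing=spacing_mm,
        patient_id=patient_id,
        slice_index=slice_index,
        dose_tag=DoseTag.HQ,
    )
    return ct, labels


def simulate_low_dose(
    img: CTImage,
    dose_fraction: float,
    noise: NoiseModel | None = None,
    seed: int | None = 0,
) -> CTImage:
    """Degrade a full-dose slice to a given dose fraction.

    Adds i.i.d. zero-mean Gaussian noise with SD ``noise.sigma(f)`` in HU.
    """
    noise = noise or NoiseModel()
    sigma = noise.sigma(dose_fraction)  # validates the fraction
    rng = np.random.default_rng(seed)
    lq = img.pixels + rng.normal(0.0, sigma, size=img.pixels.shape)
    return img.with_pixels(lq, dose_tag=DoseTag.LQ)


def make_paired_dataset(
    n_patients: int = 23,
    slices_per_patient: int = 10,
    size_px: tuple[int, int] = (512, 512),
    spacing_mm: tuple[float, float] | None = None,
    dose_reduction_range: tuple[float, float] = (0.41, 0.83),
    dose_reductions: list[float] | None = None,
    noise: NoiseModel | None = None,
    organs: tuple[OrganSpec, ...] | None = None,
    seed: int = 0,
) -> list[ImagePair]:
    """Generate a per-patient stack of paired HQ/LQ slices.

    Each patient receives a single dose reduction, drawn uniformly from
    ``dose_reduction_range`` (or taken from an explicit ``dose_reductions``
    list, one entry per patient); the dose fraction is ``1 - reduction``.
    Slices within a patient differ by a small rigid jitter of the organ
    layout and by their noise realisation.  Fully reproducible from
    ``seed``.

    ``spacing_mm`` defaults to a 512 mm field of view divided by the pixel
    grid, so the organ layout keeps its physical size at any resolution.
    """
    if spacing_mm is None:
        spacing_mm = (512.0 / size_px[0], 512.0 / size_px[1])
    if n_patients < 3:
        raise ValueError("need at least 3 patients to honor a train/val/test split")
    if dose_reductions is not None and len(dose_reductions) != n_patients:
        raise ValueError("dose_reductions must have one entry per patient")
    noise = noise or NoiseModel()
    base_organs = default_organs() if organs is None else tuple(organs)
    rng = np.random.default_rng(seed)

    pairs: list[ImagePair] = []
    for p in range(n_patients):
        if dose_reductions is None:
            reduction = rng.uniform(*dose_reduction_range)
        else:
            reduction = dose_reductions[p]
        f = 1.0 - reduction
        pid = f"SYN{p:03d}"
        # per-patient anatomical variation: jitter organ centers and sizes
        jitter = rng.uniform(-0.02, 0.02, size=(len(base_organs), 2))
        scale = rng.uniform(0.9, 1.1, size=len(base_organs))
        organs_p = tuple(
            OrganSpec(
                o.name,
                (o.center_frac[0] + jitter[k, 0], o.center_frac[1] + jitter[k, 1]),
                (o.semi_axes_mm[0] * scale[k], o.semi_axes_mm[1] * scale[k]),
                o.mean_hu,
                rotation_deg=o.rotation_deg,
                texture_sd=o.texture_sd,
            )
            for k, o in enumerate(base_organs)
        )
        for s in range(slices_per_patient):
            hq, _ = make_phantom(
                size_px,
                spacing_mm,
                organs_p,
                patient_id=pid,
                slice_index=s,
                seed=rng.integers(0, 2**31 - 1),
            )
            lq = simulate_low_dose(hq, f, noise, seed=rng.integers(0, 2**31 - 1))
            pairs.append(ImagePair(hq=hq, lq=lq, dose_fraction=f))
    return pairs
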