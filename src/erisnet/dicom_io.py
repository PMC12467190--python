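"""CT slice containers and DICOM input/output.

A :class:`CTImage` carries a 2-D grid of Hounsfield-unit (HU) values plus
the geometry and provenance metadata every downstream stage needs.  The
network itself consumes 8-bit arrays (:class:`Image8`); the HU -> uint8
mapping is an explicit, invertible (up to clipping/quantisation) linear
window whose parameters travel with the 8-bit image, so that ROI noise
analysis always runs in HU, never on display values.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "DoseTag",
    "CTImage",
    "Image8",
    "ImagePair",
    "SOFT_TISSUE_WINDOW",
    "stored_to_hu",
    "hu_to_stored",
    "hu_to_uint8",
    "uint8_to_hu",
    "read_series",
    "write_series",
    "export_png",
]

#: Default display window (center, width) in HU: soft tissue.
SOFT_TISSUE_WINDOW: tuple[float, float] = (40.0, 400.0)


class DoseTag(str, enum.Enum):
    """Which arm of a paired acquisition a slice belongs to."""

    HQ = "HQ"
    LQ = "LQ"
    OUTPUT = "OUTPUT"


class FormatError(ValueError):
    """Malformed input data (non-numeric pixels, missing DICOM tags)."""


class GeometryError(ValueError):
    """Inconsistent image geometry (shape or spacing mismatch)."""


@dataclass(frozen=True)
class CTImage:
    """One CT slice in Hounsfield units.

    Attributes
    ----------
    pixels : (m, n) float array of HU values, all finite.
    pixel_spacing : (row_mm, col_mm), strictly positive.
    patient_id : opaque subject identifier.
    slice_index : position of the slice within its series, >= 0.
    dose_tag : HQ reference, LQ input, or network OUTPUT.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    patient_id: str = "anon"
    slice_index: int = 0
    dose_tag: DoseTag = DoseTag.HQ

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise GeometryError(f"pixels must be a non-empty 2-D grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise FormatError("pixels contain non-finite values")
        if not all(s > 0 for s in self.pixel_spacing):
            raise GeometryError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        if self.slice_index < 0:
            raise ValueError(f"slice_index must be >= 0, got {self.slice_index}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "dose_tag", DoseTag(self.dose_tag))

    @property
    def m(self) -> int:
        return self.pixels.shape[0]

    @property
    def n(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray, dose_tag: DoseTag | None = None) -> "CTImage":
        """Copy of this slice with new pixel data (same geometry/metadata)."""
        return replace(self, pixels=pixels, dose_tag=dose_tag or self.dose_tag)


@dataclass(frozen=True)
class Image8:
    """8-bit image as consumed by the network, plus the HU window used."""

    pixels: np.ndarray
    window: tuple[float, float] = SOFT_TISSUE_WINDOW  # (center_hu, width_hu)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.min() < 0 or px.max() > 255:
            raise ValueError("Image8 pixels must lie in [0, 255]")
        if self.window[1] <= 0:
            raise ValueError(f"window width must be > 0, got {self.window[1]}")
        object.__setattr__(self, "pixels", px.astype(np.uint8))


@dataclass(frozen=True)
class ImagePair:
    """Aligned (HQ reference, LQ input) slices from the same subject/position.

    ``augmented`` marks pairs derived by geometric augmentation; such pairs
    must never enter validation or test sets.
    """

    hq: CTImage
    lq: CTImage
    dose_fraction: float = 1.0
    augmented: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.dose_fraction <= 1.0):
            raise ValueError(f"dose_fraction must be in (0, 1], got {self.dose_fraction}")
        a, b = self.hq, self.lq
        if (a.m, a.n) != (b.m, b.n) or a.pixel_spacing != b.pixel_spacing:
            raise GeometryError("hq and lq geometry differ")
        if a.patient_id != b.patient_id or a.slice_index != b.slice_index:
            raise ValueError("hq and lq must come from the same subject and position")


def stored_to_hu(stored: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Rescale stored integer values to HU: ``hu = stored * slope + intercept``."""
    if slope == 0:
        raise ValueError("rescale slope must be non-zero")
    arr = np.asarray(stored)
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"stored values must be numeric, got dtype {arr.dtype}")
    return arr.astype(float) * slope + intercept


def hu_to_stored(hu: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Inverse rescale, rounded half-up to the nearest stored integer."""
    if slope == 0:
        raise ValueError("rescale slope must be non-zero")
    return np.floor((np.asarray(hu, dtype=float) - intercept) / slope + 0.5).astype(np.int16)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def hu_to_uint8(img: CTImage, window: tuple[float, float] = SOFT_TISSUE_WINDOW) -> Image8:
    """Window an HU slice into an 8-bit image.

    The interval [center - width/2, center + width/2] maps linearly onto
    [0, 255]; values outside are clipped.  Rounding is half-up, so a pixel
    exactly at the window center maps to 128.
    """
    center, width = window
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    lo = center - width / 2.0
    scaled = (img.pixels - lo) / width * 255.0
    out = np.clip(_round_half_up(scaled), 0, 255).astype(np.uint8)
    return Image8(out, window=(float(center), float(width)))


def uint8_to_hu(img8: Image8, like: CTImage, dose_tag: DoseTag = DoseTag.OUTPUT) -> CTImage:
    """Invert the HU window (up to clipping/quantisation) back to an HU slice."""
    center, width = img8.window
    lo = center - width / 2.0
    hu = img8.pixels.astype(float) / 255.0 * width + lo
    return like.with_pixels(hu, dose_tag=dose_tag)


# ---------------------------------------------------------------------------
# DICOM series I/O

_DEFAULT_SLOPE = 1.0
_DEFAULT_INTERCEPT = -1024.0


def _to_dataset(img: CTImage, slope: float, intercept: float) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = img.patient_id
    ds.PatientName = img.patient_id
    ds.SeriesDescription = img.dose_tag.value
    ds.InstanceNumber = img.slice_index + 1  # DICOM instance numbers are 1-based
    ds.SliceLocation = float(img.slice_index)
    ds.Rows, ds.Columns = img.m, img.n
    ds.PixelSpacing = [str(img.pixel_spacing[0]), str(img.pixel_spacing[1])]
    ds.RescaleSlope = str(slope)
    ds.RescaleIntercept = str(intercept)
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = hu_to_stored(img.pixels, slope, intercept).tobytes()
    return ds


def write_series(
    images: Sequence[CTImage],
    path: str | Path,
    slope: float = _DEFAULT_SLOPE,
    intercept: float = _DEFAULT_INTERCEPT,
) -> list[Path]:
    """Write slices as single-frame CT DICOM files under ``path``.

    All slices must share geometry.  A JSON sidecar records per-file
    metadata so datasets are self-describing on disk.
    """
    images = list(images)
    if images:
        geom = (images[0].m, images[0].n, images[0].pixel_spacing)
        for img in images[1:]:
            if (img.m, img.n, img.pixel_spacing) != geom:
                raise GeometryError("all slices in a series must share shape and spacing")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sidecar = []
    for img in images:
        ds = _to_dataset(img, slope, intercept)
        fname = path / f"{img.patient_id}_{img.dose_tag.value}_{img.slice_index:04d}.dcm"
        pydicom.dcmwrite(fname, ds, enforce_file_format=True)
        written.append(fname)
        sidecar.append(
            {
                "file": fname.name,
                "patient_id": img.patient_id,
                "slice_index": img.slice_index,
                "dose_tag": img.dose_tag.value,
            }
        )
    (path / "series.json").write_text(json.dumps(sidecar, indent=1))
    return written


def read_series(path: str | Path) -> list[CTImage]:
    """Read a directory of single-frame CT DICOM files, rescaled to HU.

    Slices are returned ordered by slice position regardless of file-name
    order.  An empty directory yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files = sorted(path.glob("*.dcm"))
    if not files:
        warnings.warn(f"no DICOM files found in {path}", stacklevel=2)
        return []
    images = []
    for f in files:
        ds = pydicom.dcmread(f)
        for tag in ("RescaleSlope", "RescaleIntercept"):
            if tag not in ds:
                raise FormatError(f"{f.name}: missing required DICOM tag {tag}")
        hu = stored_to_hu(ds.pixel_array, float(ds.RescaleSlope), float(ds.RescaleIntercept))
        spacing = tuple(float(s) for s in ds.PixelSpacing) if "PixelSpacing" in ds else (1.0, 1.0)
        tag = DoseTag(ds.SeriesDescription) if ds.get("SeriesDescription") in DoseTag._value2member_map_ else DoseTag.HQ
        images.append(
            CTImage(
                hu,
                pixel_spacing=spacing,  # type: ignore[arg-type]
                patient_id=str(ds.get("PatientID", "anon")),
                slice_index=int(ds.get("InstanceNumber", 1)) - 1,
                dose_tag=tag,
            )
        )
    shapes = {(im.m, im.n, im.pixel_spacing) for im in images}
    if len(shapes) > 1:
        raise GeometryError(f"mixed geometries in series: {sorted(shapes)}")
    images.sort(key=lambda im: (im.patient_id, im.dose_tag.value, im.slice_index))
    return images


def export_png(img8: Image8, path: str | Path) -> None:
    """Dump an 8-bit image to PNG for quick visual inspection."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), img8.pixels)
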