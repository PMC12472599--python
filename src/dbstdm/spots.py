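"""Spot-area estimation and concentration correction for irregular DBS.

A fixed-diameter punch taken from a dried blood spot that does not fully
cover the punch contains less blood than assumed, so the measured
concentration underestimates the true one.  Scanning the card before and
after punching gives the blood area removed by the punch; the correction
factor is

    factor = punch_area / (area_before - area_after)

and the corrected concentration is measured x factor.  Areas are always
in mm^2, converted from pixel counts via the scan's DPI (square pixels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import filters, measure

MM_PER_INCH = 25.4


class ZeroAreaError(ValueError):
    """No dark foreground found in the scan."""


class CalibrationError(ValueError):
    """Missing or invalid resolution metadata."""


class InvalidMeasurementError(ValueError):
    """Before/after areas inconsistent with a real punch."""


class InconsistentScanError(ValueError):
    """Area difference exceeds the punch area beyond tolerance."""


@dataclass(frozen=True)
class AreaMeasurement:
    """Areas of one card's before/after scans and the resulting factor."""

    card_id: str
    area_before_mm2: float
    area_after_mm2: float
    punch_area_mm2: float
    factor: float
    full_coverage: bool


def load_grayscale(path, dpi: int | None = None) -> tuple[np.ndarray, int]:
    """Load a PNG/TIFF scan as 8-bit grayscale, reading DPI from metadata.

    An explicit ``dpi`` overrides the file metadata; if neither is
    available a :class:`CalibrationError` is raised.
    """
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
        meta = im.info.get("dpi")
    if dpi is None:
        if not meta or meta[0] <= 0:
            raise CalibrationError(f"{path}: no DPI metadata and none supplied")
        dpi = int(round(meta[0]))
    return arr, dpi


def estimate_spot_area(
    image: np.ndarray,
    dpi: int,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
) -> float:
    """Estimate the blood area (mm^2) of a grayscale DBS scan.

    Foreground is the largest connected component of pixels darker than
    the threshold (Otsu by default, or a fixed intensity); the area is the
    component's pixel count times (25.4/dpi)^2.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D grayscale raster")
    if dpi <= 0:
        raise CalibrationError("dpi must be positive")
    if threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("fixed threshold requires threshold_value")
        thresh = threshold_value
    elif threshold_method == "otsu":
        if img.min() == img.max():
            raise ZeroAreaError("uniform image: no foreground to segment")
        thresh = filters.threshold_otsu(img)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    fg = img <= thresh  # skimage convention: values above the threshold are background
    if not fg.any():
        raise ZeroAreaError("no pixels at or below threshold")
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    n_px = counts.max()
    return float(n_px) * (MM_PER_INCH / dpi) ** 2


def correction_factor(
    area_before_mm2: float,
    area_after_mm2: float,
    punch_diameter_mm: float = 6.0,
    tolerance: float = 0.05,
) -> float:
    """Punch-coverage correction factor from before/after blood areas.

    factor = pi*(d/2)^2 / (area_before - area_after).  Differences up to
    ``tolerance`` above the nominal punch area are treated as full
    coverage (the punch diameter is only approximate) and clipped to a
    factor of exactly 1; larger differences indicate inconsistent scans.
    """
    if area_after_mm2 < 0 or area_before_mm2 < 0:
        raise InvalidMeasurementError("areas must be non-negative")
    diff = area_before_mm2 - area_after_mm2
    if diff <= 0:
        raise InvalidMeasurementError(
            f"area difference {diff:.3f} mm^2 is not positive; punch removed no blood?"
        )
    punch_area = math.pi * (punch_diameter_mm / 2.0) ** 2
    if diff > punch_area * (1.0 + tolerance):
        raise InconsistentScanError(
            f"area difference {diff:.2f} mm^2 exceeds the {punch_diameter_mm} mm "
            f"punch area {punch_area:.2f} mm^2 beyond {tolerance:.0%} tolerance"
        )
    return max(1.0, punch_area / diff)


def correct_concentration(measured_mgL: float, factor: float) -> float:
    """Rescale a measured concentration by the punch-coverage factor."""
    if measured_mgL < 0:
        raise ValueError("measured concentration must be non-negative")
    if factor < 1.0:
        raise ValueError("correction factor must be >= 1 after clipping")
    return measured_mgL * factor


def measure_card(
    before_path,
    after_path,
    punch_diameter_mm: float = 6.0,
    dpi: int | None = None,
    card_id: str | None = None,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
) -> AreaMeasurement:
    """Measure one card's before/after scans and compute its factor."""
    before, dpi_b = load_grayscale(before_path, dpi)
    after, dpi_a = load_grayscale(after_path, dpi)
    if dpi_b != dpi_a:
        raise CalibrationError("before/after scans have different DPI")
    ab = estimate_spot_area(before, dpi_b, threshold_method, threshold_value)
    aa = estimate_spot_area(after, dpi_a, threshold_method, threshold_value)
    factor = correction_factor(ab, aa, punch_diameter_mm)
    return AreaMeasurement(
        card_id=card_id or Path(before_path).stem,
        area_before_mm2=ab,
        area_after_mm2=aa,
        punch_area_mm2=math.pi * (punch_diameter_mm / 2.0) ** 2,
        factor=factor,
        full_coverage=factor == 1.0,
    )
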