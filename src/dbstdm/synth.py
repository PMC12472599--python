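"""Synthetic data with known ground truth for the DBS pipeline.

Two generators:

* :func:`generate_paired_dataset` draws paired serum / venous-DBS /
  capillary-DBS concentrations from the linear conversion model
  C_dbs = k_true * (C_serum - b_true) with multiplicative lognormal
  measurement noise, hematocrit from a truncated normal on the validated
  selectivity range, and a partial-coverage fraction for the capillary
  spot (measured capillary concentration = true concentration x coverage
  of the punch).
* :func:`generate_spot_image_pair` renders before/after-punch grayscale
  scans of an irregular blood spot whose blood coverage of the punch is a
  requested fraction, with analytic pixel-count ground truth.

All randomness is driven by explicit seeds; there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

MM_PER_INCH = 25.4


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


class GenerationError(RuntimeError):
    """Raised when a requested synthetic object cannot be constructed."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated bridging study.

    Defaults are the study conditions of the clinical dataset this
    pipeline targets: n = 35 paired venous samples, the linear-model
    constants k = 1.17 and b = 1.04 mg/L, a 15% assay CV, hematocrit
    0.40 +/- 0.03 (IBD patients span roughly 0.35-0.46), serum
    concentrations log-uniform on 3-120 mg/L (weeks 0-16 of therapy),
    and 56% of capillary spots fully covering the 6 mm punch.
    """

    n_samples: int = 35
    k_true: float = 1.17
    b_true: float = 1.04
    cv_noise: float = 0.15
    hct_mean: float = 0.40
    hct_sd: float = 0.03
    serum_range: tuple[float, float] = (3.0, 120.0)
    capillary_coverage_range: tuple[float, float] = (0.3, 1.0)
    regular_fraction: float = 0.56
    capillary_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.serum_range
        clo, chi = self.capillary_coverage_range
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be positive")
        if self.k_true <= 0:
            raise ConfigurationError("k_true must be positive")
        if not 0 <= self.cv_noise < 1:
            raise ConfigurationError("cv_noise must lie in [0, 1)")
        if not 0 < self.hct_mean < 1 or self.hct_sd < 0:
            raise ConfigurationError("hct_mean must be in (0,1), hct_sd >= 0")
        if not lo < hi:
            raise ConfigurationError("serum_range must satisfy low < high")
        if self.b_true >= lo:
            raise ConfigurationError("b_true must be below the lower serum bound")
        if not (0 < clo <= chi <= 1):
            raise ConfigurationError("coverage fractions must lie in (0, 1]")
        if not 0 <= self.regular_fraction <= 1:
            raise ConfigurationError("regular_fraction must lie in [0, 1]")


#: study weeks at which samples are drawn; a label only, no kinetics
WEEKS = np.array([0.0, 2.0, 4.0, 8.0, 10.0, 12.0, 16.0])

PAIRED_COLUMNS = [
    "sample_id",
    "week",
    "serum_mgL",
    "dbsv_mgL",
    "dbsc_meas_mgL",
    "coverage",
    "hct",
    "dbsc_true_mgL",
]


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def generate_paired_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Draw a paired serum / venous-DBS / capillary-DBS dataset.

    Serum concentrations are log-uniform on ``serum_range``; the venous
    DBS concentration is k_true * (serum - b_true) times lognormal noise
    with CV ``cv_noise``; the true capillary concentration is venous times
    a truncated N(1, capillary_cv^2) factor; the *measured* capillary
    concentration is the true one times the coverage fraction of the
    punch.  A ``regular_fraction`` subset has coverage exactly 1; the rest
    draw coverage uniformly on ``capillary_coverage_range``.  Hematocrit
    is normal(hct_mean, hct_sd) truncated to (0.2, 0.6).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    lo, hi = config.serum_range
    serum = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    week = rng.choice(WEEKS, size=n)

    dbsv = config.k_true * (serum - config.b_true) * _lognormal_factor(rng, config.cv_noise, n)

    # capillary-venous link: slight proportional error, truncated positive
    cap_factor = np.clip(rng.normal(1.0, config.capillary_cv, size=n), 1e-6, None)
    dbsc_true = dbsv * cap_factor

    coverage = np.ones(n)
    n_regular = int(round(config.regular_fraction * n))
    irregular = rng.permutation(n)[: n - n_regular]
    clo, chi = config.capillary_coverage_range
    coverage[irregular] = rng.uniform(clo, chi, size=irregular.size)
    dbsc_meas = dbsc_true * coverage

    if config.hct_sd == 0:
        hct = np.full(n, config.hct_mean)
    else:
        a = (0.2 - config.hct_mean) / config.hct_sd
        b = (0.6 - config.hct_mean) / config.hct_sd
        hct = stats.truncnorm.rvs(
            a, b, loc=config.hct_mean, scale=config.hct_sd, size=n, random_state=rng
        )

    return pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n)],
            "week": week,
            "serum_mgL": serum,
            "dbsv_mgL": dbsv,
            "dbsc_meas_mgL": dbsc_meas,
            "coverage": coverage,
            "hct": hct,
            "dbsc_true_mgL": dbsc_true,
        }
    )


def write_paired_csv(df: pd.DataFrame, path) -> None:
    """Write a paired dataset to CSV (concentrations in mg/L, 6 decimals)."""
    df.to_csv(path, index=False, float_format="%.6f")


def read_paired_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Spot images


@dataclass(frozen=True)
class SpotImagePair:
    """Before/after-punch grayscale scans of one DBS card position."""

    before: np.ndarray
    after: np.ndarray
    dpi: int
    card_id: str = ""

    def __post_init__(self) -> None:
        if self.before.shape != self.after.shape:
            raise ConfigurationError("before and after rasters must share dimensions")
        if self.dpi <= 0:
            raise ConfigurationError("dpi must be positive")


@dataclass(frozen=True)
class SpotImageResult:
    """A generated image pair plus its analytic ground truth (areas in mm^2)."""

    pair: SpotImagePair
    blood_in_punch_mm2: float
    area_before_mm2: float
    area_after_mm2: float
    punch_area_mm2: float
    achieved_coverage: float
    requested_coverage: float
    true_factor: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_factor", self.punch_area_mm2 / self.blood_in_punch_mm2)


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    r0_px: float,
    irregularity: float,
    rng: np.random.Generator,
    n_harmonics: int = 6,
) -> np.ndarray:
    """Star-shaped blob: r(theta) = r0 * (1 + irregularity * smooth_noise(theta))."""
    yy, xx = np.indices(shape)
    dy = yy - center[0]
    dx = xx - center[1]
    radius = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    if irregularity == 0:
        return radius <= r0_px
    noise = np.zeros_like(theta)
    amps = rng.normal(size=n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    for h, (a, ph) in enumerate(zip(amps, phases), start=2):
        noise += a * np.cos(h * theta + ph)
    peak = np.max(np.abs(noise))
    if peak > 0:
        noise = noise / peak  # normalise so |perturbation| <= irregularity
    return radius <= r0_px * (1.0 + irregularity * noise)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], r_px: float) -> np.ndarray:
    yy, xx = np.indices(shape)
    return np.hypot(yy - center[0], xx - center[1]) <= r_px


def generate_spot_image_pair(
    coverage_fraction: float,
    punch_diameter_mm: float = 6.0,
    dpi: int = 300,
    irregularity: float = 0.15,
    seed: int = 0,
    card_id: str = "",
    coverage_tol: float = 0.02,
    max_retries: int = 8,
) -> SpotImageResult:
    """Render a before/after-punch scan pair at a requested punch coverage.

    The blob is drawn with radius ~1.5x the punch radius and a radially
    perturbed contour; the punch disk is then slid outward from the blob
    centre (bisection on the pixel-counted overlap) until the blood
    fraction inside the punch matches ``coverage_fraction`` within
    ``coverage_tol``.  The after image is the before image with the punch
    disk removed (set to background).  Ground-truth areas are exact pixel
    counts, so area(before) - area(after) equals the blood-in-punch area
    by construction.
    """
    if not 0 < coverage_fraction <= 1:
        raise ConfigurationError("coverage_fraction must lie in (0, 1]")
    if dpi < 150:
        raise ConfigurationError("dpi must be >= 150 for reliable area estimates")
    if irregularity < 0:
        raise ConfigurationError("irregularity must be non-negative")

    px_per_mm = dpi / MM_PER_INCH
    px_area = (MM_PER_INCH / dpi) ** 2
    punch_r_px = (punch_diameter_mm / 2.0) * px_per_mm
    # blob comfortably larger than the punch so full coverage is reachable
    r0_px = 1.5 * punch_r_px / max(1e-9, 1.0 - irregularity) if irregularity < 1 else 3 * punch_r_px
    half = int(math.ceil(r0_px * (1 + irregularity) + 2 * punch_r_px + 4))
    shape = (2 * half + 1, 2 * half + 1)
    center = (float(half), float(half))

    rng = np.random.default_rng(seed)
    punch_px = None
    for _ in range(max_retries):
        blob = _blob_mask(shape, center, r0_px, irregularity, rng)

        def overlap(d: float) -> tuple[float, np.ndarray]:
            disk = _disk_mask(shape, (center[0], center[1] + d), punch_r_px)
            n_disk = disk.sum()
            return (blob & disk).sum() / n_disk, disk

        d_lo, d_hi = 0.0, r0_px * (1 + irregularity) + punch_r_px + 1
        f_lo, disk_lo = overlap(d_lo)
        if f_lo < coverage_fraction - coverage_tol:
            continue  # blob dips into the centred punch too much; redraw
        best_d, best_f, best_disk = d_lo, f_lo, disk_lo
        for _ in range(40):
            mid = 0.5 * (d_lo + d_hi)
            f_mid, disk_mid = overlap(mid)
            if abs(f_mid - coverage_fraction) < abs(best_f - coverage_fraction):
                best_d, best_f, best_disk = mid, f_mid, disk_mid
            if f_mid > coverage_fraction:
                d_lo = mid
            else:
                d_hi = mid
        if abs(best_f - coverage_fraction) <= coverage_tol:
            punch_px = best_disk
            achieved = best_f
            break
    if punch_px is None:
        raise GenerationError(
            f"could not reach coverage {coverage_fraction:.3f} with irregularity "
            f"{irregularity} after {max_retries} blob draws"
        )

    before = np.full(shape, 245, dtype=np.uint8)
    before[blob] = 40
    after = before.copy()
    after[punch_px] = 245  # punched-out disk scans as background

    blood_in_punch = float((blob & punch_px).sum()) * px_area
    area_before = float(blob.sum()) * px_area
    area_after = float((blob & ~punch_px).sum()) * px_area
    return SpotImageResult(
        pair=SpotImagePair(before=before, after=after, dpi=dpi, card_id=card_id),
        blood_in_punch_mm2=blood_in_punch,
        area_before_mm2=area_before,
        area_after_mm2=area_after,
        punch_area_mm2=float(punch_px.sum()) * px_area,
        achieved_coverage=achieved,
        requested_coverage=coverage_fraction,
    )


def write_spot_png(image: np.ndarray, dpi: int, path) -> None:
    """Save an 8-bit grayscale scan as PNG with DPI metadata."""
    Image.fromarray(image, mode="L").save(path, dpi=(dpi, dpi))
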