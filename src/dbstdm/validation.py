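"""Bioanalytical validation metrics for a DBS immunoassay.

Calibration linearity with back-calculated deviations, intra/inter-day
accuracy and precision at QC levels, extraction recovery, hematocrit
effect, storage stability, dilution integrity, and a selectivity ANOVA
across hematocrit levels — the computations behind an IATDMCT-style
validation of a dried-blood-spot method.

Acceptance limits follow the usual guideline thresholds: back-calculated
calibrator deviation and QC accuracy/precision within 15% (20% at the
LLOQ), hematocrit-effect ratio within 85-115% of the concentration at the
reference hematocrit 0.4, stability deviation within 15%, dilution
accuracy within 15%.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats


class ValidationError(ValueError):
    """Raised for degenerate validation inputs."""


QC_NOMINALS = {"LLOQ": 3.0, "QC_L": 5.0, "QC_M": 8.0, "QC_H": 10.0}


@dataclass
class QCRun:
    """Replicate measurements at one nominal concentration and condition."""

    level: str
    nominal_mgL: float
    replicate_values_mgL: list[float]
    day: int = 0
    hct: float = 0.4
    condition: str = "fresh"
    time_days: float = 0.0

    def __post_init__(self) -> None:
        if self.nominal_mgL <= 0:
            raise ValidationError("nominal concentration must be positive")
        if len(self.replicate_values_mgL) < 1:
            raise ValidationError("a QC run needs at least one replicate")


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float
    intercept: float
    r2: float
    range_mgL: tuple[float, float]
    back_calc_devs_pct: dict[float, float]
    dev_flags: dict[float, bool]


def fit_calibration(
    nominal, response, lloq_tolerance_pct: float = 20.0, tolerance_pct: float = 15.0
) -> CalibrationCurve:
    """Least-squares calibration line of response on nominal concentration.

    Back-calculates each calibrator as (response - intercept)/slope and
    flags per-calibrator percent deviation against 15% (20% at the lowest
    level, taken as the LLOQ).
    """
    nominal = np.asarray(nominal, dtype=float)
    response = np.asarray(response, dtype=float)
    if nominal.shape != response.shape or nominal.ndim != 1:
        raise ValidationError("nominal and response must be paired 1-D arrays")
    levels = np.unique(nominal)
    if levels.size < 3:
        raise ValidationError("calibration needs >= 3 distinct nominal levels")
    res = stats.linregress(nominal, response)
    if res.slope == 0:
        raise ValidationError("zero calibration slope: curve unusable")
    back = (response - res.intercept) / res.slope
    dev = 100.0 * (back - nominal) / nominal
    lloq = levels.min()
    devs: dict[float, float] = {}
    flags: dict[float, bool] = {}
    for lv in levels:
        d = float(np.mean(dev[nominal == lv]))
        lim = lloq_tolerance_pct if lv == lloq else tolerance_pct
        devs[float(lv)] = d
        flags[float(lv)] = abs(d) <= lim
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        range_mgL=(float(levels.min()), float(levels.max())),
        back_calc_devs_pct=devs,
        dev_flags=flags,
    )


def accuracy_pct(measured_mean: float, nominal: float) -> float:
    """Accuracy as percent of nominal: 100 * measured / nominal."""
    if nominal <= 0:
        raise ValidationError("nominal must be positive")
    return 100.0 * measured_mean / nominal


def precision_rsd(values) -> float:
    """Relative standard deviation in percent (n-1 sd over mean)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("RSD needs >= 2 replicates")
    m = v.mean()
    if m <= 0:
        raise ValidationError("mean must be positive for RSD")
    return float(100.0 * v.std(ddof=1) / m)


def recovery_pct(pre_extraction_responses, post_extraction_responses) -> tuple[float, float]:
    """Extraction recovery: 100 * mean(pre) / mean(post), with propagated sd.

    The sd of the ratio combines the standard errors of the two means by
    first-order (delta-method) propagation.
    """
    pre = np.asarray(pre_extraction_responses, dtype=float)
    post = np.asarray(post_extraction_responses, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValidationError("recovery needs non-empty response sets")
    mpost = post.mean()
    if mpost <= 0:
        raise ValidationError("post-extraction mean must be positive")
    mpre = pre.mean()
    ratio = mpre / mpost
    se_pre = pre.std(ddof=1) / np.sqrt(pre.size) if pre.size > 1 else 0.0
    se_post = post.std(ddof=1) / np.sqrt(post.size) if post.size > 1 else 0.0
    rel = np.sqrt((se_pre / mpre) ** 2 + (se_post / mpost) ** 2) if mpre > 0 else 0.0
    return float(100.0 * ratio), float(100.0 * ratio * rel)


def hct_effect(
    concentrations_by_hct: dict[float, "np.typing.ArrayLike"],
    reference_hct: float = 0.4,
    tolerance_pct: float = 15.0,
) -> dict[float, tuple[float, bool]]:
    """Hematocrit-effect ratios against the reference hematocrit.

    For each HCT level, ratio = 100 * mean(C at HCT) / mean(C at
    reference); pass iff the ratio lies within 100 +/- tolerance.
    """
    if reference_hct not in concentrations_by_hct:
        raise ValidationError(f"reference HCT level {reference_hct} missing")
    ref_mean = float(np.mean(concentrations_by_hct[reference_hct]))
    if ref_mean <= 0:
        raise ValidationError("reference-level mean must be positive")
    out: dict[float, tuple[float, bool]] = {}
    for h, vals in concentrations_by_hct.items():
        ratio = 100.0 * float(np.mean(vals)) / ref_mean
        out[h] = (ratio, 100.0 - tolerance_pct <= ratio <= 100.0 + tolerance_pct)
    return out


def stability_deviation(stored_values, fresh_values, tolerance_pct: float = 15.0) -> tuple[float, bool]:
    """Storage-stability deviation: 100 * (mean(stored) - mean(fresh)) / mean(fresh)."""
    stored = np.asarray(stored_values, dtype=float)
    fresh = np.asarray(fresh_values, dtype=float)
    if stored.size == 0 or fresh.size == 0:
        raise ValidationError("stability needs non-empty value sets")
    mf = fresh.mean()
    if mf == 0:
        raise ValidationError("fresh mean must be non-zero")
    dev = float(100.0 * (stored.mean() - mf) / mf)
    return dev, abs(dev) <= tolerance_pct


def dilution_integrity(
    nominal: float, diluted_measured, dilution_factor: int, tolerance_pct: float = 15.0
) -> tuple[float, float, bool]:
    """Accuracy and precision of above-range samples measured after dilution.

    Back-calculated concentration = measured * factor; accuracy is percent
    of nominal; pass iff |accuracy - 100| < tolerance.
    """
    if dilution_factor < 1:
        raise ValidationError("dilution factor must be >= 1")
    if nominal <= 0:
        raise ValidationError("nominal must be positive")
    meas = np.asarray(diluted_measured, dtype=float)
    if meas.size == 0:
        raise ValidationError("no diluted measurements supplied")
    back = meas * dilution_factor
    acc = accuracy_pct(float(back.mean()), nominal)
    rsd = precision_rsd(back) if back.size > 1 else 0.0
    return acc, rsd, abs(acc - 100.0) < tolerance_pct


def selectivity_anova(
    blank_responses_by_group: dict,
) -> tuple[float, float, dict[tuple, float]]:
    """One-way ANOVA across groups with Bonferroni-adjusted pairwise t tests.

    Returns (F, p, {(group_a, group_b): adjusted p}); adjusted
    p = min(1, m * p_raw) with m the number of pairwise comparisons.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in blank_responses_by_group.items()}
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValidationError(f"group {k!r} has fewer than 2 observations")
    arrays = list(groups.values())
    means = [a.mean() for a in arrays]
    if np.ptp(means) == 0:  # zero between-group variance, incl. identical groups
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
    keys = list(groups)
    pairs = list(combinations(keys, 2))
    m = len(pairs)
    pairwise: dict[tuple, float] = {}
    for a, b in pairs:
        if np.array_equal(groups[a], groups[b]):
            pairwise[(a, b)] = 1.0
            continue
        _, pr = stats.ttest_ind(groups[a], groups[b])
        pairwise[(a, b)] = min(1.0, m * float(pr)) if np.isfinite(pr) else 1.0
    return float(f_stat), float(p), pairwise


def validation_report(runs: list[QCRun], calibrators=None) -> dict:
    """Per-level intra-day and pooled inter-day accuracy and precision.

    Intra-day statistics are computed within each day; inter-day pools all
    replicates across days.  Acceptance: RSD and |accuracy - 100| within
    20% at the LLOQ level, 15% otherwise.  Levels absent from ``runs`` are
    reported as missing rather than raising.
    """
    if not runs:
        raise ValidationError("at least one QC run is required")
    report: dict = {"levels": {}}
    levels = sorted({r.level for r in runs}, key=lambda lv: QC_NOMINALS.get(lv, 1e9))
    for lv in levels:
        lv_runs = [r for r in runs if r.level == lv]
        nominal = lv_runs[0].nominal_mgL
        limit = 20.0 if lv == "LLOQ" else 15.0
        intra = {}
        for r in sorted(lv_runs, key=lambda r: r.day):
            vals = np.asarray(r.replicate_values_mgL, dtype=float)
            acc = accuracy_pct(float(vals.mean()), nominal)
            rsd = precision_rsd(vals) if vals.size > 1 else 0.0
            intra[r.day] = {
                "n": int(vals.size),
                "mean_mgL": float(vals.mean()),
                "accuracy_pct": acc,
                "rsd_pct": rsd,
                "pass": abs(acc - 100.0) <= limit and rsd <= limit,
            }
        pooled = np.concatenate([np.asarray(r.replicate_values_mgL, float) for r in lv_runs])
        acc = accuracy_pct(float(pooled.mean()), nominal)
        rsd = precision_rsd(pooled) if pooled.size > 1 else 0.0
        report["levels"][lv] = {
            "nominal_mgL": nominal,
            "intra_day": intra,
            "inter_day": {
                "n": int(pooled.size),
                "mean_mgL": float(pooled.mean()),
                "accuracy_pct": acc,
                "rsd_pct": rsd,
                "pass": abs(acc - 100.0) <= limit and rsd <= limit,
            },
        }
    for lv in QC_NOMINALS:
        if lv not in report["levels"]:
            report["levels"][lv] = "missing"
    if calibrators is not None:
        nominal, response = calibrators
        cal = fit_calibration(nominal, response)
        report["calibration"] = {
            "slope": cal.slope,
            "intercept": cal.intercept,
            "r2": cal.r2,
            "range_mgL": list(cal.range_mgL),
            "back_calc_devs_pct": {str(k): v for k, v in cal.back_calc_devs_pct.items()},
            "all_within_limits": all(cal.dev_flags.values()),
        }
    return report
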