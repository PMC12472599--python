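"""Method-agreement and predictive-performance statistics.

Deming (errors-in-both-variables) regression, Bland-Altman bias and limits
of agreement, the EMA cross-validation criterion (>= 67% of pairs within
+/-20% of the pair mean), and MPPE/MAPE predictive percent errors.

Conventions, stated once and echoed in every report:

* Bland-Altman differences are ``first argument minus second``.
* In :func:`evaluate_model` the difference is predicted minus measured
  serum, and the Deming fit regresses predicted (y) on measured (x); an
  overpredicting model therefore shows positive bias and slope > 1.
* Limits of agreement use the multiplier 1.96 exactly; the confidence
  interval of the bias uses the t distribution (the pair counts in DBS
  bridging studies are small, typically 25-35).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from dbstdm.conversion import ConversionFit, predict_serum

logger = logging.getLogger(__name__)


class AgreementError(ValueError):
    """Raised for degenerate inputs to agreement statistics."""


# ---------------------------------------------------------------------------
# Deming regression


def _deming_point(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, float]:
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    syy = float(np.sum((y - ybar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    if sxy == 0.0:
        raise AgreementError("S_xy = 0: Deming slope is undefined for uncorrelated data")
    disc = syy - lam * sxx
    slope = (disc + np.sqrt(disc * disc + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    return slope, ybar - slope * xbar


@dataclass(frozen=True)
class DemingResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    lambda_ratio: float
    n: int


def deming_regression(x, y, lambda_ratio: float = 1.0) -> DemingResult:
    """Deming regression of y on x with error-variance ratio ``lambda_ratio``.

    ``lambda_ratio`` is var(error in y) / var(error in x); the default 1
    is orthogonal regression.  The slope is the closed-form minimiser of
    the lambda-scaled orthogonal squared distances,

        slope = [S_yy - lam*S_xx + sqrt((S_yy - lam*S_xx)^2 + 4*lam*S_xy^2)]
                / (2*S_xy)

    with centered sums of squares and products, and
    intercept = ybar - slope * xbar.  95% confidence intervals are
    leave-one-out jackknife with a t quantile on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgreementError("x and y must be paired 1-D arrays")
    n = x.size
    if n < 3:
        raise AgreementError(f"Deming regression needs n >= 3, got {n}")
    if lambda_ratio <= 0:
        raise AgreementError("lambda_ratio must be positive")
    if np.var(x) == 0:
        raise AgreementError("x has zero variance")

    slope, intercept = _deming_point(x, y, lambda_ratio)

    idx = np.arange(n)
    jack = np.empty((n, 2))
    for i in range(n):
        keep = idx != i
        jack[i] = _deming_point(x[keep], y[keep], lambda_ratio)
    # jackknife SE; df = n - 2 (two fitted parameters)
    se = np.sqrt((n - 1) / n * np.sum((jack - jack.mean(axis=0)) ** 2, axis=0))
    tq = stats.t.ppf(0.975, n - 2)
    return DemingResult(
        slope=slope,
        intercept=intercept,
        slope_ci=(slope - tq * se[0], slope + tq * se[0]),
        intercept_ci=(intercept - tq * se[1], intercept + tq * se[1]),
        lambda_ratio=lambda_ratio,
        n=n,
    )


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa: tuple[float, float]
    bias_ci: tuple[float, float]
    n: int
    loa_multiplier: float = 1.96


def bland_altman(a, b, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman agreement of paired series; differences are a - b.

    bias = mean(d); LoA = bias +/- 1.96 * sd(d) with the n-1 sample
    standard deviation; the 95% CI of the bias is
    bias +/- t_{0.975, n-1} * sd(d)/sqrt(n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AgreementError("a and b must be paired 1-D arrays")
    n = a.size
    if n < 2:
        raise AgreementError(f"Bland-Altman needs n >= 2, got {n}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = loa_multiplier * sd
    tq = stats.t.ppf(0.975, n - 1)
    ci = tq * sd / np.sqrt(n)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa=(bias - half, bias + half),
        bias_ci=(bias - ci, bias + ci),
        n=n,
        loa_multiplier=loa_multiplier,
    )


# ---------------------------------------------------------------------------
# EMA +/-20% criterion and predictive errors


def ema_within_20(
    a, b, band: float = 0.20, pass_fraction: float = 0.67
) -> tuple[float, bool]:
    """Fraction of pairs whose difference is within ``band`` of the pair mean.

    Pair i counts as within iff |a_i - b_i| <= band * (a_i + b_i)/2.
    Pairs with non-positive mean are excluded (with a logged count).
    Returns (fraction, fraction >= pass_fraction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise AgreementError("a and b must be paired, non-empty 1-D arrays")
    mean = (a + b) / 2.0
    valid = mean > 0
    n_excluded = int(np.sum(~valid))
    if n_excluded:
        logger.info("ema_within_20: excluded %d pairs with non-positive mean", n_excluded)
    if not np.any(valid):
        raise AgreementError("no pairs with positive mean")
    within = np.abs(a[valid] - b[valid]) <= band * mean[valid]
    frac = float(within.mean())
    return frac, frac >= pass_fraction


def predictive_errors(predicted, observed, center: str = "mean") -> tuple[float, float]:
    """MPPE and MAPE in percent.

    pe_i = 100 * (pred_i - obs_i) / obs_i; MPPE = center(pe),
    MAPE = center(|pe|), where ``center`` is ``"mean"`` or ``"median"``.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 1:
        raise AgreementError("predicted and observed must be paired, non-empty 1-D arrays")
    if np.any(obs <= 0):
        raise AgreementError("observed values must be positive for percent errors")
    if center not in ("mean", "median"):
        raise AgreementError(f"center must be 'mean' or 'median', got {center!r}")
    fn = np.mean if center == "mean" else np.median
    pe = 100.0 * (pred - obs) / obs
    return float(fn(pe)), float(fn(np.abs(pe)))


# ---------------------------------------------------------------------------
# One-stop model evaluation


@dataclass(frozen=True)
class AgreementReport:
    """Agreement and predictive performance of one conversion model."""

    model_id: str
    deming_slope: float
    deming_slope_ci: tuple[float, float]
    deming_intercept: float
    deming_intercept_ci: tuple[float, float]
    ba_bias: float
    ba_bias_ci: tuple[float, float]
    ba_loa: tuple[float, float]
    ema_fraction: float
    ema_pass: bool
    mppe_pct: float
    mape_pct: float
    n: int
    direction: str = field(default="predicted - measured")

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "direction": self.direction,
            "deming_slope": self.deming_slope,
            "deming_slope_ci": list(self.deming_slope_ci),
            "deming_intercept": self.deming_intercept,
            "deming_intercept_ci": list(self.deming_intercept_ci),
            "ba_bias": self.ba_bias,
            "ba_bias_ci": list(self.ba_bias_ci),
            "ba_loa": list(self.ba_loa),
            "ema_fraction": self.ema_fraction,
            "ema_pass": self.ema_pass,
            "mppe_pct": self.mppe_pct,
            "mape_pct": self.mape_pct,
            "n": self.n,
        }


def evaluate_model(
    serum,
    dbs_venous,
    model: ConversionFit,
    hct=None,
    lambda_ratio: float = 1.0,
    ema_band: float = 0.20,
    ema_pass_fraction: float = 0.67,
    mppe_center: str = "mean",
    loa_multiplier: float = 1.96,
) -> AgreementReport:
    """Evaluate one conversion model against measured serum concentrations.

    Predicts serum from the venous DBS concentrations, then reports Deming
    regression (predicted on measured), Bland-Altman (predicted minus
    measured), the EMA within-band fraction, and MPPE/MAPE.
    """
    serum = np.asarray(serum, dtype=float)
    predicted = predict_serum(model, dbs_venous, hct=hct)
    dem = deming_regression(serum, predicted, lambda_ratio=lambda_ratio)
    ba = bland_altman(predicted, serum, loa_multiplier=loa_multiplier)
    frac, ok = ema_within_20(predicted, serum, band=ema_band, pass_fraction=ema_pass_fraction)
    mppe, mape = predictive_errors(predicted, serum, center=mppe_center)
    return AgreementReport(
        model_id=model.model_id,
        deming_slope=dem.slope,
        deming_slope_ci=dem.slope_ci,
        deming_intercept=dem.intercept,
        deming_intercept_ci=dem.intercept_ci,
        ba_bias=ba.bias,
        ba_bias_ci=ba.bias_ci,
        ba_loa=ba.loa,
        ema_fraction=frac,
        ema_pass=ok,
        mppe_pct=mppe,
        mape_pct=mape,
        n=serum.size,
    )
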