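"""DBS-to-serum concentration conversion models.

Three models relate the drug concentration measured in a venous dried
blood spot (C_dbs, mg/L) to the serum concentration (C_s, mg/L):

* proportional:  C_s = C_dbs / k
* linear:        C_s = C_dbs / k + b
* hct:           C_s = C_dbs / (1 - HCT)   (no free parameters)

k is reported as the DBS-to-serum divisor (the convention used in
method-comparison tables for this assay), so the ordinary least-squares
slope of serum on DBS is 1/k.  The hct model is the textbook
plasma-restriction prediction for a drug excluded from erythrocytes; it
carries no fitted parameters and is prediction-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class FitError(ValueError):
    """Raised when a conversion-model fit is infeasible or degenerate."""


@dataclass(frozen=True)
class ConversionFit:
    """Fitted parameters of a serum-prediction model.

    Parameters
    ----------
    model_id
        One of ``"proportional"``, ``"linear"``, ``"hct"``.
    k
        DBS-to-serum divisor (dimensionless, > 0); ``None`` for the hct
        model, which has no parameters.
    b
        Intercept in mg/L; 0 for the proportional model, ``None`` for hct.
    sse
        Residual sum of squares on the concentration scale (mg/L)^2.
    n
        Number of pairs used in the fit (after exclusions).
    """

    model_id: str
    k: float | None
    b: float | None
    sse: float
    n: int

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "k": self.k,
            "b": self.b,
            "sse": self.sse,
            "n": self.n,
        }


def _clean_pairs(dbs, serum) -> tuple[np.ndarray, np.ndarray]:
    dbs = np.asarray(dbs, dtype=float)
    serum = np.asarray(serum, dtype=float)
    if dbs.shape != serum.shape or dbs.ndim != 1:
        raise FitError("dbs and serum must be 1-D arrays of equal length")
    keep = (dbs > 0) & (serum > 0) & np.isfinite(dbs) & np.isfinite(serum)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropped %d pairs with non-positive or non-finite concentrations", n_dropped)
    return dbs[keep], serum[keep]


def fit_proportional(dbs, serum) -> ConversionFit:
    """Fit C_s = C_dbs / k by unweighted least squares.

    Minimising sum_i (serum_i - dbs_i/k)^2 over k is through-origin OLS of
    serum on dbs in the slope 1/k, so the closed form is
    k = sum(dbs^2) / sum(dbs * serum).
    """
    dbs, serum = _clean_pairs(dbs, serum)
    if dbs.size < 2:
        raise FitError(f"proportional fit needs >= 2 positive pairs, got {dbs.size}")
    denom = float(np.dot(dbs, serum))
    if denom <= 0:
        raise FitError("sum(dbs * serum) must be positive")
    k = float(np.dot(dbs, dbs)) / denom
    resid = serum - dbs / k
    return ConversionFit("proportional", k=k, b=0.0, sse=float(resid @ resid), n=dbs.size)


def fit_linear(dbs, serum) -> ConversionFit:
    """Fit C_s = C_dbs / k + b by unweighted least squares.

    Equivalent to OLS of serum on dbs with slope 1/k and intercept b.
    """
    dbs, serum = _clean_pairs(dbs, serum)
    if dbs.size < 3:
        raise FitError(f"linear fit needs >= 3 positive pairs, got {dbs.size}")
    sxx = float(np.var(dbs))
    if sxx == 0:
        raise FitError("dbs values are constant; slope is unidentifiable")
    slope = float(np.cov(dbs, serum, ddof=0)[0, 1]) / sxx
    if slope <= 0:
        raise FitError("fitted slope is non-positive; k would not be a positive divisor")
    b = float(np.mean(serum) - slope * np.mean(dbs))
    k = 1.0 / slope
    resid = serum - dbs / k - b
    return ConversionFit("linear", k=k, b=b, sse=float(resid @ resid), n=dbs.size)


def hct_model() -> ConversionFit:
    """The parameter-free hematocrit model C_s = C_dbs / (1 - HCT)."""
    return ConversionFit("hct", k=None, b=None, sse=0.0, n=0)


def predict_serum(model: ConversionFit, dbs_venous, hct=None) -> np.ndarray:
    """Predict serum concentration (mg/L) from a venous DBS concentration.

    ``hct`` is required (elementwise, in (0, 1)) iff ``model.model_id`` is
    ``"hct"`` and ignored otherwise.
    """
    dbs = np.asarray(dbs_venous, dtype=float)
    if model.model_id == "proportional":
        return dbs / model.k
    if model.model_id == "linear":
        return dbs / model.k + model.b
    if model.model_id == "hct":
        if hct is None:
            raise ValueError("hct model requires a hematocrit value per sample")
        hct = np.asarray(hct, dtype=float)
        if np.any(hct <= 0) or np.any(hct >= 1):
            raise ValueError("hematocrit must lie strictly in (0, 1)")
        return dbs / (1.0 - hct)
    raise ValueError(f"unknown model_id {model.model_id!r}")
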