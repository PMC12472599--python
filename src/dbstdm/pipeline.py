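"""End-to-end pipeline: formats, configuration, and stage chaining.

Order of stages mirrors the clinical workflow: correct irregular
capillary spots from scans, fit the DBS-to-serum conversion models on
venous/serum pairs, evaluate all three models, then compare venous and
(corrected) capillary DBS concentrations.

All concentrations are serialized in mg/L; every written report echoes
the configuration it was produced with, and reruns with the same inputs
and config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dbstdm import agreement, conversion, spots, validation

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["sample_id", "week", "serum_mgL", "dbsv_mgL", "dbsc_meas_mgL", "coverage", "hct"]

QC_CSV_COLUMNS = ["level", "nominal_mgL", "value_mgL", "day", "hct", "condition", "time_days"]


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable constants of the analysis, with guideline defaults."""

    punch_diameter_mm: float = 6.0
    deming_lambda: float = 1.0
    ema_band: float = 0.20
    ema_pass_fraction: float = 0.67
    mppe_center: str = "mean"
    loa_multiplier: float = 1.96
    lloq_mgL: float = 3.0
    include_below_lloq: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ema_band < 1 or not 0 < self.ema_pass_fraction < 1:
            raise SchemaError("ema_band and ema_pass_fraction must lie in (0, 1)")
        if self.loa_multiplier <= 0 or self.punch_diameter_mm <= 0 or self.deming_lambda <= 0:
            raise SchemaError("multipliers and punch diameter must be positive")
        if self.mppe_center not in ("mean", "median"):
            raise SchemaError("mppe_center must be 'mean' or 'median'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def load_paired_csv(path) -> pd.DataFrame:
    """Read and validate a paired-measurements CSV.

    Required columns: sample_id, week, serum_mgL, dbsv_mgL, dbsc_meas_mgL,
    coverage, hct.  Rows with missing or out-of-range values are reported
    by row number in the raised :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    numeric = ["week", "serum_mgL", "dbsv_mgL", "dbsc_meas_mgL", "coverage", "hct"]
    bad_rows: list[int] = []
    for i, row in df.iterrows():
        vals = row[numeric]
        if vals.isna().any() or not np.isfinite(vals.to_numpy(dtype=float)).all():
            bad_rows.append(int(i))
            continue
        if row["serum_mgL"] < 0 or row["dbsv_mgL"] < 0 or row["dbsc_meas_mgL"] < 0:
            bad_rows.append(int(i))
        elif not (0 < row["coverage"] <= 1) or not (0 < row["hct"] < 1):
            bad_rows.append(int(i))
    if bad_rows:
        raise SchemaError(f"{path}: invalid values in rows {bad_rows}")
    return df


def read_qc_csv(path) -> list[validation.QCRun]:
    """Read QC replicate rows and group them into :class:`QCRun` objects."""
    df = pd.read_csv(path)
    missing = [c for c in QC_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    runs = []
    keys = ["level", "nominal_mgL", "day", "hct", "condition", "time_days"]
    for vals, grp in df.groupby(keys, sort=True):
        rec = dict(zip(keys, vals))
        runs.append(
            validation.QCRun(
                level=str(rec["level"]),
                nominal_mgL=float(rec["nominal_mgL"]),
                replicate_values_mgL=grp["value_mgL"].astype(float).tolist(),
                day=int(rec["day"]),
                hct=float(rec["hct"]),
                condition=str(rec["condition"]),
                time_days=float(rec["time_days"]),
            )
        )
    return runs


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_json(data: dict, path) -> None:
    """Deterministic JSON writer (sorted keys, fixed layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonify(data), fh, indent=2, sort_keys=True)
        fh.write("\n")


def correct_capillary(
    df: pd.DataFrame, config: PipelineConfig, images_dir=None
) -> tuple[pd.DataFrame, list[dict], list[str]]:
    """Apply spot-area correction to irregular capillary samples.

    Samples flagged irregular (coverage < 1) need before/after scans named
    ``<sample_id>_before.png`` / ``<sample_id>_after.png`` in
    ``images_dir``; those without scans are warned about and excluded from
    the capillary comparison (dbsc_corr_mgL = NaN).  Regular samples get
    factor 1.
    """
    corrections: list[dict] = []
    warnings: list[str] = []
    corrected = np.full(len(df), np.nan)
    factors = np.ones(len(df))
    images_dir = Path(images_dir) if images_dir is not None else None
    for pos, (_, row) in enumerate(df.iterrows()):
        sid = str(row["sample_id"])
        if row["coverage"] >= 1.0:
            corrected[pos] = row["dbsc_meas_mgL"]
            corrections.append(
                {
                    "card_id": sid,
                    "area_before_mm2": np.nan,
                    "area_after_mm2": np.nan,
                    "factor": 1.0,
                    "flag_full_coverage": True,
                }
            )
            continue
        before = images_dir / f"{sid}_before.png" if images_dir else None
        if before is None or not before.exists():
            warnings.append(f"{sid}: irregular spot without scans; excluded from capillary comparison")
            continue
        meas = spots.measure_card(
            before,
            images_dir / f"{sid}_after.png",
            punch_diameter_mm=config.punch_diameter_mm,
            card_id=sid,
        )
        factors[pos] = meas.factor
        corrected[pos] = spots.correct_concentration(row["dbsc_meas_mgL"], meas.factor)
        corrections.append(
            {
                "card_id": sid,
                "area_before_mm2": meas.area_before_mm2,
                "area_after_mm2": meas.area_after_mm2,
                "factor": meas.factor,
                "flag_full_coverage": meas.full_coverage,
            }
        )
    out = df.copy()
    out["factor"] = factors
    out["dbsc_corr_mgL"] = corrected
    return out, corrections, warnings


def run_pipeline(
    config: PipelineConfig, paired_csv, images_dir=None, out_dir=None
) -> dict:
    """Run the full analysis on a paired-measurements CSV.

    Returns a report bundle; if ``out_dir`` is given, also writes
    fits.json, agreement_models.json, capillary_agreement.json,
    corrections.csv and run_log.json there.
    """
    df = load_paired_csv(paired_csv)
    n_total = len(df)
    below = (df["serum_mgL"] < config.lloq_mgL) | (df["dbsv_mgL"] < config.lloq_mgL)
    fit_df = df if config.include_below_lloq else df[~below]
    n_below = int(below.sum())
    if n_below:
        logger.info("%d samples below LLOQ %.1f mg/L flagged", n_below, config.lloq_mgL)

    df, corrections, warnings = correct_capillary(df, config, images_dir)

    fits = {
        "proportional": conversion.fit_proportional(fit_df["dbsv_mgL"], fit_df["serum_mgL"]),
        "linear": conversion.fit_linear(fit_df["dbsv_mgL"], fit_df["serum_mgL"]),
        "hct": conversion.hct_model(),
    }

    eval_kwargs = dict(
        lambda_ratio=config.deming_lambda,
        ema_band=config.ema_band,
        ema_pass_fraction=config.ema_pass_fraction,
        mppe_center=config.mppe_center,
        loa_multiplier=config.loa_multiplier,
    )
    reports = {
        name: agreement.evaluate_model(
            fit_df["serum_mgL"],
            fit_df["dbsv_mgL"],
            fit,
            hct=fit_df["hct"] if name == "hct" else None,
            **eval_kwargs,
        )
        for name, fit in fits.items()
    }

    # venous vs capillary, uncorrected and corrected (differences venous - capillary)
    cap = df.dropna(subset=["dbsc_corr_mgL"])
    capillary: dict = {"direction": "venous - capillary", "n": int(len(cap))}
    if len(cap) >= 3:
        for label, col in (("uncorrected", "dbsc_meas_mgL"), ("corrected", "dbsc_corr_mgL")):
            ba = agreement.bland_altman(cap["dbsv_mgL"], cap[col], config.loa_multiplier)
            frac, ok = agreement.ema_within_20(
                cap["dbsv_mgL"], cap[col], config.ema_band, config.ema_pass_fraction
            )
            dem = agreement.deming_regression(cap["dbsv_mgL"], cap[col], config.deming_lambda)
            capillary[label] = {
                "ba_bias": ba.bias,
                "ba_bias_ci": list(ba.bias_ci),
                "ba_loa": list(ba.loa),
                "ema_fraction": frac,
                "ema_pass": ok,
                "deming_slope": dem.slope,
                "deming_slope_ci": list(dem.slope_ci),
                "deming_intercept": dem.intercept,
                "deming_intercept_ci": list(dem.intercept_ci),
            }
    else:
        warnings.append("fewer than 3 capillary samples usable; capillary comparison skipped")

    cfg = config.to_dict()
    bundle = {
        "config": cfg,
        "counts": {
            "n_total": n_total,
            "n_below_lloq": n_below,
            "n_used_in_fits": int(len(fit_df)),
            "n_irregular": int((df["coverage"] < 1).sum()),
            "n_capillary_compared": int(len(cap)),
        },
        "warnings": warnings,
        "fits": {k: v.to_dict() for k, v in fits.items()},
        "model_agreement": {k: v.to_dict() for k, v in reports.items()},
        "capillary_agreement": capillary,
        "corrections": corrections,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json({"config": cfg, "fits": bundle["fits"]}, out / "fits.json")
        write_json(
            {"config": cfg, "model_agreement": bundle["model_agreement"]},
            out / "agreement_models.json",
        )
        write_json(
            {"config": cfg, "capillary_agreement": capillary}, out / "capillary_agreement.json"
        )
        pd.DataFrame(
            corrections,
            columns=["card_id", "area_before_mm2", "area_after_mm2", "factor", "flag_full_coverage"],
        ).to_csv(out / "corrections.csv", index=False, float_format="%.6f")
        write_json({"config": cfg, "counts": bundle["counts"], "warnings": warnings}, out / "run_log.json")
    return bundle
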