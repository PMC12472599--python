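# Methods

`dbstdm` implements the statistical core of a dried-blood-spot (DBS)
therapeutic-drug-monitoring bridging study for a monoclonal antibody
measured by ELISA: validating the assay, converting DBS concentrations to
serum equivalents, and quantifying agreement between sampling routes. All
concentrations are in mg/L, all areas in mm², all fractions dimensionless.

## Conversion models

Three models map the venous-DBS concentration C_dbs to serum C_s:

1. proportional — C_s = C_dbs / k
2. linear — C_s = C_dbs / k + b
3. hematocrit — C_s = C_dbs / (1 − HCT), no free parameters

k is reported as the DBS→serum *divisor* (the convention of the
method-comparison literature for this assay), so the OLS slope of serum
on DBS is 1/k. Both fits minimize unweighted SSE on the concentration
scale; the reparameterization makes them exactly (through-origin) OLS,
with closed forms k = Σd²/Σ(d·s) (proportional) and k = 1/slope,
b = intercept (linear). Pairs with non-positive concentrations are
dropped with a logged count. Whether the error should be minimized on the
log scale instead is genuinely open; the linear scale is the simplest
reading and was fixed before any evaluation.

The hematocrit model is the plasma-restriction identity for a drug
excluded from erythrocytes. It is evaluated but never fitted; on data
whose DBS/serum ratio does not actually carry an HCT signal it
overpredicts by roughly (1/k)/(1−HCT) ≈ 1.9× and serves as the pipeline's
built-in negative control.

## Agreement statistics

* **Deming regression** with error-variance ratio λ (default 1,
  orthogonal regression; the ratio of assay error variances is unknown).
  Slope by the closed form on centered sums; 95% CIs by leave-one-out
  jackknife with a t quantile on n−2 degrees of freedom (pair counts here
  are 25–35, too small for a normal quantile; no analytic CI is assumed).
* **Bland–Altman**: bias = mean difference, limits of agreement
  bias ± 1.96·sd (sample sd, n−1), CI of bias via t on n−1 df.
  Differences are always first argument minus second; in model
  evaluation the convention is **predicted − measured**, so an
  overpredicting model has positive bias (this is the orientation under
  which the hematocrit model's published-style failure signature — large
  positive bias, Deming slope ≈ 2 — reproduces).
* **EMA ±20% criterion**: pair i is "within" iff
  |a_i − b_i| ≤ 0.20·(a_i + b_i)/2; acceptance requires ≥ 67% of pairs
  within. Pairs with non-positive mean are excluded with a logged count.
* **MPPE/MAPE**: percent errors 100·(pred−obs)/obs centered by mean
  (default) or median — guideline texts use the mean, comparison tables
  often the median; both are one keyword apart.

## Assay validation

Calibration is least-squares of response on nominal with back-calculated
deviations flagged at ±15% (±20% at the LLOQ, 3 mg/L). Accuracy is
100·mean/nominal; precision is RSD (n−1 sd / mean). Inter-day statistics
pool all replicates across days (Table-style n = 5 days × 5 replicates);
per-day-means variants are not used. Recovery is the ratio of mean
pre-extraction to mean post-extraction response with a delta-method sd.
Hematocrit effect is the ratio of mean concentrations at each HCT level
to the level at the reference HCT 0.4, accepted within 85–115%.
Stability compares stored and fresh level means (±15%). Selectivity uses
one-way ANOVA with Bonferroni-adjusted pairwise t tests
(p_adj = min(1, m·p)).

## Spot-area correction

A 6 mm punch from a spot that does not fully cover it contains less
blood than the calibrators assume, biasing the measured concentration
low by exactly the coverage fraction. Scanning the card before and after
punching gives the blood area the punch removed, and

    factor = π(d/2)² / (area_before − area_after),  corrected = measured × factor.

Segmentation: Otsu threshold on the grayscale scan (with values at the
threshold kept as foreground, and a fixed-threshold fallback for
non-uniform scans), then the largest connected dark component — the card
frame printing and specks are smaller than the spot. Area = pixel count ×
(25.4/dpi)²; pixels are assumed square. Differences up to 5% above the
nominal punch area are clipped to factor 1 (the punch diameter is only
nominally 6 mm); larger differences raise an inconsistent-scan error.
The segmented "blood area" is the dark region only; a convention that
included a halo would rescale all factors proportionally.

## Synthetic-data generator

The generator is the study's ground truth, not a tuning knob. Defaults:
n = 35 pairs; truth k = 1.17, b = 1.04 mg/L (the linear-model constants a
bridging study of this design reports); serum log-uniform on 3–120 mg/L
(the clinical range across therapy weeks 0–16); multiplicative lognormal
noise with CV 15% on DBS given serum (assay RSDs are proportional and
concentrations positive; the true measurement-error magnitude of patient
samples is not known, so 15% is a choice); hematocrit normal(0.40, 0.03)
truncated to (0.2, 0.6), the validated selectivity range — the IBD
population sits at 0.35–0.46; capillary = venous × N(1, 0.05²) truncated
positive (capillary sampling slightly, not significantly, overreads);
56% of capillary spots fully cover the punch, the remainder drawing
coverage uniformly on (0.3, 1.0].

Spot images are star-shaped blobs r(θ) = r₀(1 + irregularity·s(θ)) with
s a normalized sum of 6 random Fourier harmonics, rendered at ≥150 dpi;
the punch disk is slid outward from the blob center by bisection on the
pixel-counted overlap until the blood fraction inside the punch matches
the request within ±0.02 (bounded redraws, then a generation error).
Ground-truth areas are exact pixel counts, so before − after equals
blood-in-punch to the pixel.

What the generator does **not** emulate: pharmacokinetic time courses
(week is a label), anti-drug antibodies, plate effects or 4PL optical
density curves, HCT-dependent spreading or recovery, scanner shading and
JPEG artifacts, or multi-spot card layouts. Passing tests therefore show
that the estimators recover known structure under idealized proportional
noise — not that the assay itself behaves.

## Numerical choices and known limitations

* Noise enters the generator on DBS given serum, but the fits regress
  serum on DBS; classical errors-in-regressors attenuation then biases
  1/k̂ slightly downward (k̂ up ~3% at CV 15%, and b̂ upward more
  noticeably, since the intercept is weakly identified on a log-uniform
  design). The recovery criterion is on k, whose median stays within 5%
  of truth at the study conditions; this bias is a property of the
  design, matching the real study's situation, and is left visible
  rather than "corrected".
* Determinism: every generator takes an explicit seed
  (`numpy.random.default_rng`); no global state. Pipeline JSON output is
  sorted-key with fixed layout, so reruns are byte-identical.
* Degenerate inputs raise typed errors (constant regressor, S_xy = 0 in
  Deming, blank scans, zero area difference) rather than returning NaN.
* Samples with serum or venous DBS below the LLOQ (3 mg/L) are flagged
  and excluded from fits by default (`include_below_lloq` overrides).
* Reported percentages are displayed rounded; all comparisons and stored
  values are full precision.
* Problem sizes used by the bundled analyses: 200 replicates for
  parameter recovery, 100 for the hematocrit-model comparison, 10⁴ pairs
  for the Bland–Altman closed-form check, 8 coverages at 300 dpi for the
  image round trip. Each analysis runs in seconds on one CPU.
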