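# Methods

## The measurement model

The package analyzes two delay-discounting tasks administered to a cohort
randomly assigned to one of three narrative scenarios (`positive`,
`negative`, `negative_regret`).

**Sexual discounting.** For each of four partner conditions
(`least_attractive`, `most_attractive`, `least_sti`, `most_sti`) a
participant rates, on a 0–100 visual analog scale (VAS), the choice between
immediate unprotected sex (0) and condom-protected sex after a delay (100).
Ratings are collected at a zero-delay anchor trial plus seven delays: 1 h,
3 h, 6 h, 1 day, 1 week, 1 month, 3 months. Calendar conversions are fixed
at 1 month = 30 days = 720 h and 3 months = 2160 h so that normalized delay
positions are reproducible.

**Monetary discounting.** Indifference points between a titrated immediate
amount and a delayed $1000 are measured at 1 day, 1 week, 1 month,
3 months, 1 year (8760 h) and 5 years (43800 h).

**AUC.** Each curve is summarized by the area under the normalized
indifference-point curve: delays divided by the longest delay, values
divided by their maximum (100 for VAS, $1000 for money), area taken as the
trapezoidal sum over consecutive points. AUC lies in [0, 1]; lower AUC
means steeper discounting. Monetary curves receive a synthetic anchor
(0, 1) before integration — the undelayed full amount is worth its face
value by definition. For sexual curves the zero-delay trial is a measured
response; whether it enters the integrand is controlled by the
`auc_anchor` flag (`measured`, the default, includes it; `exclude-zero`
drops it and rescales the remaining positions to span [0, 1] so a constant
curve still scores its constant). The active choice is recorded in every
report's metadata.

Curves with any missing response are excluded from that condition's
analyses (no imputation); exclusion counts are logged. Out-of-range VAS
values in loaded data raise in strict mode or are clipped-and-counted in
lenient mode.

## Statistics

**Rank-sum comparisons.** Scenario pairs are compared per condition with
the rank-sum (Wilcoxon/Mann–Whitney) test, standardized as
Z = (W − n_a(n+1)/2) / √Var with the tie-corrected variance
Var = n_a·n_b/12·[(n+1) − Σ(t³−t)/(n(n−1))]. AUC distributions carry point
masses at 0 and 1, so the tie correction matters. No continuity correction
is applied by default (matching common statistical-software output for
tie-adjusted Z); it is available as a toggle. At very small group sizes
(≤ 6) the W lattice is coarse relative to its standard deviation and the
uncorrected normal approximation can deviate from the exact permutation
distribution by up to ~0.056 in two-sided p; with the continuity toggle the
deviation stays below 0.05. At the cohort sizes this pipeline targets
(≥ 40 per group) the distinction is negligible.

The Z sign follows the first-listed group, and tables list scenario pairs
in a fixed order (negative vs negative-regret, positive vs negative,
positive vs negative-regret) so signs are comparable across runs. The
reported `mean_rank_diff` (mean rank of the first group minus the second)
is a descriptive analogue of a rank-score mean difference, not an
inferential quantity.

**Spearman correlations.** rho is the product-moment correlation of
tie-averaged ranks; p uses the t approximation on n − 2 degrees of freedom.
A constant vector makes rho undefined; such results are flagged, never
silently dropped.

**Permutation test for correlation differences.** The strength of the
AUC–HRBS association is compared between two scenario groups without
distributional assumptions: (x, y) pairs stay intact, group labels are
reshuffled B times (default B = 100,000) preserving group sizes, and the
two-sided p is the plain proportion of resampled |rho_A − rho_B| that
reach or exceed the observed |rho_A − rho_B| ("≥" rather than ">", which
is conservative and stable when the observed difference is exactly zero).
A resample in which a relabeled group has zero rank variance contributes a
null difference of 0 and is tallied. An optional (count+1)/(B+1) estimator
is available behind a flag. For small pooled samples an exhaustive
enumeration of all C(n, n_a) relabelings provides the exact null; the
Monte-Carlo path is tested against it. Pooled pairs are put in a canonical
sort order before resampling, so results are invariant to input row order,
and every stochastic result records its seed; identical seed and inputs
give bit-identical output.

**Quantiles.** Medians and quartiles use linear interpolation between
order statistics. No multiple-testing adjustment is applied anywhere; the
tables carry unadjusted p values with significance markers (0.05/0.001 for
the rank-sum table, 0.05/0.01 elsewhere) as presentation only.

## Questionnaire scoring

HRBS: sum of 11 items scored 0–5 (range 0–55, higher = riskier behavior).
ZTPI future subscale: mean of the 12 retained items scored 1–5 (one item
of the 13-item subscale is absent from the data this pipeline mirrors).
SSS: sum of 21 items scored 1–5 (range 21–105). CFC: mean (or total, by
flag) of 12 items scored 1–5. Reverse-keyed positions are configurable
because published keys differ across instrument versions; the defaults are
CFC {3, 4, 5, 9, 10, 11, 12} and ZTPI-future {2, 6} (the standard
future-subscale reversals re-indexed after the dropped item), and the
active key is recorded on every score. A column-mapping config can load
pre-computed totals directly, bypassing the scorers, when reproducing an
existing data set whose aggregation convention is unknown.

## The synthetic cohort generator

The generator exists so every pipeline stage is testable end-to-end
without collected data. It emulates the structure the analysis assumes —
not any particular empirical cohort.

**Discounting model.** Agents are hyperbolic discounters,
V = A/(1 + kD) with k in 1/h (an exponential variant is available behind a
flag for robustness checks). Sexual log k is normal per scenario ×
condition: log k = mu[scenario][condition] + sigma·z + male shift +
condition jitter, with z a standard-normal discounting propensity shared
across conditions. Defaults: sigma = 2.0 (AUC then spans most of [0, 1]),
condition jitter 0.3, male shift +0.8 (males discount sex more steeply,
mirroring the observed gender contrast), baseline mu = −5 (median
half-value delay about six days). VAS responses add N(0, 4²) noise on the
0–100 scale and clip to the scale; the monetary task runs the actual
adjusting-amount ladder (start offer $500, step $250 halving over 8
trials, deterministic value comparison by default, optional logistic
choice noise).

**Extreme responders.** Real AUC distributions carry point masses at both
ends. With probability `p_floor` (default 0.20) an agent answers 0
everywhere (AUC exactly 0); with `p_ceiling` (default 0.15) answers 100
everywhere (AUC exactly 1). Status is assigned by thresholding the latent
propensity at its upper/lower tails: marginally identical to an
independent coin flip with those weights, but the coupling keeps AUC
monotone in the propensity so rank correlations with other measures
survive the mixture.

**Copula.** Questionnaire totals, image count and the monetary rate are
tied to the propensity through a Gaussian one-factor copula. Target
Spearman correlations (between *sexual AUC* and each measure; defaults
monetary +0.04, HRBS −0.15, ZTPI +0.08, SSS −0.14, CFC −0.20, image count
−0.20 — the weak rank correlations typical of this literature) are
converted to latent Pearson loadings via rho_P = 2·sin(pi·rho_S/6), with
signs flipped where AUC's monotone-decreasing relation to the propensity
requires it. The one-factor structure is positive definite by
construction; the implied matrix is still checked. Totals come from
mapping latent normals through each instrument's range quantile function
(uniform bins) — simple, monotone, approximately rank-preserving. Marginal
uniformity over the instrument range is a simplification: real totals
cluster mid-scale, so passing tests say nothing about marginal score
shapes, only about rank structure. Downstream noise (VAS error, scenario
shifts, discretization, the point-mass ties) attenuates realized AUC–trait
correlations slightly below target (about 0.02–0.03 at the defaults),
which the recovery tests account for within their ±0.05 band.

**Scenario effects.** The shipped preset shifts log k downward (less
discounting, higher AUC) for: the regret scenario most strongly in the
most-attractive and least-STI conditions (−1.35 and −1.15), both negative
scenarios in the least-attractive and most-STI conditions (−0.85 to
−1.15), and not at all for money. Magnitudes were calibrated by power
scans to reproduce the qualitative sign/significance pattern at 135 per
group — the regret-vs-positive contrast in the most-attractive condition
detected in >= 95% of replicate cohorts, monetary contrasts at the ~5%
false-positive floor — because the target pattern is qualitative, not a
set of specific Z values. `null_config()` provides the same marginals with
no scenario effect for calibration studies.

**Demographics** are log-normal (age median 30, IQR ≈ 25–37; days since
last encounter median 6; income median $37,000) or simple categoricals
(44% female, 90% some college, 43% single, 75% employed), chosen to match
the cohort structure this pipeline targets. They play no role in the
inferential stages beyond the gender contrast and the summary table.

**Determinism.** One `numpy` Generator seeded from the config drives a
fixed draw order; identical config + seed gives byte-identical cohort
files. Analysis stages derive per-row seeds from a master seed and record
them in the emitted tables.

## Problem sizes used in the checks

The test suite and the acceptance script size their simulations to run on
one CPU in a few minutes: 100 replicate cohorts at 135/group for the
power/selectivity checks, 500 replicate 40/group cohorts for null
calibration (type-I error of the assembled rank-sum table within
[0.03, 0.07] at alpha = 0.05, per-contrast p uniform by KS), ~5000
participants for mixture and copula recovery, and exhaustive-oracle
comparisons at 5 pairs per group where C(10,5) = 252 relabelings can be
enumerated. The full pipeline at the study size (408 participants,
B = 100,000 permutations for all 12 correlation-difference rows) completes
in under two minutes.

## Known limitations

- The generator's marginals (uniform-bin questionnaire totals, log-normal
  demographics) are deliberately simple; only rank structure and the
  point-mass mixture are calibrated.
- All four sexual conditions share one latent propensity, so
  between-condition AUC correlations are higher than a real cohort would
  show; no analysis here depends on them.
- The rank-sum normal approximation is asymptotic; for groups smaller than
  about 10 prefer the continuity toggle or an exact test.
- The permutation test compares correlation *differences* on the pooled
  relabeling null; it does not test either correlation against zero.
- Reproducing a deposited data set requires a user-supplied column mapping
  (and, if the file stores AUC rather than trial-level responses, the
  AUC-bypass path); scoring conventions of pre-computed totals cannot be
  inferred from the file itself.
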