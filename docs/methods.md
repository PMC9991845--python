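# Methods

This note documents the models, defaults and design choices behind the
package, and what the synthetic-data tests do and do not establish about
real data.

## Adherence scoring

Nine SAFBDG recommendations are scorable from QFFQ-style inputs; the salt
and water guidelines are excluded because the required data are not part
of the input schema. Every guideline contributes at most one point, so the
overall score lies in [0, 9] under both schemes.

### Suggested cut-points

Thresholds and boundary conventions (all configurable via
`SuggestedCutpoints`):

| guideline | rule | tie handling |
|---|---|---|
| variety | DDS >= 4 of 9 FAO groups | inclusive |
| active | precomputed `pa_active` flag | — |
| starchy | >= 10 food-guide units/d | inclusive |
| fruit & veg | >= 400 g/d | inclusive |
| legumes | >= 21.4 g/d (75 g serving scale) | inclusive |
| dairy | >= 400 g/d liquid dairy or >= 50 g/d hard cheese | inclusive |
| protein: meat sub | 0 < fish/chicken/lean meat < 90 g/d (0.5) | strict both ends |
| protein: egg sub | >= 4 eggs/week = 200/7 ~ 28.6 g/d (0.5) | inclusive |
| fats: range sub | 20 <= fat %TE <= 30 (0.5) | inclusive |
| fats: SFA sub | SFA < 10 %TE (0.5) | strict |
| sugar | < 6 %TE -> 1; < 10 %TE -> 0.5; else 0 | strict |

Rules phrased "at least"/"up to" resolve ties toward adherence; strict
"less than" rules resolve away from it. Two deliberate choices: the meat
sub-rule requires strictly positive intake (an abstainer does not satisfy
"can be eaten daily"; set `meat_require_positive=False` to relax), and the
egg threshold uses the exact 200/7 g/d rather than a rounded 29 g/d.
%TE conversions use 37 kJ/g for fat and saturated fat and 17 kJ/g for
added sugar. The DDS counts a FAO group at >= 15 g/d by default
(conventional practice; configurable) and flags low diversity below 4.

### Data-driven tertiles

Each recommendation has a continuous compliance metric with an
orientation (higher-better, lower-better, or distance outside the 20-30
%TE fat range). The metric table is a reconstruction from the guideline
definitions — DDS, activity units/week, starchy units, g/d for food
groups (dairy in milk-equivalents, liquid + 8 x hard cheese via the
400 g / 50 g rule), %TE for SFA and sugar — and is overridable
(`metric_defs=`). Cut-points are the 33rd and 66th percentiles of the
control distribution only; highest tertile scores 1, middle 0.5, lowest 0,
with sub-recommendations halved so each guideline still tops out at 1.
The sugar guideline is tertiled like the others by default.

Percentile definition: the inverted empirical CDF, i.e. each cut-point is
an order statistic. This makes tertile scores exactly invariant under any
strictly monotone transform of a metric (interpolated quantiles are not),
at the cost of cut-points always being observed values. Ties at a
cut-point fall to the lower tertile, consistent with "low: score <= q33"
for the overall categorisation. With ~400 controls the difference from
interpolated percentiles is at most one subject per boundary.

The overall score is categorised low/mid/high by control overall-score
tertiles; on the default synthetic cohort these boundaries come out near
3.75 and 5.0 on the 0-9 scale.

## Energy misreporting

BMR uses the Schofield weight-only equations (female bands 18-30, 30-60,
60+; male bands included for completeness). The Goldberg band on EI/BMR is
`PAL * exp(+/- z * S/100)` with `S = sqrt(CV_EI^2/n + CV_BMR^2 + CV_PAL^2)`;
defaults PAL 1.55, CV_EI 23 %, CV_BMR 8.5 %, CV_PAL 15 %, n = 1 (a
one-month questionnaire treated as a single observation), z = 1.96, giving
a plausibility band of roughly 0.88-2.72. All constants are assumptions
exposed in `GoldbergParams`; subjects are classified, never excluded.

## Inference

`fit_clogit_1to1` maximises the 1:1 conditional likelihood by
Newton-Raphson on within-pair differences: convergence at max |step| <
1e-8, at most 50 iterations, analytic gradient and Hessian; separation is
declared when a coefficient passes |beta| > 30 with a non-vanishing
gradient, and a term with no within-pair variation raises a
non-identifiability error rather than silently dropping out. Standard
errors come from the inverse observed information; all p-values are Wald
and no multiplicity adjustment is applied. Unconditional logistic
regression (used for menopausal and obesity strata, which break the
matching) is delegated to statsmodels behind the same result contract.

Categorical covariates are one-hot coded against the alphabetically first
level; `"unknown"` and NaN count as missing and models are complete-case
with the dropped count reported. The trend test reports both the ordinal
(0/1/2) Wald slope and the labelled highest-vs-lowest dummy contrast,
since "trend across tertiles" is read both ways in practice. The
confounder screen evaluates candidates one at a time against the crude
model (the cumulative variant can be built from the same pieces) and keeps
a candidate when |OR_adj - OR_crude| / OR_crude > 0.10.

## Synthetic data

The generator emulates: 1:1 pairs matched on age (members within +/- 5
years) and area; right-skewed, zero-inflated log-normal intakes per food
group split over a bundled ~45-item toy food list (the published starchy
unit weights: soft porridge 125 g, stiff 60 g, crumbly 45 g, bread 35 g,
potato/sweet potato 100 g, pasta/samp 75 g, cereal 25 g, rice 65 g);
arm-specific waist circumference (93.3 +/- 13.8 vs 95.8 +/- 13.7 cm), HIV
prevalence (16.5 % vs 22.6 %) and alcohol; receptor status for cases; and
injected under-/over-reporting (13.1 %/24.0 % cases, 11.6 %/27.0 %
controls) realised as EI/BMR ratios drawn strictly inside the
corresponding Goldberg regions.

Intake parameters were fixed once, analytically, from control-arm
adherence levels reported for this population: for a zero-inflated
lognormal with consumption probability p, median m and log-sd s, the
adherence probability at threshold t is `p * Phi((ln m - ln t)/s)`; p, m
and s were chosen so that legume adherence is ~22.5 %, egg ~47 %,
fish/chicken/lean meat ~74 %, liquid dairy ~13 %, starchy units ~40 %,
fat-in-range ~44 % and SFA < 10 %TE ~55 %. These are the generator's
defaults and are not revisited.

Case assignment is the key design choice: both pair members draw
exchangeable profiles, each member's overall tertile category c in
{0, 1, 2} is computed against reference cut-points (an internal reference
pool of 600 profiles), and the case label goes to member A with
probability `exp(b*cA) / (exp(b*cA) + exp(b*cB))`, `b = log(OR)/2`. The
conditional likelihood of the generated data is then exactly the
conditional logistic model with per-step log odds b, so the high-vs-low
clogit estimand equals the configured OR by construction. Optional
stratum-specific ORs (postmenopausal pairs, ER-positive tumours) override
the overall OR for those pairs, with the ER override taking precedence.
`simulate_exposure_pairs` exposes the same mechanism at category level for
cheap replicate studies (parameter recovery, test calibration).

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: nutrient totals are drawn as %TE fractions
rather than computed from the food list, so item intakes and nutrient
totals cohere only through energy; misreporting scales energy and nutrient
grams but not item intakes (real under-reporters under-report foods too);
dietary diversity comes out higher than survey reports for this population
because matching the printed per-food adherence levels forces most FAO
groups to be consumed; intakes are independent across food groups; and the
analyst's re-derived tertiles differ slightly from the generating
reference cut-points, which attenuates a fitted OR of 0.56 to roughly 0.6
on average over replicate studies — a measurement-error effect the package
reports honestly rather than hides.

## Problem sizes

Default study size is 396 pairs throughout, the motivating design.
Replicate-based checks use 500 replicates for parameter recovery, 1000 for
trend-test calibration and CI coverage, and 300 per odds ratio for the
multi-OR recovery suite; convergence of the empirical conditional OR is
checked at 5000 pairs. The brute-force likelihood oracle uses iterated
grid refinement (12 rounds, 21 points per axis from a +/- 8 span) reaching
~1e-7 resolution on each coefficient.

## Known limitations

- The continuous-metric table behind the tertile scheme is a
  reconstruction; a study with access to the original variable definitions
  may choose different metrics for "be active" and the fat-range rule.
- The 1:1 conditional MLE is slightly biased away from zero at realistic
  numbers of informative pairs (order 1/n); the recovery tests account for
  this explicitly.
- No 1:M matching, penalised or exact logistic regression; separated data
  raise an error instead of producing a penalised estimate.
- The toy food list is illustrative, not a reconstruction of any survey
  instrument.
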