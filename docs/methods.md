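# Methods

## Rule engines

All three systems act on three nodule attributes: the mean diameter (the
average of the maximum axial diameter and its perpendicular minor
diameter, in mm), the GGN-vessel-relationship type (GVR I–IV), and a
boolean flag for "other suspicious malignant imaging features". The flag
is an input: the package never infers it from size or any other attribute,
because no closed list of qualifying features exists. Diameters are
compared raw — thresholds are inclusive (`>=` at 20 mm and 30 mm) and no
rounding is applied before comparison, which avoids boundary artifacts at
values like 19.95 mm.

The 4x upgrade applies after base categorization and only to base
categories 3, 4a and 4b; a flagged category-2 nodule stays 2 (4x is
defined as "category 3 or 4 with suspicious features"). Positivity
(predicted invasive) is category ≥ 4a for cLung-RADS v2022. For the
baselines the cutoff is taken as 4x, the only reachable category ≥ 4 for a
pGGN under size-only rules; this is the unique choice consistent with the
small baseline positive counts in the published confusion tables (e.g.
TP+FP = 10 of 169 for Lung-RADS 1.0 on the training set, versus the far
larger count a positive-at-3 cutoff would imply given the diameter
distribution). `is_positive` raises a contract error for (system,
category) pairs the system cannot emit, e.g. 4a under a baseline.

Follow-up stability (the inclusion criterion of stable or grown nodules
over ≥ 3 months) is metadata, not a rule input; the engines do not enforce
it.

## Metrics

All panel metrics are computed from the exact integer cells; percentages
are rounded half-up to one decimal *only for display* (`pct`). Two
published training-set values are internally inconsistent with their own
printed cells — the training cLung-RADS MCC (printed 60.2%, exact 55.2%
from TP=131, FP=14, FN=7, TN=17) and several F1 values evidently computed
from pre-rounded percentages (exact training cLung F1 is 92.6%, printed
92.5%). The package always reports the exact values; tests and the
acceptance script only assert the published numbers that are consistent
with their cells.

Degenerate-input conventions: MCC is 0 when any marginal is empty;
recall/precision with empty denominators are `None` with an explanatory
flag, never silently 0; F scores are undefined whenever either factor is.

AUC treats a system's output as an ordinal score via the category ranks
2→1, 3→2, 4a→3, 4b→4, 4x→5 — the only information-preserving scoring of an
ordinal system. The estimator is the tie-corrected Mann–Whitney
probability (ties credit 0.5), computed via midranks; its variance uses
the DeLong structural components S10/m + S01/n, and the 95% CI is the
normal approximation truncated to [0, 1]. The paired DeLong test uses the
full 2×2 placement covariance; a zero-variance difference of exactly zero
(identical scores, or both systems constant) reports p = 1 rather than an
error — the comparison is vacuous, not ill-posed. Single-class pathology
labels do raise, since the ROC itself is undefined.

Inter-rater agreement is ICC(2,1): two-way random effects, absolute
agreement, single rater, from the standard mean-squares decomposition

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).

Absolute agreement is the right variant for category assignments, where a
systematically shifted reader should be penalized; tests verify this with
a constant-offset design (ICC ≤ 0) and cross-check against pingouin's
ICC(A,1). An all-identical matrix returns 1 by convention.

## Synthetic cohorts

The generator emulates a two-set prospective pGGN screening study:
patients carry 1–3 nodules (multiplicity 487/32/7 across 526 patients in
the combined default); each nodule independently receives a GVR type, a
diameter, a suspicious flag (Bernoulli given GVR), and a pathology label
(Bernoulli given GVR and flag). Ages are normal truncated to [18, 90];
axis lengths are derived from the mean diameter with a short/long ratio
uniform on [0.7, 1], so the mean-diameter invariant holds exactly. One
integer seed drives a single `numpy.random.Generator`; cohorts are
bit-identical per (config, seed).

Diameters are lognormal, moment-matched to the reported mean ± SD
(13.8 ± 6.4 mm training, 13.5 ± 6.0 validation, 13.6 ± 6.1 pooled):
σ² = ln(1 + s²/m²), μ = ln m − σ²/2. Only moments are reported for the
real cohorts; the lognormal guarantees positivity and the right skew
typical of nodule sizes.

Default configurations (`training_config`, `validation_config`,
`study_config`) carry the reported GVR margins ((15,19,19,116)/169,
(35,41,51,276)/403, pooled (50,60,70,392)/572), sex and age moments, and
pinned nodule totals (169/403/572; the multiplicity vector is
rejection-resampled until it sums to the pinned total, typically ~20
draws). Invasiveness conditionals are a monotone-in-GVR table whose
GVR-IV-unflagged entry is solved in closed form so the expected invasive
fraction equals the study prevalence (138/169, 283/403, 421/572); the
training default is further calibrated to the training cLung-RADS cells.
Suspicious-flag rates (0.02/0.17/0.03/0.03 by GVR) are chosen so the 4x
frequency (~4%) and the extra positive-stratum mass match the reported
category and cell counts; they are derived, not measured, quantities.

### Calibration to confusion cells

`calibrate_to_cells` makes the *expected* cells of one system equal a
target (tp, fp, fn, tn) exactly, by making the predicted-positive stratum
an event of exactly the right probability and setting
P(invasive | positive) = TP/(TP+FP), P(invasive | negative) = FN/(FN+TN):

* baselines — flags are sampled only at/above the size threshold
  (`suspicious_floor_mm`), so positives = flagged and the flag rate is
  s = [(TP+FP)/n] / P(D ≥ t); infeasible if that exceeds 1;
* cLung-RADS v2022 — only GVR II nodules are flagged, so positives =
  {GVR III, GVR IV, flagged GVR II} with flag rate
  s₂ = [(TP+FP)/n − g₃ − g₄] / g₂. Flagging GVR I as well would leak
  flagged sub-30-mm GVR I nodules (category 2, negative) into the
  positive-stratum invasiveness rate; restricting to GVR II keeps the
  algebra exact. Targets below the GVR III+IV floor g₃+g₄, or above
  g₃+g₄+g₂, raise a calibration error.

One published target is genuinely infeasible: the validation-set GVR
margins put 327/403 nodules in types III+IV (all mapped to positive
categories), but the validation cLung-RADS confusion table has only 310
positives. The unpublished joint GVR × prediction table cannot exist under
the printed margins and rules simultaneously; calibration reports this as
an explicit error rather than approximating. Exact reproduction of any
printed table is instead provided by `fixture_exact_cohort`, which builds
a deterministic cohort (GVR IV 12-mm nodules for predicted-positives, GVR
I 10-mm for negatives; flagged 25/35-mm nodules for the baselines) hitting
the cells nodule-for-nodule.

### What the synthetic data does not capture

Nodules are independent given the patient (no within-patient biological
correlation); GVR, diameter, flag and pathology have no residual
dependence beyond the modelled conditionals; there is no reader noise, no
longitudinal growth, and no joint GVR × pathology structure beyond the
margins (the real joint table is unpublished). Tests passing on these
cohorts validate the rule engines, the metric estimators and the
calibration algebra — not the clinical performance of any system on real
patients.

## Problem sizes and numerical choices

The test suite uses ~18k-patient cohorts for parameter recovery and a
4.6k-patient cohort for the stochastic DeLong separation check; the
acceptance script uses a ~100k-nodule cohort for recovery, 200 random
instances (n ≤ 200) for the AUC oracle, and n ≤ 100 for the DeLong
variance oracle (tolerance 1e-10). Oracle comparisons for AUC use exact
pair counting; ICC cross-checks use an independently coded ANOVA and
pingouin. Hypothesis property tests run derandomized.

## Limitations

* Published AUCs (0.718/0.543/… ) are not reproducible exactly: they
  depend on per-category × pathology cross-tabulations that were never
  published. The AUC machinery is therefore validated by construction
  (oracles and identities), not against those numbers.
* Per-nodule evaluation throughout; no per-patient aggregation rule for
  multi-nodule patients is defined (the study analysed 572 nodules as
  units).
* The reported cohort tables contain small internal inconsistencies
  (a column summing to 168 of 169; invasive totals differing between
  tables; the infeasible validation joint noted above). Where they
  conflict, the confusion tables and the overall invasive count n = 421
  take precedence.
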