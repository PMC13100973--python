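# Methods

This note documents the models and procedures implemented in
`frailtybrain`, the choices made where the design was genuinely open, and
what the synthetic cohort does and does not emulate.

## The deficit-accumulation frailty index

The index for a participant is the number of health deficits present
divided by the number of health variables observed, in [0, 1]. Items are
first binarized (0 no deficit, 1 deficit, missing stays missing) and then
screened, in this fixed order:

1. **missingness** — items with > 15 % missing values are dropped
   (`dropped_missing`);
2. **prevalence** — deficit rate among observed values must lie in
   [1 %, 80 %] (`dropped_rare` / `dropped_common`);
3. **pairwise correlation** — while any retained pair has Pearson
   |r| ≥ 0.8 (pairwise-complete, on the binarized items), the member with
   more missing values is dropped; ties go to the later item in spec order
   (`dropped_correlated`). Pearson on 0/1 items is the phi coefficient;
   the coefficient type is a package choice;
4. **multicollinearity** — variance inflation factors on complete cases,
   iteratively dropping the max-VIF item while any VIF > 10
   (`dropped_vif`).

The screening order itself is a package choice; each decision and the
statistic that triggered it are recorded in the `ScreeningLedger`, so the
retained set is reproducible from the ledger alone. Scores are computed
per participant over the observed retained items and reported only when
≥ 80 % of items are observed; otherwise `included = False` and the index
is missing. No imputation is performed anywhere.

**Binarization cut-points.** The default 32-item map uses conventional
clinical cuts (BMI outside [18.5, 30); SBP ≥ 140; DBP ≥ 90; resting HR
outside [60, 100); GDS-SF ≥ 5; GAD-7 ≥ 5; MMSE < 24; PFAQ ≥ 6; any CDR
item ≥ 0.5; polypharmacy ≥ 5 drugs; multimorbidity ≥ 2 diagnoses; current
smoking, substance/alcohol misuse and disease histories as reported).
These are conveniences — a study with its own scoring syntax should pass
its own `HealthItemSpec` list. Threshold rules are closed on the deficit
side (value = cut ⇒ deficit); for two-sided band rules the healthy band is
[low, high), i.e. the upper cut is on the deficit side.

**Sensitivity variants.** Three index variants drop the tagged items —
(a) CDR; (b) CDR + MMSE; (c) CDR + MMSE + GAD-7 + GDS-SF — with the
completeness gate applied to the reduced denominator.

## Group statistics

Continuous variables: one-way ANOVA, F with df (k−1, N−k), Tukey HSD post
hoc, pooled-SD Cohen's d (sign convention matching the Tukey mean
difference: positive when the second group of the pair is larger).
Categorical variables: Pearson χ² without continuity correction (this is
the variant that reproduces the worked contingency examples exactly).
The ANCOVA group test is the extra-sum-of-squares F of the group factor
on top of the covariates (age, sex, education by default); post hoc
contrasts run on the outcome with the mean-centred covariate contribution
removed, so they are contrasts of adjusted means. All analyses are
complete-case per variable and report the n actually used. When the
covariates already explain the outcome to numerical precision the group F
is reported as 0 with p = 1 rather than an ill-conditioned ratio.

## Diagnostic classification

Binary XGBoost logistic models (one per pairwise group comparison; the
disease or more-impaired group is coded 1). Class imbalance is handled in
the loss with `scale_pos_weight = n_neg/n_pos` computed on the training
partition. Data are split 80 % train / 10 % test / 10 % reserve,
stratified; the reserve partition is never touched.

Hyperparameters (`max_depth` 2–8, `learning_rate` 0.01–0.3 log-uniform,
`n_estimators` 50–500, `min_child_weight` 1–10, `subsample` 0.6–1.0;
default budget 25 evaluations) are selected by a Gaussian-process
surrogate search: 8 random initial points, then expected-improvement
acquisition over a Matérn-5/2 GP on the unit cube, each candidate scored
by mean 10-fold stratified CV AUC on the training partition.

The **reported fold AUCs** are re-computed with the selected configuration
on an independent fold split: reusing the search-winning folds would carry
the winner's-curse optimism of the search into the headline number (worth
≈ +0.04 AUC on a weakly separable pair). The final model is refit once on
the full training partition; threshold metrics (confusion matrix
row-normalized over true classes, sensitivity, specificity, precision,
F1, accuracy, balanced accuracy, Brier score) are computed on the held-out
test partition at threshold 0.5 (the threshold is a package default, not a
tuned value). For a single monotone feature the mean CV AUC coincides, up
to fold noise, with the tie-corrected rank AUC (Mann–Whitney U/(n₁n₀)),
which for two normal classes converges to Φ(Δμ/√(σ₁²+σ₂²)) — the analytic
oracle used in the tests.

**Attributions.** Per-sample additive attributions use the exact TreeSHAP
path algorithm implemented in-package in float64 (numba-compiled), with
node covers as the background weighting — the same convention as
XGBoost's native `pred_contribs`, which serves as an independent
cross-check in the tests. The native path accumulates in float32 and
leaves ~1e-6 residue in the local-accuracy identity for large ensembles;
the float64 implementation satisfies `sum(φ) + base = margin` to ~1e-12.
Branch decisions replicate XGBoost's `float32(x) < float32(split)`
comparison exactly.

## Mass-univariate brain associations

One OLS per unit — an atlas region's gray-matter volume, or a
connectivity edge (Fisher z = atanh r, inputs clipped at |r| = 1−1e-7
with a warning). The design is: intercept, frailty index, dummy-coded
scanner (reference = most frequent level), plus any extra covariates
(CDR total, SNR metrics) for sensitivity re-runs. Edges live on the
strict upper triangle with the unordered pair canonicalized by atlas
order; self-edges are rejected.

Because every unit in a family shares one design matrix, the family is
solved with a single QR decomposition; results match `statsmodels` OLS to
1e-8 on small fixtures (tested). Constant-outcome units are flagged
degenerate and excluded from the FDR family with a log entry.

Significance uses the dual criterion: Benjamini–Hochberg FDR across the
family of model p values within one group's analysis, a unit significant
iff FDR-adjusted model p < α **and** raw frailty-predictor p < α
(α = 0.05). FDR-adjusted predictor p values are also emitted but do not
feed the flag. Families are never pooled across groups. Node-degree
summaries count each region's significant edges split by the sign of t,
ranked with a deterministic name tie-break.

## Subsampling contrasts

Within a group, each unit's OLS is refit on `n_draws` subsamples drawn
without replacement at a configurable fraction (default 0.8 — not a
published value; recorded in the output metadata). Draw d's random stream
is derived from (master seed, d), so results do not depend on execution
order; degenerate draws are resampled (capped retries). Two groups'
empirical t distributions are compared per unit with Welch t-tests
(equal-variance is not assumed; the flavour of "independent-sample t-test"
is a package choice), restricted to units significant in at least one
group's full-sample analysis, with BH-FDR over the restricted set. The
dominant group is the one with the larger mean |t|; its direction is the
sign of its mean t.

Two caveats are intrinsic to the procedure and documented deliberately:

* the magnitude of the contrast t grows with `n_draws` (subsample draws
  are treated as samples), so `n_draws` is reported alongside every
  contrast and printed contrast magnitudes are not comparable across
  configurations;
* conditioned on two fixed datasets, the draw-level Welch test is
  anticonservative — between-dataset sampling noise in the full-sample t
  (order 1) dwarfs the subsampling SE. Calibration under the null comes
  from the restriction rule: with no injected effects, no unit passes the
  full-sample dual criterion in either group, so nothing is contrasted.

## Quality metrics

Spatial SNR = mean/SD of (already masked) brain-voxel intensities; scale
invariant by construction. Temporal SNR: the series is cut into
consecutive non-overlapping 20-point segments anchored at the first
sample; each complete segment contributes mean/SD; the trailing remainder
is discarded (n segments = ⌊T/20⌋). The raw mean-of-ratios estimator is
biased upward by E[σ/S] ≈ 4 % at segment length 20 (Jensen's inequality);
by default each ratio is divided by the normal-theory factor
√((L−1)/2)·Γ((L−2)/2)/Γ((L−1)/2) so the estimator is unbiased for μ/σ on
stationary Gaussian data (switchable via `bias_correction=False`).
tSNR is deliberately not shift-invariant. SNR is computed per series;
voxel-level aggregation happens upstream of this package.

## Synthetic cohort generator

The generator defines the study conditions for every test: three groups
with latent frailty drawn from normals truncated to [0, 1] by rejection
(CU 0.14 ± 0.065 n = 1924; AD 0.24 ± 0.075 n = 1126; FTLD 0.27 ± 0.10
n = 411), 32 binary items whose per-group deficit probability defaults to
the group mean frailty (so the computed index recovers the group means in
expectation), missingness completely at random, ROI volumes linear in
frailty with per-group slopes, scanner offsets and Gaussian noise, and
connectivity edges with the same linear structure on the Fisher-z scale.
Demographics (age, sex, education) are drawn from the published
group-specific distributions for use as ANCOVA covariates. Rejection
truncation (not clipping) keeps moments close to the configured normal in
this parameter range; items are independent given group by default, with
an opt-in logistic coupling to latent frailty for end-to-end runs.

What the generator does **not** emulate: within-person dependence between
items beyond the group/frailty structure, spatial covariance between ROIs
or edges, non-Gaussian volume noise, site/scanner confounding with
diagnosis, and informative missingness. Passing tests therefore establish
that the machinery is correct and calibrated under these idealised
conditions, not that real acquisitions satisfy them.

## Problem sizes and determinism

Classification runs at the full published group sizes; the imaging stages
in the tests and the demonstration pipeline use reduced parcellations
(6–116 regions) and `n_draws` of 100–200 subsamples, which the package's
vectorised OLS handles in seconds — the statistical properties under test
do not depend on the family size. Every stochastic component (generator,
splits, folds, search, subsampling) is driven by explicit seeds through
`numpy.random.SeedSequence`; identical configuration and seed reproduce
byte-identical outputs, which the test suite verifies.
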