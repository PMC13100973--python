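# frailtybrain

Frailty — the accumulation of health deficits across physical, behavioral,
cognitive, emotional and functional domains — distinguishes people living
with dementia from cognitively unimpaired (CU) older adults and tracks the
structural and functional brain changes of Alzheimer's disease (AD) and
frontotemporal lobar degeneration (FTLD). `frailtybrain` implements the
complete analysis chain for this kind of study as a tested Python package:

1. **Frailty index construction** (deficit accumulation). Each of *k* ≥ 30
   health variables is rescored to 0 (no deficit) / 1 (deficit); items are
   screened (≤ 15 % missing, deficit prevalence in [1 %, 80 %], pairwise
   Pearson |r| < 0.8, iterative VIF < 10, every decision recorded in a
   ledger) and the index for person *i* is

   FI_i = (number of deficits present) / (number of items observed),

   computed only when ≥ 80 % of items are observed. Three sensitivity
   variants drop the dementia-severity (CDR), cognition (MMSE) and
   anxiety/depression (GAD-7, GDS-SF) items to control circularity.
2. **Group statistics** — one-way ANOVA with Tukey HSD, Pearson χ² (no
   continuity correction), covariate-adjusted ANCOVA, Cohen's *d*.
3. **Diagnostic classification** — an XGBoost binary logistic model on the
   frailty index (or the items), loss-weighted by
   `scale_pos_weight = n_neg / n_pos`, hyperparameters chosen by a
   Gaussian-process Bayesian search maximising 10-fold stratified CV AUC on
   the 80 % training partition, evaluated on a held-out 10 % test partition;
   exact (float64) TreeSHAP attributions explain each prediction.
4. **Mass-univariate brain associations** — one OLS per AAL-atlas region
   (gray-matter volume) or ROI-pair connectivity edge (Fisher z), frailty as
   main predictor, scanner dummies as covariates; Benjamini–Hochberg FDR
   over the model p family, a unit is significant when FDR-adjusted model
   p < .05 **and** raw frailty p < .05; node-degree summaries for edges.
5. **Subsampling contrasts** — per-group empirical distributions of the
   frailty *t* statistic from repeated subsamples without replacement,
   contrasted between groups with Welch t-tests over units significant in
   at least one group, FDR corrected.
6. **Quality metrics** — spatial SNR (mean/SD of masked voxel intensities)
   and segmented temporal SNR (20-point segments, bias-corrected mean of
   per-segment mean/SD) with per-group frailty correlations.

A synthetic cohort generator reproduces the published three-group structure
(CU n = 1924 with FI ≈ 0.14 ± 0.065, AD n = 1126 with 0.24 ± 0.075, FTLD
n = 411 with 0.27 ± 0.10; truncated normals on [0, 1]) together with binary
items, ROI volumes with injectable frailty slopes and scanner effects, and
connectivity edges — so the whole chain runs and is testable end to end
without any external data.

## Worked example

```python
import frailtybrain as fb

# cohort at the published group parameters
cfg = fb.CohortConfig(seed=1)
frailty, group = fb.generate_frailty_scores(cfg)

res = fb.one_way_anova(frailty, group)
print(res.summary())

mask = group != "FTLD"
clf = fb.FrailtyClassifier(
    frailty[mask].to_frame("frailty"),
    (group[mask] == "AD").astype(int),
    fb.ClassifierConfig(seed=1, search_iters=12, n_init=6),
)
print(clf.fit().summary())
```

prints (abridged):

```
anova: F(2, 3458) = 964.653, p = 0, n = 3461
group_a group_b   mean_a   mean_b      diff        p_adj  cohens_d
     AD      CU 0.236986 0.143253 -0.093733 1.305955e-12 -1.408461
     AD    FTLD 0.236986 0.273565  0.036579 1.305955e-12  0.454983
     CU    FTLD 0.143253 0.273565  0.130312 1.305955e-12  1.911487

Class-weighted gradient-boosted classification
scale_pos_weight (neg/pos on training): 1.708
CV AUC (k=10): 0.833 +/- 0.033  [range 0.766-0.897]
held-out test AUC: 0.808
accuracy 0.744 | balanced accuracy 0.742 | Brier 0.191
sensitivity 0.732 | specificity 0.751 | precision 0.631 | F1 0.678
```

The ANOVA *F* ≈ 965 on one simulated draw matches the published
F(2, 3458) = 948.9 up to cohort sampling noise, and the mean CV AUC of
0.83 for AD vs CU sits at the binormal ceiling
Φ(Δμ/√(σ₁² + σ₂²)) ≈ 0.843 implied by the group frailty distributions
(published: 0.85 ± 0.04).

A full run — simulation, screening, frailty variants, three pairwise
classifications, per-group region/edge associations and subsampling
contrasts — is one command:

```bash
frailtybrain run-all --out results/demo --seed 1
frailtybrain report --run-dir results/demo
```

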