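# asps

Risk scoring for longitudinal urinary steroid-ratio panels. The package
turns each athlete's time series of the five monitored ratios (T/E,
A/Etio, 5a-ADiol/5b-ADiol, 5a-ADiol/E, A/T) into a single doping-risk
probability and decomposes that risk into per-biomarker contributions.

The pipeline:

1. **Sequence probabilities** (`asps.abp_sequence`) — a normal-normal
   conjugate hierarchy on log ratios yields, for every new measurement,
   the posterior-predictive CDF value given the athlete's *previous*
   measurements (prequential scoring). Values near 0/1 mean unusually
   low/high relative to the athlete's own adaptive reference range.
2. **Trajectory features** (`asps.trajectory_features`) — 80 named
   per-athlete summaries: 5 means, 5 ranges, 5 ranges of first and 5 of
   second differences, 10 level covariances, 10 first-difference
   covariances, plus the square of each. Computed either on raw ratios
   (`original`) or on sequence probabilities (`abp_sp`).
3. **Classifier** (`asps.asps_classifier`) — weighted logistic
   regression (laboratory athletes weight 20, doping-control athletes
   weight 1), backward-elimination variable selection (default target:
   21 regressors), stratified K-fold cross-validation with equal
   positives per fold (laboratory athletes always train, never test),
   and midrank Mann-Whitney AUC. The model's predicted probability is
   the abnormal steroid profile score (ASPS).
4. **Source attribution** (`asps.source_attribution`) — the linear
   predictor splits additively into per-biomarker contributions plus a
   covariance source; sources with contribution > 0.8 are flagged
   (an increment of 0.8 multiplies the doping odds by exp(0.8) ≈ 2.2).
   Threshold calibration reports FPR/TPR operating points.
5. **Cohort simulator** (`asps.cohort_simulator`) — synthetic clean and
   doped athletes with log-scale random intercepts, within-athlete
   noise, regime-specific additive effects with exponential washout, and
   correlated T/E vs 5a-ADiol/E responses, so the whole pipeline is
   testable without any external data.

Note: the enumerated feature recipe yields 40 base features and their
40 squares per measurement kind (80 names); larger counts quoted
elsewhere for this construction cannot be reconciled with the recipe.

## CLI

```sh
asps simulate --seed 1 --out cohort.csv              # synthetic cohort
asps abp-sp cohort.csv --out zvalues.csv             # sequence probabilities
asps features zvalues.csv --out features.csv         # 80-column table
asps train features.csv --model-out model.json --select-to 21
asps cv features.csv --folds 5 --seed 1              # stratified CV AUC
asps score features.csv --model model.json --out scored.csv
asps attribute features.csv --model model.json --out attribution.csv
asps thresholds attribution.csv --out thresholds.csv
asps run --seed 1 --outdir out/                      # end-to-end
```

`asps run` writes `cohort.csv`, `model.json`, `scores.csv` (per-athlete
contributions, flags, ASPS and out-of-fold score), `thresholds.csv`,
`priors.json` and a `manifest.json` that reproduces the run.

Input CSVs are wide (`athlete_id, occasion, te, a_etio, adiol_ratio,
adiol_e, a_t` with optional `label`, `weight`, `source`) or long
(`athlete_id, occasion, biomarker, value`). Athletes with fewer than 4
occasions are excluded.

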