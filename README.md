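# pairclass

Rank-based gene-pair features and boosted ensembles for predicting tumor
subtype cluster labels **across expression platforms** — microarray to
RNA-seq — with downstream survival stratification and single-cell
localization of the predictive pattern.

## Who this is for and what it does

Cohorts profiled on different platforms cannot be compared value-for-value:
each platform applies its own roughly monotone within-sample response plus
platform-specific noise, and cross-sample normalization destroys exactly
the information a transferable classifier needs. `pairclass` sidesteps the
problem by reducing expression to binary *within-sample orderings*: the
feature "gene A < gene B in this sample" is invariant to every strictly
increasing per-sample transform, so a model trained on array data applies
unchanged to RNA-seq counts.

For an oriented pair (A, B) and a patient cluster C, with `p_in` and
`p_out` the fractions of in- and out-of-cluster samples where A < B:

```
PD    = p_in − p_out                      (proportion difference, ∈ [−1, 1])
score = |PD| · (−1 · Q · R)               (Q, R: mean of A − B inside / outside C)
score = |PD| · |PD_val| · (−1 · Q · R)    (cross-cohort rescoring; 0 if the
                                           two PDs disagree in sign)
```

A high score needs both a near-perfect ordering flip (|PD| → 1) and a large
reversed mean separation (Q and R of opposite sign). Pairs are ranked per
cluster, greedily selected under a 0.85 correlation cap, binarized, and fed
to per-cluster ensembles of 11 binary XGBoost learners (80% stratified
bags, median-aggregated) whose scores a final XGBoost meta-predictor turns
into the "best call" label. The package also ships synthetic cohort /
platform-view / survival / single-cell generators with planted ground
truth, which is how everything is tested. See `docs/methods.md` for the
full model description and `docs/formats.md` for file schemas.

## Worked example

`examples/01_score_and_select_pairs.py` builds a 140-sample cohort in five
clusters (the protective cluster has only 14 samples) with 5 planted pair
reversals per cluster among 300 genes, ranks all pairs and selects a
feature set:

```
Top pairs for the protective cluster fc3 (PD = p_in - p_out):
  PAIR_fc3_04_B < PAIR_fc3_04_A: PD=+1.000 Q=-3.76e+03 R=+7.96e+03 score=3e+07
  PAIR_fc3_00_B < PAIR_fc3_00_A: PD=+1.000 Q=-3.17e+03 R=+1.46e+03 score=4.61e+06
  PAIR_fc3_03_A < PAIR_fc3_03_B: PD=+0.992 Q=-283 R=+266 score=7.46e+04
  ...
Selected 25 pairs over 5 clusters;
recovered 25/25 planted pairs.
```

PD = +1.000 means the ordering flips in every in-cluster sample relative to
the rest; Q and R of opposite sign confirm the mean reversal. The remaining
examples continue the pipeline, each printing what it computes:

- `02_train_and_cross_validate.py` — 10-fold CV with in-fold feature
  selection: overall accuracy 0.986, macro F1 0.988, protective-cluster
  specificity 1.000.
- `03_cross_platform_transfer.py` — train on an array-like view, predict an
  RNA-seq-like view: transfer accuracy 0.950; round-trip back-prediction
  (retrain on the predicted labels, predict back) 0.936.
- `04_survival_stratification.py` — predicted protective cluster reaches
  median survival 988 days vs 179–344 for the others; protective-vs-rest
  log-rank p = 2.3e-05.
- `05_single_cell_localization.py` — the pair reversal between IDH1-mutant
  and wild-type patients is flagged in tumor cells and in no other cell
  type.

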