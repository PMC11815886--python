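# Methods

## The problem

Gene-expression cohorts profiled on different platforms (microarray vs
RNA-seq) are not directly comparable: each platform applies its own,
roughly monotone, within-sample response plus platform-specific noise.
Any feature defined as a *within-sample ordering* of two genes — "gene A is
expressed above gene B in this sample" — is invariant to every strictly
increasing per-sample transform, so a classifier built on such features can
be trained on one platform and applied to another without joint
normalization. `pairclass` implements that idea end to end for multi-class
patient-cluster prediction, with survival stratification and single-cell
localization as downstream checks.

## Pair statistics

For an oriented pair (A, B) and a target cluster C within labeled samples
S (s ∈ C, t ∉ C):

- `p_in = P_{s∈C}[A < B]`, `p_out = P_{t∉C}[A < B]`; the **proportion
  difference** `PD = p_in − p_out ∈ [−1, 1]`. Ties count as *not* A < B,
  which keeps the indicator deterministic on count data and makes PD
  exactly antisymmetric under orientation swap when no ties exist.
- `Q` and `R` are the mean of A − B inside and outside the cluster, on the
  matrix's own scale. They measure the magnitude of the separation; unlike
  PD they are *not* invariant to monotone transforms.
- **Pair score** `|PD| · (−1 · Q · R)`: positive exactly when the mean
  ordering reverses between the cluster and the rest (Q, R of opposite
  sign) and the rank pattern is informative.
- **Cross-cohort score** `|PD| · |PD_val| · (−1 · Q · R)` up-ranks pairs
  whose proportion difference replicates in a second cohort. When the two
  PDs disagree in sign the score is set to 0 rather than scored by
  magnitudes: a direction-discordant pair cannot transfer, and letting two
  negatives multiply into a positive would actively promote it.

Ranking enumerates each unordered pair once per cluster in the canonical
orientation with PD ≥ 0 (larger PD wins under ties, then gene-name order),
drops pairs with PD below `pd_min` (default 0.5), and sorts by score, then
PD, then names — a fully deterministic order.

## Feature selection

Greedy walk down each cluster's ranking. A pair is accepted iff neither
member correlates above `corr_max` (default 0.85, Pearson) with any gene
already selected for that cluster; self-correlation of 1 means no gene is
ever used twice per cluster. Correlation is computed on **log1p-transformed
values**: expression correlation is conventionally assessed on the log
scale, and on a raw exponential scale the sample correlation between
independent genes is dominated by the few most extreme samples (we observed
spurious r > 0.9 between unrelated genes, which silently rejects good
pairs). Cross-platform refinement drops pairs whose genes have Spearman
correlation below `corr_min` across matched samples of two platform views —
rank correlation because the platforms differ by monotone distortion.

## The ensemble

Expression is binarized into pair features (`cluster:geneA<geneB`, 1 iff
A < B, ties 0), pooled across all clusters' pair lists. Per cluster, a
stack of `ensemble_size` (default 11) binary XGBoost learners is trained
one-vs-rest, each on an independent stratified random 80% subsample
(stratification guarantees ≥ 1 positive even for a 14-sample cluster —
unstratified 80% bags can lose a tiny class entirely). The per-cluster
score is the **median** of the stack's probabilities; a final multi-class
XGBoost learner maps the vector of per-cluster median scores to the best
call. Ties in the final probabilities break by higher median score, then
label order. Defaults: depth 12, eta 0.3, 50 rounds, L2 = 1, L1 = 0;
ensemble size and depth are the tuned values for the unbalanced
five-cluster setting, the rest are conventional and exposed to
`grid_search` (exhaustive, macro-F1 objective, ties to the simpler model).
Every learner's seed derives from the base seed via
`SeedSequence([seed, cluster_index, member_index])`, so training is
reproducible to the bit with one thread.

Cross-validation is stratified k-fold (default 10); with a
`SelectionConfig`, ranking *and* selection re-run inside each training
fold, so held-out samples never influence the features — on pure-noise
cohorts this yields chance-level macro F1, which the tests assert.
`feature_importance` reports each feature's median total split gain across
the stack (gain units are the boosting library's own).

## Experiment designs

- **Transfer**: train on one platform view, predict another; report
  attached when target labels are known, survival summary when outcomes are
  supplied.
- **Round trip**: predict labels on an unlabeled cohort, retrain from
  scratch on those predicted labels, predict back onto the original cohort
  and score against its known labels. Clusters that receive no predictions
  are dropped from the stage-2 model with a warning.
- **Aggregation**: per dataset, select features, train, and take the top
  `top_n` pairs per cluster by median gain, restricted to the cluster's own
  pair features (a cluster's binary model may also split on other clusters'
  features; the published aggregated tables are organized per cluster, so
  the informative lists are too). Pairs are identified by cluster +
  unordered gene pair; those appearing in ≥ `min_datasets` datasets *and*
  in the reference dataset's lists are kept, with orientation taken from
  the reference.

## Synthetic cohorts

`generate_cohort` plants, per cluster, `pairs_per_cluster` gene pairs whose
log-scale mean difference is `+effect_size · noise_sd` inside the cluster
and the negative outside (direction randomized), on top of i.i.d. Gaussian
log-noise (`noise_sd`) and a log-normal background (gene means ~ N(4, 1)).
`effect_size` is therefore a signal-to-noise ratio: at 4, a planted pair's
per-sample ordering is correct with probability Φ(4/√2) ≈ 0.998 and its PD
is ≈ 1 even in a 14-sample cluster.

The two members of a planted pair additionally share a per-sample log-level
(uniform, sd `pair_level_sd` = 10 · noise_sd by default). This models
co-regulation of the two signature genes and is load-bearing: the shared
level cancels inside the pair (the reversal stays crisp) but decorrelates
the ranks of genes from *different* pairs, so cross-combinations of
signature genes — or a signature gene against an intermediate-level
background gene — are not themselves strong rank features. Without it,
planted-signal "recovery" is ill-posed, because the generator would create
many informative pairs it did not nominate. The level is uniform rather
than Gaussian so linear-scale means (which enter Q·R) stay within a
realistic dynamic range (~4 orders of magnitude at the defaults).

`platform_distort` first applies an independent strictly increasing
transform per sample (`scale · x^γ`, γ ∈ [0.7, 1.3]) — at strength 0 this
is the whole distortion and every ordering is preserved exactly. Strength
then scales platform-flavored noise: *array_like* compresses and perturbs
values below the within-sample 20% quantile (background noise at the low
end of the dynamic range) and softly saturates above the 98% quantile;
*rnaseq_like* resamples counts from a gamma-Poisson with dispersion
10/strength, per-sample proportionality anchored so the median gene
receives ~200 expected counts (a total-depth anchor lets a few giant genes
starve the rest to zeros, erasing orderings; anchoring the median keeps the
mid-range informative, which is where selected signature genes live).

Survival times are exponential with a cluster hazard (defaults: protective
1/1500 per day ≈ 1040-day median, others 1/350 ≈ 243 days), censored by an
independent uniform draw on (0, horizon], horizon 2500 days (~20–30%
censoring). `generate_single_cell` draws zero-inflated gamma-Poisson
counts; the planted pair's median ordering flips between condition groups
only in the designated cell type, distractor genes are broadly expressed in
the other cell types.

What the generators do **not** emulate: probe-level effects, GC/length
bias, batch structure, correlated gene networks beyond the within-pair
level, non-exponential hazards, informative censoring, or realistic
single-cell library-size variation. Passing tests demonstrate the
pipeline's statistical machinery and its platform invariance under the
stated model, not performance on any real cohort.

## Study conditions used by the tests and the acceptance script

- Cohorts of 140 samples in clusters 30/30/14/33/33 (the protective
  cluster is the 14-sample one), 500 genes, 10 planted pairs per cluster,
  `noise_sd` 0.25, effect size 4 — the strong-signal regime; effect ~1e-6
  serves as the no-signal control.
- Cross-validation: 10-fold, in-fold selection, default model parameters;
  3 strong-signal and 2 no-signal seeds (script: 2 and 1).
- Transfer/round-trip: array-like and RNA-seq-like views at strength 1,
  5 seeds (script: 3). Within-platform accuracy is measured against an
  independent second array-like draw, not training-set self-prediction.
- Aggregation: balanced 5 × 28 cohort, 8 shared pairs per cluster, 4 views
  that are monotone re-renderings plus 2 view-specific planted pairs per
  cluster, selection with `pd_min` 0.65 (between planted PDs ≈ 1 and the
  ≲ 0.6 PDs that cross-combinations of signature genes can reach through
  sampling noise), `top_n` 10, `min_datasets` 3. This isolates the
  cross-dataset replication logic from the small-cluster sampling effects
  exercised elsewhere.
- Survival: null calibration with two identical exponential groups of 200
  (500 simulations in tests, 300 in the script); power at hazard ratio 0.3
  with 150 + 150 subjects and ~30% censoring (100 simulations).
- Single cell: 1000 cells over four cell types, pattern planted in tumor
  cells, support floor 10% expressing.

These sizes keep the full suite and the acceptance script at desk scale
while leaving the assertions' margins wide.

## Numerical and degenerate-input choices

- All randomness flows through `numpy` `Generator`/`SeedSequence`; any
  derived seed is reduced mod 2³¹.
- Writers print floats with `%.12g`; round-trips are exact to 1e-9.
- Missing values in expression input are an error, never imputed; duplicate
  symbols after alias mapping keep the highest-mean row (logged); aliases
  mapping to `unknown` drop the row (logged). Alias maps must be idempotent
  and are validated as such.
- Missing feature genes at prediction time: error by default; `"drop"`
  removes the pair everywhere but refuses if > 25% of any cluster's pairs
  would vanish.
- An empty feature matrix (no pair survives selection, as happens on pure
  noise) trains a majority-label fallback rather than failing, so
  chance-level CV remains measurable.
- Log-rank p-values use the chi-square approximation; an exact 0 from the
  tail is reported as the smallest positive float so p ∈ (0, 1].

## Known limitations

- Full pair enumeration is O(G²·S); above 2000 genes `rank_pairs` falls
  back to the top-2000 by variance unless a candidate list is given.
- Q and R (and hence scores) are scale-dependent by design; scores from
  matrices on different scales are not comparable — only the rank order
  within one dataset is used.
- The chi-square log-rank approximation is inaccurate for very small
  groups; no permutation option is provided.
- The final meta-predictor sees only per-cluster median scores, so its
  probabilities are not calibrated class posteriors.
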