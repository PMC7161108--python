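# Methods

This note documents the models and procedures implemented in `pathme`, the
numerical choices behind them, and what the synthetic benchmark does and
does not establish.

## Problem setting

Multi-omics studies measure the same patients on several molecular layers
(mRNA expression, miRNA expression, DNA methylation, copy number), each
with its own dimensionality and numeric range. `pathme` compresses all
features that map to one biological pathway — across every layer — into a
single per-patient *pathway score*, then bi-clusters the resulting
pathways x patients score matrix to find molecular subgroups together with
the pathways that characterize them.

## Feature-to-pathway mapping

Gene sets come from GMT files; features are joined to genes through
modality-specific annotations (identity for gene-level modalities such as
expression and CNV; explicit feature-to-gene tables for CpGs and miRNAs,
where one feature may map to several genes and vice versa). Patients are
harmonized by intersection across modalities and ordered lexicographically,
as are features within a view, so mapping is deterministic. A modality
contributing fewer than `min_features_per_modality` (default 1) features
to a pathway is dropped from that pathway's view; pathways with no
remaining modality are omitted. Features in several pathways appear in
every matching view — pathways are modeled independently.

## Pathway scoring: multi-modal sparse denoising autoencoder

For one pathway with modality blocks x_1..x_k (p_j features each, n
patients), the encoder maps each modality *separately* to at most
floor(p_j/2) first-hidden units (h_j is a tuned hyper-parameter; there are
no cross-modality input connections), then all first-hidden units to a
single shared bottleneck unit whose tanh activation is the pathway score.
The decoder mirrors the encoder laterally. All activations are tanh.

* **Standardization.** Inputs are per-feature z-scores of the training
  data; reconstructions are reported back in original units through the
  inverse transform. This puts modalities with very different native
  ranges (log-expression vs methylation betas) on one loss scale.
* **Batch normalization** is applied to the pre-activations of both hidden
  layers (training-mode batch statistics; running statistics with momentum
  0.9 at evaluation).
* **Loss.** sigma(W) = (1/n) sum_j sum_i || x_j^(i) - reconstruction ||^2
  on the standardized scale. The training objective is
  F(W) = sigma(W)/2 + penalty(W).
* **Sparse group lasso penalty.**
  penalty = (lambda/2) [ (1-alpha) sum_j sqrt(p_j h_j) sum (W_ij)^2
  + alpha sum |W_ij| ], where the first (group) sum runs over the k
  modality-specific input weight blocks — selecting entire omics
  modalities — and the l1 sum over all encoder and decoder weight
  matrices — selecting individual features. Note the group term is a
  dimension-weighted ridge as printed in the source formulation, not the
  sqrt-of-sum group-lasso norm. alpha=1 recovers the lasso, alpha=0 the
  group penalty. Biases and batch-norm parameters are unpenalized.
* **Denoising.** Each mini-batch's inputs are corrupted by independent
  feature dropout with retention probability p in [0.5, 1] (dropped
  features sit at the standardized zero, i.e. the feature mean);
  reconstruction targets stay clean. p is read as a *keep* probability:
  the stated range [0.5, 1] matches keep-probability conventions, and a
  drop probability of 1 would erase the input entirely.
* **Optimization.** Mini-batch stochastic gradient descent with
  hand-derived analytic gradients (verified against central finite
  differences to <1e-4 relative error, batch-norm included); momentum,
  RMSProp, Adam and Nadam are available, Adam is the default. Training
  monitors the full-data objective and stops after 20 epochs without a
  relative improvement of at least 1e-6, restoring the best weights.
  A non-finite objective aborts with the offending epoch. Weight
  initialization is symmetric uniform with fan-in scaling from the run
  seed; everything is deterministic given the seed.
* **Hyper-parameter search.** Seeded random search (50 draws by default)
  over mini-batch size {4,8,16,32}, lambda in [1e-9,1e-1] (log-uniform),
  alpha in [0,1], learning rate in [1e-5,1e-1] (log-uniform), retention
  p in [0.5,1] and per-modality hidden sizes in [1, floor(p_j/2)]; each
  draw is scored by mean held-out sigma over 5-fold cross-validation
  with seed-fixed splits. Random search was chosen over a model-based
  (Bayesian) optimizer: the 6-dimensional space is small, the objective
  is noisy, and random search keeps the dependency footprint minimal
  while remaining fully reproducible.

Scores of all pathways are stacked into a P x n matrix. tanh scores are
signed, so each row is independently min-max rescaled to [0,1] (constant
rows map to 0.5) to satisfy the factorization's non-negativity constraint;
a +1 shift was rejected because it compresses dynamic range non-uniformly
across pathways.

## Bi-clustering: consensus sparse NMF

The score matrix X (P x n, X >= 0) is factorized as X ~ B H, B >= 0
(P x m), H >= 0 (m x n), minimizing

    1/2 { ||X - BH||_F^2 + eta ||B||_F^2 + beta sum_j ||H(:,j)||_1^2 }

with eta = max(X) by default and beta tuned in [0.001, 1]. Both
subproblems are exact non-negative least squares on augmented systems
(the squared-l1 column penalty is absorbed by stacking a sqrt(beta) row of
ones under B; the ridge by sqrt(eta) I under H'), solved by block
principal pivoting vectorized over right-hand sides with warm-started
active sets (JIT-compiled; a pure-numpy reference path exists). Because
every subproblem is solved exactly, the objective is monotonically
non-increasing; iteration stops at 1e-6 relative change (default) or
`max_iter`. Patients are assigned to the row of H with their largest
coefficient (ties to the lowest row; all-zero columns to row 1 with a
warning).

**Consensus.** The factorization is restarted `runs` times (500 by
default; per-run seeds derive from the master seed) from random uniform
initializations; C(i,j) is the fraction of runs co-clustering patients i
and j. Final labels cut the average-linkage dendrogram of 1-C at m
clusters. Cluster quality is recorded as (a) the cophenetic correlation
between 1-C and the dendrogram's cophenetic distances, (b) the silhouette
of the final labels under distance 1-C ("consensus silhouette"), and
(c) the silhouette of the best (lowest-objective) single run under
Euclidean distance on score columns ("best-run silhouette") — the source
work reports both silhouettes without defining the distances, so both
conventions are computed and labeled.

**Rank selection.** For each candidate m in 2..9 (at its best beta by
cophenetic correlation) the data cophenetic is compared against
copheneties of `n_perm` (40 by default) matrices permuted independently
within rows (each pathway's score distribution is preserved, patient
co-structure destroyed); m* is the smallest rank whose data value
strictly exceeds the upper bound of the 95% confidence interval of the
*mean* null cophenetic, mean + 1.96 sd / sqrt(n_perm). Two properties of
this construction matter and are deliberate:

* because the alternating solver descends exactly, consensus restarts on
  strongly structured data collapse to very few basins and the data
  cophenetic saturates at 1.0 — at the true rank but also below it. The
  decision therefore rests on the null: within-row permutation keeps each
  driver row bimodal, so the null *also* saturates at small ranks, and a
  rank whose null reaches 1 cannot be certified (strict exceedance
  fails). At ranks where spurious stability would need several permuted
  rows to agree, the null mean drops clearly below 1 and the true rank
  qualifies;
* the CI of the mean is used rather than a spread band over the raw
  values (mean + 1.96 sd routinely exceeds 1, which the data cophenetic —
  capped at 1 — could never beat) and rather than an empirical 95%
  quantile (with few permutations that quantile is the sample maximum,
  making the decision knife-edged on single permutations touching 1.0).

When no rank qualifies the selection is flagged unresolved (the pipeline
then falls back to the rank with the best cophenetic, with a warning).
Two boundary behaviors follow from the construction and are documented
rather than hidden: a genuine 2-cluster structure whose null saturates at
the smallest candidate rank cannot be certified (the selection skips it
or stays unresolved), and a pure-noise matrix presented as real data can
marginally exceed the tight CI-of-mean bound at some rank — the
procedure finds the smallest stable rank of structured data; it is not a
global test for the presence of structure.  On very cleanly separated
data the consensus is perfectly stable even below the true rank (merging
two true clusters is reproducible across restarts), so the decision at
sub-true ranks rests entirely on the null's saturation and can
occasionally certify the coarser clustering — which is, strictly, also a
significant structure of such data.

**Cluster-descriptive pathways.** Per basis component, column values are
sorted by decreasing magnitude and the prefix ending at the largest drop
between consecutive sorted values is reported (at least one pathway; a
constant column is flagged non-discriminative, an all-zero column returns
the empty list).

## Interpretation: Shapley attribution

The pathway score f(x) of a trained model is attributed to input features
by Shapley values with the background-replacement convention: absent
features take the per-feature training mean (configurable to a reference
sample). `exact_shapley` enumerates all subsets (guarded to <= 15
features) with weights |S|!(|F|-|S|-1)!/|F|!. `approx_shapley` samples
feature orderings (200 by default, seeded) and accumulates marginal
contributions; the telescoping sum makes the efficiency identity
sum(phi) = f(x) - f(background) exact for any sample count, and on small
models the estimate correlates >= 0.95 with exact enumeration. Feature
relevance is summarized as the mean absolute Shapley value per feature,
and modality relevance as the mean over all the modality's per-patient
absolute values; both are reported descending.

## Post-hoc statistics

* **Mutational burden**: per patient, the fraction of a pathway's covered
  genes with any somatic mutation; Kruskal-Wallis (with tie correction)
  across clusters, BH-corrected over pathways as one family.
* **Survival**: if age is nominally significant (p < 0.05, a configurable
  threshold) in an age-only Cox model, the cluster effect is a
  likelihood-ratio test of {cluster+age} vs {age}; otherwise a log-rank
  test. The method tag records the branch.
* **Other clinical variables**: chi-squared for categoricals (singleton
  levels pooled into "other"), one-way ANOVA for numerics; BH over the
  table as one family. Families are kept per analysis type, not pooled
  across endpoints.

## Synthetic benchmark

The generator plants m_true patient clusters (largest-remainder sizes
from mixing proportions) expressed through *cluster-specific pathway
activity*: each informative pathway is assigned one driving cluster
(round-robin) and its driver features (a configurable fraction) are
shifted upward by `effect_size x noise_sd` for that cluster's patients
only. Non-informative pathways are pure noise. The three default
modalities land on deliberately different scales (location/scale 8/2,
4/0.5, and a probit-squashed methylation-like layer bounded in (0,1)) to
exercise the standardization path. Mutations are Bernoulli with planted
(cluster, pathway) enrichment; survival times are exponential with
per-cluster hazard ratios and independent exponential censoring whose
rate is solved numerically for the target expected censoring fraction;
age, gender and a noisy cluster-correlated subtype column round out the
clinical table.

Defaults: n=150 patients, m_true=3 equal clusters, P=20 pathways of which
6 are informative, 30/15/30 features per pathway per modality, effect
size 4, driver fraction 0.5, hazard ratios (1, 2, 3), 30% censoring.
Six informative pathways give each of the three clusters exactly two
driving pathways; an unbalanced count would leave one cluster
under-driven, making the sub-rank merge deterministic and rank selection
degenerate at m=2 regardless of the null.

What passing on this generator shows: the end-to-end machinery recovers
strong planted structure, and each statistic matches its independent
oracle. What it does not show: performance under realistic omics
marginals, batch effects, correlated features within pathways, missing
data, or weak effect sizes — none of which the generator emulates.

## Reduced computational profile

Library defaults follow the published protocol (hyper-parameter budget 50
with 5-fold CV, 500 consensus restarts, 40 permutations, ranks 2..9,
beta grid [0.001, 1]). The test suite and the acceptance script use
`RunConfig.fast_profile` — budget 10, 50 restarts, 10 permutations,
ranks 2..6, beta 0.01, 60-80 training epochs — sized so a complete run
fits on a single desk-scale CPU; these change only computational effort,
not the data or the model.

## Known limitations

* tanh output units cannot reconstruct standardized targets beyond
  (-1, 1); extreme z-scores are clipped by saturation. This is inherited
  from the all-tanh architecture.
* The l1 term of the penalty is applied to all weight matrices; the
  source formulation's layer index range is ambiguous and the
  alternative (input layers only) is not implemented.
* With batch statistics at mini-batch size 4, batch normalization is
  noisy; the tuner may prefer larger batches on small cohorts.
* Batch normalization partially neutralizes the group penalty: the
  unpenalized scale parameter can restore a hidden unit's pre-activation
  variance after its input weights shrink, so whole-modality selection
  through the group term is only cleanly observable with batch
  normalization disabled (the sparsity diagnostics do exactly that).
* Exact Shapley is exponential and guarded at 15 features; attribution of
  the sNMF stage is out of scope.
* The multiplicative-update solver family is not implemented; the ANLS
  solver's exact subproblem solutions make consensus restarts converge to
  very few basins, which is precisely why the rank-selection null and
  bound construction above were chosen with care.
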