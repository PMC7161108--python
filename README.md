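# pathme

Pathway-level integration and clustering of multi-omics cancer cohorts.

Omics studies of the same patients routinely span several molecular
layers — mRNA and miRNA expression, DNA methylation, copy number — whose
dimensionalities and numeric ranges differ by orders of magnitude.
`pathme` reduces this to an interpretable common currency: for every
biological pathway it compresses all features of all modalities mapping
to that pathway into a single per-patient **pathway score**, learned by a
multi-modal sparse denoising autoencoder. The resulting pathways x
patients score matrix is then **bi-clustered** by consensus sparse
non-negative matrix factorization, yielding patient subgroups together
with the pathways that characterize each subgroup, and the scores are
**explained** feature-by-feature with Shapley values and post-hoc
statistics (mutational burden, survival, clinical associations).

It is aimed at computational biologists who have per-modality feature
tables, gene sets (GMT) and feature-to-gene annotations, and want
molecular subgroups that come with a pathway-level explanation.

## Method in brief

**Scoring.** For a pathway with modality blocks x_1, ..., x_k (p_j
features, n patients), each modality is encoded separately into at most
⌊p_j/2⌋ hidden units (no cross-modality input connections), then all
hidden units into one shared tanh bottleneck — the pathway score.  The
decoder mirrors the encoder.  Training minimizes

    F(W) = ½·σ(W) + (λ/2)·[ (1−α) Σ_j √(p_j h_j) Σ (W_ij)²  +  α Σ |W_ij| ]

where σ(W) = (1/n) Σ_j Σ_i ‖x_j^(i) − x̂_j^(i)‖² is the summed
per-modality reconstruction error (on per-feature standardized data) and
the penalty is a sparse group lasso: the group term selects whole omics
modalities, the l1 term individual features.  Inputs are corrupted by
feature dropout with retention probability p (denoising); batch
normalization, early stopping, and a choice of momentum / RMSProp / Adam
/ Nadam round out training.  Hyper-parameters (λ, α, learning rate, p,
batch size, hidden widths) are tuned by seeded random search under
5-fold cross-validated reconstruction error.

**Bi-clustering.** Scores are min-max rescaled per pathway to [0,1] and
factorized as X ≈ BH (B, H ≥ 0) under

    min ½( ‖X − BH‖²_F + η‖B‖²_F + β Σ_j ‖H(:,j)‖₁² ),   η = max(X)

by alternating exact non-negative least squares (block principal
pivoting), so the objective descends monotonically.  Consensus over
hundreds of random restarts gives a co-clustering matrix; its
average-linkage dendrogram yields the final labels, and the cophenetic
correlation — compared against a within-row permutation null — selects
the number of clusters.  Each cluster's descriptive pathways are the
leading sorted prefix of its basis column (largest-gap rule).

**Interpretation.** Shapley values attribute each patient's pathway
score to individual features (exact subset enumeration for small
pathways, seeded permutation sampling otherwise), aggregated as mean
|φ| per feature and per modality.  Clusters are characterized by
Kruskal–Wallis tests on pathway mutational burden, Cox/log-rank survival
tests (age-corrected when age is prognostic), and χ²/ANOVA clinical
associations, all with Benjamini–Hochberg correction.

## Worked example

A reduced-size synthetic cohort with three planted patient clusters
expressed through cluster-specific pathway activity (the generator is
part of the package — no downloads needed):

```python
import os, tempfile
from pathme.simulate import SyntheticConfig, ModalitySpec, generate, write_fixture
from pathme.pipeline import RunConfig, run_pipeline
from pathme.snmf import adjusted_rand_index

ds = generate(SyntheticConfig(
    n=90, m_true=3, n_pathways=10, n_informative=6, genes_per_pathway=12,
    modalities=[ModalitySpec("mrna", 12, location=8.0, scale=2.0),
                ModalitySpec("meth", 10, gene_level=False, bounded=True)],
    seed=7))
work = tempfile.mkdtemp()
paths = write_fixture(ds, os.path.join(work, "fixture"))
cfg = RunConfig.fast_profile(
    out_dir=os.path.join(work, "out"),
    gmt=paths["gmt"],
    omics={"mrna": paths["omics_mrna"], "meth": paths["omics_meth"]},
    maps={"meth": paths["map_meth"]},
    mutations=paths["mutations"], clinical=paths["clinical"],
    budget=5, folds=3, max_epochs=50, runs=30, n_perm=8, ranks=[2, 3, 4, 5],
    seed=1)
bundle = run_pipeline(cfg)
print("clusters used:", bundle.rank_selection["used_rank"])
print("cophenetic:", round(bundle.rank_selection["cophenetic"], 3))
print("ARI vs planted labels:",
      round(adjusted_rand_index(bundle.labels.to_numpy(), ds.labels), 3))
```

prints (about two minutes on one CPU):

```
clusters used: 4
cophenetic: 1.0
ARI vs planted labels: 0.983
```

The consensus is perfectly stable (cophenetic correlation 1.0) and the
recovered partition matches the planted one almost exactly (adjusted
Rand index 0.983: at this reduced size the permutation test certifies
one extra split, dividing a planted cluster in two without mixing
clusters).  The Shapley summary for the first driver pathway ranks
methylation as the most influential modality for its score:

```python
pw, att = sorted(bundle.attributions.items())[0]
att["per_modality"]        # [('meth', 0.0037), ('mrna', 0.002)]
```

and the clusters differ in overall survival (log-rank p = 0.017), driven
by the generator's planted per-cluster hazard ratios.

The same pipeline is available from the shell:

```bash
pathme simulate --out fixture --seed 7 --n 90
pathme run --config run.yaml          # paths + stage parameters in YAML
```

with intermediate commands (`pathme map / train / score / cluster /
explain / stats`) for stage-by-stage runs; every stage caches its outputs
under the run directory and re-uses them when inputs are unchanged.

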