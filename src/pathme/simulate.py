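"""Synthetic multi-omics datasets with planted patient clusters.

The generator emulates the structure the pipeline assumes: k omics
modalities whose features map (directly or through annotation tables) to
genes grouped into pathways, with a subset of "informative" pathways whose
driver features carry cluster-specific mean shifts across all modalities.
Matching mutation and clinical tables plant cluster-specific mutational
enrichment and hazard ratios, so every downstream analysis has a known
ground truth.  Modality value ranges are deliberately heterogeneous (and
the methylation-like modality is probit-squashed into (0, 1)) to exercise
the standardization path.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .mapping import (FeatureGeneMap, OmicsBlock, PathwayDefinition,
                      identity_feature_gene_map, load_feature_gene_map,
                      load_gene_sets, load_omics_table)

__all__ = ["ModalitySpec", "SyntheticConfig", "SyntheticDataset",
           "generate", "write_fixture", "load_fixture"]


@dataclass
class ModalitySpec:
    """One simulated omics modality.

    ``location``/``scale`` set the modality-native numeric range (so the
    modalities land on very different scales); ``noise_sd`` is the
    within-cluster standard deviation on the latent scale that cluster
    shifts are expressed in; ``gene_level`` modalities use feature IDs that
    are gene IDs (identity annotation), others get an explicit feature ->
    gene table; ``bounded`` squashes latent values through a probit link
    into (0, 1), methylation-beta style.
    """

    name: str
    features_per_pathway: int
    noise_sd: float = 1.0
    location: float = 0.0
    scale: float = 1.0
    gene_level: bool = True
    genes_per_feature: int = 1
    bounded: bool = False


def _default_modalities() -> list[ModalitySpec]:
    return [
        ModalitySpec("mrna", 30, noise_sd=1.0, location=8.0, scale=2.0,
                     gene_level=True),
        ModalitySpec("mirna", 15, noise_sd=1.0, location=4.0, scale=0.5,
                     gene_level=False, genes_per_feature=2),
        ModalitySpec("meth", 30, noise_sd=1.0, location=0.0, scale=1.0,
                     gene_level=False, bounded=True),
    ]


@dataclass
class SyntheticConfig:
    n: int = 150
    m_true: int = 3
    proportions: list[float] | None = None
    n_pathways: int = 20
    n_informative: int = 6
    genes_per_pathway: int = 30
    modalities: list[ModalitySpec] = field(default_factory=_default_modalities)
    effect_size: float = 4.0        # cluster mean shift in units of noise_sd
    driver_fraction: float = 0.5    # fraction of driver features per informative pathway
    hazard_ratios: list[float] | None = None   # per cluster, first = reference
    baseline_median_days: float = 1000.0
    censoring_fraction: float = 0.3
    mutation_rate: float = 0.05
    mutation_enriched_rate: float = 0.4
    # (cluster label, pathway index) pairs carrying mutation enrichment
    enriched: list[tuple[int, int]] = field(default_factory=lambda: [(1, 0)])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportions is None:
            self.proportions = [1.0 / self.m_true] * self.m_true
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if len(self.proportions) != self.m_true:
            raise ValueError("one proportion per cluster required")
        if self.n_informative > self.n_pathways:
            raise ValueError("n_informative exceeds n_pathways")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not 0 < self.driver_fraction <= 1:
            raise ValueError("driver_fraction must be in (0, 1]")
        for spec in self.modalities:
            if int(round(spec.features_per_pathway * self.driver_fraction)) < 1:
                raise ValueError(
                    f"modality '{spec.name}': fewer than one driver feature")
        if self.hazard_ratios is None:
            self.hazard_ratios = [1.0 + 1.0 * c for c in range(self.m_true)]
        if len(self.hazard_ratios) != self.m_true:
            raise ValueError("one hazard ratio per cluster required")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    blocks: list[OmicsBlock]
    gene_sets: list[PathwayDefinition]
    maps: list[FeatureGeneMap]
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    labels: np.ndarray  # 1-based cluster per patient, aligned to patients
    patients: list[str]


def _cluster_sizes(n: int, proportions: list[float]) -> list[int]:
    """Largest-remainder apportionment: deterministic, sums to n."""
    raw = [p * n for p in proportions]
    sizes = [int(np.floor(r)) for r in raw]
    rema = np.argsort([s - r for s, r in zip(sizes, raw)])
    for i in range(n - sum(sizes)):
        sizes[rema[i]] += 1
    return sizes


def _censoring_rate(event_rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving the target expected censoring
    fraction under per-patient exponential event rates."""
    def frac(mu):
        return float(np.mean(mu / (event_rates + mu))) - target
    return brentq(frac, 1e-12, 1e6)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset: omics blocks, gene sets, annotations, mutations,
    clinical table and true labels."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    patients = [f"PT{i:04d}" for i in range(cfg.n)]

    sizes = _cluster_sizes(cfg.n, cfg.proportions)
    labels = np.concatenate([np.full(s, c + 1) for c, s in enumerate(sizes)])
    labels = labels[rng.permutation(cfg.n)]

    # pathway gene sets
    gene_sets = []
    pathway_genes: list[list[str]] = []
    for p in range(cfg.n_pathways):
        genes = [f"G{p:02d}_{g:03d}" for g in range(cfg.genes_per_pathway)]
        pathway_genes.append(genes)
        gene_sets.append(PathwayDefinition(f"PW{p:02d}", frozenset(genes)))

    # cluster-specific pathway activity: informative pathway p is "active"
    # (driver features shifted up) in exactly one cluster, round-robin
    driving_cluster = {p: (p % cfg.m_true) + 1 for p in range(cfg.n_informative)}

    blocks: list[OmicsBlock] = []
    maps: list[FeatureGeneMap] = []
    for spec in cfg.modalities:
        feats: list[str] = []
        pairs: list[tuple[str, str]] = []
        latent_cols = []
        n_driver = int(round(spec.features_per_pathway * cfg.driver_fraction))
        for p in range(cfg.n_pathways):
            informative = p < cfg.n_informative
            for fi in range(spec.features_per_pathway):
                if spec.gene_level:
                    fid = pathway_genes[p][fi % cfg.genes_per_pathway]
                else:
                    fid = f"{spec.name}_{p:02d}_{fi:03d}"
                    for gk in range(spec.genes_per_feature):
                        gene = pathway_genes[p][(fi + gk) % cfg.genes_per_pathway]
                        pairs.append((fid, gene))
                feats.append(fid)
                shift = np.zeros(cfg.n)
                if informative and fi < n_driver:
                    shift[labels == driving_cluster[p]] = \
                        cfg.effect_size * spec.noise_sd
                latent = shift + rng.normal(0.0, spec.noise_sd, size=cfg.n)
                latent_cols.append(latent)
        latent_mat = np.column_stack(latent_cols)
        if spec.bounded:
            values = norm.cdf(latent_mat)  # methylation-beta style in (0, 1)
        else:
            values = spec.location + spec.scale * latent_mat
        blocks.append(OmicsBlock(spec.name, list(patients), feats, values))
        if spec.gene_level:
            maps.append(identity_feature_gene_map(blocks[-1]))
        else:
            maps.append(FeatureGeneMap(spec.name, pairs))

    # mutations: Bernoulli background, enriched in (cluster, pathway) pairs
    all_genes = [g for genes in pathway_genes for g in genes]
    prob = np.full((cfg.n, len(all_genes)), cfg.mutation_rate)
    for cluster, p_idx in cfg.enriched:
        cols = [all_genes.index(g) for g in pathway_genes[p_idx]]
        prob[np.ix_(labels == cluster, cols)] = cfg.mutation_enriched_rate
    mutations = pd.DataFrame((rng.random(prob.shape) < prob).astype(int),
                             index=patients, columns=all_genes)
    mutations.index.name = "patient"

    # clinical: survival with planted per-cluster hazards + covariates
    base_rate = np.log(2) / cfg.baseline_median_days
    event_rates = base_rate * np.asarray(cfg.hazard_ratios)[labels - 1]
    cens_rate = _censoring_rate(event_rates, cfg.censoring_fraction)
    clinical = pd.DataFrame(index=pd.Index(patients, name="patient"))
    clinical["age"] = np.round(rng.normal(60.0, 10.0, size=cfg.n), 1)
    clinical["gender"] = rng.choice(["female", "male"], size=cfg.n)
    clinical["biomarker"] = np.round(rng.normal(0.0, 1.0, size=cfg.n), 4)
    # a molecular-classification column correlated with the true clusters
    noisy = labels.copy()
    flip = rng.random(cfg.n) < 0.1
    noisy[flip] = rng.integers(1, cfg.m_true + 1, size=int(flip.sum()))
    clinical["subtype"] = [f"subtype_{c}" for c in noisy]
    for endpoint in ("os", "pfs"):
        t_event = rng.exponential(1.0 / event_rates)
        t_cens = rng.exponential(1.0 / cens_rate, size=cfg.n)
        clinical[f"{endpoint}_time"] = np.round(np.minimum(t_event, t_cens), 2)
        clinical[f"{endpoint}_event"] = (t_event <= t_cens).astype(int)

    return SyntheticDataset(cfg, blocks, gene_sets, maps, mutations,
                            clinical, labels, list(patients))


def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, str]:
    """Write every interchange file the CLI consumes (TSV/GMT dialects).

    True labels go to a separate ``truth_labels.tsv`` that no pipeline
    stage reads — they exist only for evaluation.
    """
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}

    for block in dataset.blocks:
        p = os.path.join(directory, f"omics_{block.modality_name}.tsv")
        pd.DataFrame(block.values, index=pd.Index(block.patients, name="patient"),
                     columns=block.features).to_csv(p, sep="\t")
        paths[f"omics_{block.modality_name}"] = p

    p = os.path.join(directory, "pathways.gmt")
    with open(p, "w") as fh:
        for pw in dataset.gene_sets:
            fh.write("\t".join([pw.pathway_id, "synthetic pathway",
                                *sorted(pw.gene_ids)]) + "\n")
    paths["gmt"] = p

    gene_level = {b.modality_name for b in dataset.blocks} & {
        s.name for s in dataset.config.modalities if s.gene_level}
    for fmap in dataset.maps:
        if fmap.modality_name in gene_level:
            continue  # identity map regenerated on load
        p = os.path.join(directory, f"map_{fmap.modality_name}.tsv")
        fmap.as_frame().to_csv(p, sep="\t", index=False)
        paths[f"map_{fmap.modality_name}"] = p

    p = os.path.join(directory, "mutations.tsv")
    dataset.mutations.to_csv(p, sep="\t")
    paths["mutations"] = p

    p = os.path.join(directory, "clinical.tsv")
    dataset.clinical.to_csv(p, sep="\t")
    paths["clinical"] = p

    p = os.path.join(directory, "truth_labels.tsv")
    pd.DataFrame({"patient": dataset.patients,
                  "cluster": dataset.labels}).to_csv(p, sep="\t", index=False)
    paths["truth_labels"] = p
    return paths


def load_fixture(directory) -> dict:
    """Reload a written fixture (used by round-trip tests and the CLI)."""
    out: dict = {"blocks": [], "maps": []}
    for fname in sorted(os.listdir(directory)):
        full = os.path.join(directory, fname)
        if fname.startswith("omics_") and fname.endswith(".tsv"):
            name = fname[len("omics_"):-len(".tsv")]
            out["blocks"].append(load_omics_table(full, name))
        elif fname.startswith("map_") and fname.endswith(".tsv"):
            name = fname[len("map_"):-len(".tsv")]
            out["maps"].append(load_feature_gene_map(full, name))
    mapped = {m.modality_name for m in out["maps"]}
    for block in out["blocks"]:
        if block.modality_name not in mapped:
            out["maps"].append(identity_feature_gene_map(block))
    out["gene_sets"] = load_gene_sets(os.path.join(directory, "pathways.gmt"))
    out["mutations"] = pd.read_csv(os.path.join(directory, "mutations.tsv"),
                                   sep="\t", index_col=0)
    out["clinical"] = pd.read_csv(os.path.join(directory, "clinical.tsv"),
                                  sep="\t", index_col=0)
    truth = os.path.join(directory, "truth_labels.tsv")
    if os.path.exists(truth):
        out["truth_labels"] = pd.read_csv(truth, sep="\t", index_col=0)["cluster"]
    return out
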