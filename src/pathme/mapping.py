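"""Mapping of omics features to pathways.

Each omics modality (mRNA, miRNA, CNV, DNA methylation, ...) arrives as a
patients x features matrix.  Features are linked to genes through a
modality-specific annotation (gene-level modalities use the identity map;
CpGs and miRNAs need explicit feature->gene tables), and genes to pathways
through gene sets in GMT format.  The product of this module is, per pathway,
the list of per-modality submatrices that the multi-modal autoencoder
consumes: one block per modality, restricted to the features whose mapped
genes fall inside the pathway's gene set, with a single shared patient
ordering across all blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsBlock",
    "PathwayDefinition",
    "FeatureGeneMap",
    "ViewBlock",
    "PathwayMultiOmicsView",
    "load_gene_sets",
    "load_omics_table",
    "load_feature_gene_map",
    "identity_feature_gene_map",
    "build_pathway_views",
]


class GMTParseError(ValueError):
    """Raised for malformed or empty GMT gene-set files."""


@dataclass
class OmicsBlock:
    """One omics modality as a patients x features numeric matrix."""

    modality_name: str
    patients: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patients), len(self.features)):
            raise ValueError(
                f"block '{self.modality_name}': matrix shape {self.values.shape} "
                f"does not match {len(self.patients)} patients x "
                f"{len(self.features)} features"
            )
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"block '{self.modality_name}': duplicate feature IDs")
        if len(set(self.patients)) != len(self.patients):
            raise ValueError(f"block '{self.modality_name}': duplicate patient IDs")


@dataclass
class PathwayDefinition:
    """A named gene set."""

    pathway_id: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.gene_ids = frozenset(self.gene_ids)
        if not self.gene_ids:
            raise ValueError(f"pathway '{self.pathway_id}' has an empty gene set")


@dataclass
class FeatureGeneMap:
    """Many-to-many feature -> gene annotation for one modality."""

    modality_name: str
    pairs: list[tuple[str, str]]

    def genes_for(self, feature: str) -> set[str]:
        return {g for f, g in self.pairs if f == feature}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["feature_id", "gene_id"])


@dataclass
class ViewBlock:
    """One modality's slice of a pathway view (shared patient ordering)."""

    modality_name: str
    features: list[str]
    values: np.ndarray  # patients x len(features)


@dataclass
class PathwayMultiOmicsView:
    """All omics blocks restricted to one pathway, patients aligned."""

    pathway_id: str
    patients: list[str]
    blocks: list[ViewBlock] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.blocks)

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def p(self) -> list[int]:
        """Per-modality feature counts p_j."""
        return [len(b.features) for b in self.blocks]

    @property
    def total_features(self) -> int:
        return sum(self.p)

    def concatenated(self) -> np.ndarray:
        """Patients x sum(p_j) matrix, blocks in order."""
        return np.concatenate([b.values for b in self.blocks], axis=1)

    def feature_names(self) -> list[str]:
        return [f for b in self.blocks for f in b.features]

    def modality_of_feature(self) -> dict[str, str]:
        return {f: b.modality_name for b in self.blocks for f in b.features}


def load_gene_sets(path) -> list[PathwayDefinition]:
    """Parse a GMT file into pathway definitions.

    Each line is ``id<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    genes within a line are collapsed; file order is preserved.
    """
    definitions: list[PathwayDefinition] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(id, description, genes...), got {len(fields)}"
                )
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise GMTParseError(f"{path}: line {lineno}: no genes listed")
            definitions.append(PathwayDefinition(fields[0], frozenset(genes)))
    if not definitions:
        raise GMTParseError(f"{path}: empty gene-set file")
    return definitions


def load_omics_table(path, modality_name: str) -> OmicsBlock:
    """Read a TSV omics matrix (first column patient ID, header feature IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsBlock(
        modality_name=modality_name,
        patients=[str(p) for p in df.index],
        features=[str(f) for f in df.columns],
        values=df.to_numpy(dtype=float),
    )


def load_feature_gene_map(path, modality_name: str) -> FeatureGeneMap:
    """Read a two-column TSV (feature_id, gene_id); a header row is optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["feature_id", "gene_id"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["feature_id", "gene_id"])
    pairs = list(dict.fromkeys(zip(df["feature_id"], df["gene_id"])))
    return FeatureGeneMap(modality_name, pairs)


def identity_feature_gene_map(block: OmicsBlock) -> FeatureGeneMap:
    """Gene-level modalities (expression, CNV): feature IDs are gene IDs."""
    return FeatureGeneMap(block.modality_name, [(f, f) for f in block.features])


def build_pathway_views(
    blocks: list[OmicsBlock],
    gene_sets: list[PathwayDefinition],
    maps: list[FeatureGeneMap],
    min_features_per_modality: int = 1,
    patient_policy: str = "intersect",
) -> list[PathwayMultiOmicsView]:
    """Assemble per-pathway multi-omics views.

    Patients are restricted to the sorted intersection across all blocks.
    Per pathway, each modality contributes exactly the features whose mapped
    genes intersect the pathway's gene set (lexicographic feature order);
    modalities contributing fewer than ``min_features_per_modality`` features
    are dropped from that view, and pathways left with no modality are
    omitted entirely.
    """
    if not blocks:
        raise ValueError("need at least one omics block")
    if patient_policy != "intersect":
        raise ValueError(f"unknown patient_policy '{patient_policy}'")

    maps_by_modality = {m.modality_name: m for m in maps}
    for block in blocks:
        if block.modality_name not in maps_by_modality:
            raise ValueError(
                f"no FeatureGeneMap for modality '{block.modality_name}' "
                "(gene-level modalities can use identity_feature_gene_map)"
            )

    shared = set(blocks[0].patients)
    for block in blocks[1:]:
        shared &= set(block.patients)
    if not shared:
        raise ValueError("patient intersection across modalities is empty")
    patients = sorted(shared)

    # Pre-index: per modality, gene -> set of features annotated to it.
    gene_to_features: dict[str, dict[str, set[str]]] = {}
    for block in blocks:
        fmap = maps_by_modality[block.modality_name]
        in_block = set(block.features)
        g2f: dict[str, set[str]] = {}
        for feat, gene in fmap.pairs:
            if feat in in_block:
                g2f.setdefault(gene, set()).add(feat)
        gene_to_features[block.modality_name] = g2f

    row_index = {
        block.modality_name: [block.patients.index(p) for p in patients]
        for block in blocks
    }

    views: list[PathwayMultiOmicsView] = []
    for pathway in gene_sets:
        view = PathwayMultiOmicsView(pathway.pathway_id, patients)
        for block in blocks:
            g2f = gene_to_features[block.modality_name]
            selected: set[str] = set()
            for gene in pathway.gene_ids:
                selected |= g2f.get(gene, set())
            if len(selected) < max(1, min_features_per_modality):
                continue
            feats = sorted(selected)
            cols = [block.features.index(f) for f in feats]
            sub = block.values[np.ix_(row_index[block.modality_name], cols)]
            view.blocks.append(ViewBlock(block.modality_name, feats, sub))
        if view.k >= 1:
            views.append(view)
    return views
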