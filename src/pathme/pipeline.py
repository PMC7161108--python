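"""End-to-end orchestration: map -> train/score -> cluster -> explain -> stats.

Each stage writes its outputs under the run directory and records a content
hash of its inputs and parameters in ``manifest.json``; re-running with an
unchanged configuration re-uses cached stage outputs, and corrupting an
input invalidates exactly the stages downstream of it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import autoencoder as ae
from . import snmf
from .attribution import attribute_view
from .mapping import (PathwayMultiOmicsView, ViewBlock, build_pathway_views,
                      identity_feature_gene_map, load_feature_gene_map,
                      load_gene_sets, load_omics_table)
from .stats import clinical_associations, mutational_burden, survival_association

log = logging.getLogger("pathme")

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline",
           "save_views", "load_views"]


@dataclass
class RunConfig:
    """All inputs and stage parameters of one reproducible run.

    Defaults follow the published protocol: hyper-parameter budget 50 with
    5-fold cross-validation, 500 consensus restarts, 40 permutations for
    rank selection over ranks 2..9 and beta in [0.001, 1].
    ``fast_profile`` substitutes a reduced computational profile for
    desk-scale runs; it changes no scientific defaults of the data.
    """

    out_dir: str
    gmt: str | None = None
    omics: dict = field(default_factory=dict)        # modality -> TSV path
    maps: dict = field(default_factory=dict)         # modality -> TSV path
    mutations: str | None = None
    clinical: str | None = None

    min_features_per_modality: int = 1
    budget: int = 50
    folds: int = 5
    max_epochs: int = 500
    optimizer: str = "adam"
    runs: int = 500
    n_perm: int = 40
    ranks: list[int] = field(default_factory=lambda: list(range(2, 10)))
    beta_grid: list[float] = field(default_factory=lambda: [0.001, 0.01, 0.1, 1.0])
    shap_samples: int = 200
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    @classmethod
    def fast_profile(cls, **kwargs) -> "RunConfig":
        """Reduced computational profile for desk-scale data."""
        defaults = dict(budget=10, folds=5, max_epochs=80, runs=50,
                        n_perm=10, ranks=list(range(2, 7)),
                        beta_grid=[0.01], shap_samples=100)
        defaults.update(kwargs)
        return cls(**defaults)

    def validate(self) -> None:
        for path in [self.gmt, self.mutations, self.clinical,
                     *self.omics.values(), *self.maps.values()]:
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(path)
        if not self.omics:
            raise ValueError("no omics inputs configured")
        if self.gmt is None:
            raise ValueError("no gene-set (GMT) input configured")


@dataclass
class ResultsBundle:
    config: RunConfig
    views: list[PathwayMultiOmicsView]
    scores: ae.PathwayScoreMatrix
    rank_selection: dict
    labels: pd.Series
    consensus: snmf.ConsensusResult | None
    descriptive: dict
    attributions: dict
    stats: dict
    manifest: dict


# ---------------------------------------------------------------------------
# views (de)serialization
# ---------------------------------------------------------------------------

def save_views(views: list[PathwayMultiOmicsView], path) -> None:
    blob = [
        {
            "pathway_id": v.pathway_id,
            "patients": v.patients,
            "blocks": [
                {"modality": b.modality_name, "features": b.features,
                 "values": b.values.tolist()}
                for b in v.blocks
            ],
        }
        for v in views
    ]
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_views(path) -> list[PathwayMultiOmicsView]:
    with open(path) as fh:
        blob = json.load(fh)
    views = []
    for v in blob:
        view = PathwayMultiOmicsView(v["pathway_id"], v["patients"])
        for b in v["blocks"]:
            view.blocks.append(ViewBlock(
                b["modality"], b["features"],
                np.asarray(b["values"], dtype=float)))
        views.append(view)
    return views


# ---------------------------------------------------------------------------
# caching helpers
# ---------------------------------------------------------------------------

def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(files: list[str], params: dict) -> str:
    payload = {"files": {f: _file_hash(f) for f in files if f},
               "params": params}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: str):
        self.path = os.path.join(out_dir, "manifest.json")
        self.data: dict = {"stages": {}}
        if os.path.exists(self.path):
            with open(self.path) as fh:
                self.data = json.load(fh)

    def fresh(self, stage: str, key: str, outputs: list[str]) -> bool:
        rec = self.data["stages"].get(stage)
        return (rec is not None and rec["key"] == key
                and all(os.path.exists(o) for o in rec["outputs"])
                and sorted(rec["outputs"]) == sorted(outputs))

    def record(self, stage: str, key: str, outputs: list[str], **extra) -> None:
        self.data["stages"][stage] = {"key": key, "outputs": outputs, **extra}
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_map(cfg: RunConfig, manifest: _Manifest) -> list[PathwayMultiOmicsView]:
    out = os.path.join(cfg.out_dir, "views.json")
    files = [cfg.gmt, *cfg.omics.values(), *cfg.maps.values()]
    key = _stage_key(files, {"min_features": cfg.min_features_per_modality})
    if manifest.fresh("map", key, [out]):
        log.info("map: cache hit")
        return load_views(out)
    blocks = [load_omics_table(p, name) for name, p in sorted(cfg.omics.items())]
    maps = [load_feature_gene_map(p, name) for name, p in sorted(cfg.maps.items())]
    mapped = {m.modality_name for m in maps}
    for block in blocks:
        if block.modality_name not in mapped:
            maps.append(identity_feature_gene_map(block))
    gene_sets = load_gene_sets(cfg.gmt)
    views = build_pathway_views(blocks, gene_sets, maps,
                                cfg.min_features_per_modality)
    save_views(views, out)
    manifest.record("map", key, [out], n_views=len(views))
    log.info("map: %d pathway views", len(views))
    return views


def _stage_score(cfg: RunConfig, manifest: _Manifest,
                 views: list[PathwayMultiOmicsView]) -> ae.PathwayScoreMatrix:
    scores_path = os.path.join(cfg.out_dir, "scores.tsv")
    models_dir = os.path.join(cfg.out_dir, "models")
    summary_path = os.path.join(models_dir, "summary.json")
    key = _stage_key([os.path.join(cfg.out_dir, "views.json")],
                     {"budget": cfg.budget, "folds": cfg.folds,
                      "max_epochs": cfg.max_epochs, "optimizer": cfg.optimizer,
                      "seed": cfg.seed})
    if manifest.fresh("score", key, [scores_path, summary_path]):
        log.info("score: cache hit")
        return ae.PathwayScoreMatrix.from_frame(
            pd.read_csv(scores_path, sep="\t", index_col=0))
    os.makedirs(models_dir, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    pathway_seeds = ss.generate_state(len(views)) % (2 ** 31)
    scores: dict[str, np.ndarray] = {}
    summary = {}
    for view, pw_seed in zip(views, pathway_seeds):
        X = view.concatenated()
        best_cfg, best_arch, cv, _ = ae.tune(
            X, view.p, budget=cfg.budget, folds=cfg.folds, seed=int(pw_seed),
            max_epochs=cfg.max_epochs, optimizer=cfg.optimizer,
            modalities=[b.modality_name for b in view.blocks])
        trained = ae.train(X, best_arch, best_cfg,
                           feature_names=view.feature_names())
        trained.pathway_id = view.pathway_id
        trained.model.save(os.path.join(models_dir, f"{view.pathway_id}.json"))
        scores[view.pathway_id] = ae.score_patients(trained, X)
        summary[view.pathway_id] = {
            "cv_error": cv, "hidden_sizes": best_arch.hidden_sizes,
            "config": {k: v for k, v in asdict(best_cfg).items()},
            "final_loss": trained.loss_trace[-1],
            "epochs": len(trained.loss_trace),
        }
        log.info("train: pathway=%s cv_error=%.4g epochs=%d",
                 view.pathway_id, cv, len(trained.loss_trace))
    matrix = ae.assemble_score_matrix(scores, views[0].patients)
    matrix.to_frame().to_csv(scores_path, sep="\t")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    manifest.record("score", key, [scores_path, summary_path])
    return matrix


def _stage_cluster(cfg: RunConfig, manifest: _Manifest,
                   scores: ae.PathwayScoreMatrix):
    labels_path = os.path.join(cfg.out_dir, "labels.tsv")
    consensus_path = os.path.join(cfg.out_dir, "consensus_matrix.tsv")
    rank_path = os.path.join(cfg.out_dir, "rank_selection.json")
    desc_path = os.path.join(cfg.out_dir, "descriptive_pathways.json")
    outputs = [labels_path, consensus_path, rank_path, desc_path]
    key = _stage_key([os.path.join(cfg.out_dir, "scores.tsv")],
                     {"runs": cfg.runs, "n_perm": cfg.n_perm,
                      "ranks": cfg.ranks, "beta_grid": cfg.beta_grid,
                      "seed": cfg.seed})
    if manifest.fresh("cluster", key, outputs):
        log.info("cluster: cache hit")
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)["cluster"]
        with open(rank_path) as fh:
            rank_report = json.load(fh)
        with open(desc_path) as fh:
            descriptive = json.load(fh)
        return rank_report, labels, None, descriptive

    X = scores.values
    sel = snmf.select_rank(X, ranks=cfg.ranks, beta_grid=cfg.beta_grid,
                           runs=cfg.runs, n_perm=cfg.n_perm, seed=cfg.seed)
    if sel.selected_rank is not None:
        m = sel.selected_rank
    else:
        # unresolved: fall back to the rank with the best cophenetic
        m = max(sel.best_beta, key=lambda r: sel.real_cophenetic[(sel.best_beta[r], r)])
        log.warning("rank selection unresolved; falling back to rank %d", m)
    beta = sel.best_beta[m]
    cons = snmf.consensus_cluster(X, m, beta, runs=cfg.runs, seed=cfg.seed + 1)
    log.info("cluster: m=%d beta=%g cophenetic=%.3f silhouette=%.3f",
             m, beta, cons.cophenetic, cons.consensus_silhouette)

    labels = pd.Series(cons.labels, index=scores.patients, name="cluster")
    labels.rename_axis("patient").to_frame().to_csv(labels_path, sep="\t")
    pd.DataFrame(cons.consensus_matrix, index=scores.patients,
                 columns=scores.patients).to_csv(consensus_path, sep="\t")

    rank_report = {
        "selected_rank": sel.selected_rank,
        "used_rank": int(m),
        "resolved": sel.resolved,
        "beta": beta,
        "cophenetic": cons.cophenetic,
        "consensus_silhouette": cons.consensus_silhouette,
        "best_run_silhouette": cons.best_run_silhouette,
        "real_cophenetic": {f"beta={b}|rank={r}": v
                            for (b, r), v in sel.real_cophenetic.items()},
        "permutation_upper_bounds": {str(r): v for r, v in sel.upper_bound.items()},
    }
    with open(rank_path, "w") as fh:
        json.dump(rank_report, fh, indent=2, default=str)

    descriptive = {}
    if cons.best_run is not None:
        B = cons.best_run.B
        for comp in range(1, m + 1):
            idx = snmf.descriptive_features(B, comp)
            descriptive[str(comp)] = [scores.pathway_ids[i] for i in idx]
    with open(desc_path, "w") as fh:
        json.dump(descriptive, fh, indent=2)
    manifest.record("cluster", key, outputs)
    return rank_report, labels, cons, descriptive


def _stage_explain(cfg: RunConfig, manifest: _Manifest,
                   views: list[PathwayMultiOmicsView],
                   descriptive: dict) -> dict:
    shap_dir = os.path.join(cfg.out_dir, "shap")
    summary_path = os.path.join(shap_dir, "summary.json")
    key = _stage_key([os.path.join(cfg.out_dir, "scores.tsv"),
                      os.path.join(cfg.out_dir, "descriptive_pathways.json")],
                     {"shap_samples": cfg.shap_samples, "seed": cfg.seed})
    if manifest.fresh("explain", key, [summary_path]):
        log.info("explain: cache hit")
        with open(summary_path) as fh:
            return json.load(fh)
    os.makedirs(shap_dir, exist_ok=True)
    wanted = sorted({pw for pws in descriptive.values() for pw in pws})
    views_by_id = {v.pathway_id: v for v in views}
    models_dir = os.path.join(cfg.out_dir, "models")
    summary: dict = {}
    for pw in wanted:
        view = views_by_id.get(pw)
        model_path = os.path.join(models_dir, f"{pw}.json")
        if view is None or not os.path.exists(model_path):
            continue
        model = ae.AutoencoderModel.load(model_path)
        trained = ae.TrainedPathwayModel(model, [], ae.TrainingConfig())
        att = attribute_view(trained, view.concatenated(), view.patients,
                             view.feature_names(), view.modality_of_feature(),
                             pw, n_samples=cfg.shap_samples, seed=cfg.seed)
        rows = []
        mod_of = view.modality_of_feature()
        for i, patient in enumerate(att.patients):
            for fj, feat in enumerate(att.features):
                rows.append((pw, patient, feat, mod_of[feat], att.phi[i, fj]))
        pd.DataFrame(rows, columns=["pathway", "patient", "feature",
                                    "modality", "phi"]).to_csv(
            os.path.join(shap_dir, f"{pw}.tsv"), sep="\t", index=False)
        summary[pw] = {"per_feature": att.per_feature()[:20],
                       "per_modality": att.per_modality()}
        log.info("explain: pathway=%s top=%s", pw,
                 summary[pw]["per_feature"][0][0] if summary[pw]["per_feature"] else None)
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest.record("explain", key, [summary_path])
    return summary


def _stage_stats(cfg: RunConfig, manifest: _Manifest,
                 labels: pd.Series) -> dict:
    stats_dir = os.path.join(cfg.out_dir, "stats")
    report_path = os.path.join(stats_dir, "associations.json")
    files = [os.path.join(cfg.out_dir, "labels.tsv")]
    if cfg.mutations:
        files.append(cfg.mutations)
    if cfg.clinical:
        files.append(cfg.clinical)
    key = _stage_key(files, {"gmt": cfg.gmt})
    if manifest.fresh("stats", key, [report_path]):
        log.info("stats: cache hit")
        with open(report_path) as fh:
            return json.load(fh)
    os.makedirs(stats_dir, exist_ok=True)
    report: dict = {}
    if cfg.mutations:
        mutations = pd.read_csv(cfg.mutations, sep="\t", index_col=0)
        mutations = mutations.loc[labels.index]
        pathways = load_gene_sets(cfg.gmt)
        table, _ = mutational_burden(mutations, pathways, labels)
        table.to_csv(os.path.join(stats_dir, "mutational_burden.tsv"),
                     sep="\t", index=False)
        report["mutational_burden"] = table.to_dict(orient="records")
    if cfg.clinical:
        clinical = pd.read_csv(cfg.clinical, sep="\t", index_col=0)
        clinical = clinical.loc[labels.index]
        surv = {}
        for endpoint in ("os", "pfs", "dfs"):
            tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
            if tcol in clinical.columns and ecol in clinical.columns:
                res = survival_association(labels, clinical, endpoint)
                surv[endpoint] = {"p": res.p, "method": res.method,
                                  "age_p": res.age_p}
        report["survival"] = surv
        assoc = clinical_associations(labels, clinical)
        assoc.to_csv(os.path.join(stats_dir, "clinical_associations.tsv"),
                     sep="\t", index=False)
        report["clinical"] = assoc.to_dict(orient="records")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    manifest.record("stats", key, [report_path])
    return report


def run_pipeline(cfg: RunConfig) -> ResultsBundle:
    """Execute all stages in order with per-stage caching."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest = _Manifest(cfg.out_dir)
    views = _stage_map(cfg, manifest)
    scores = _stage_score(cfg, manifest, views)
    rank_report, labels, cons, descriptive = _stage_cluster(cfg, manifest, scores)
    attributions = _stage_explain(cfg, manifest, views, descriptive)
    stats = _stage_stats(cfg, manifest, labels) \
        if (cfg.mutations or cfg.clinical) else {}
    return ResultsBundle(cfg, views, scores, rank_report, labels, cons,
                         descriptive, attributions, stats, manifest.data)
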