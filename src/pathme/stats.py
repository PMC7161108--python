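"""Post-hoc characterization of patient clusters.

Three analyses, each a separate multiple-testing family with
Benjamini-Hochberg correction:

* mutational burden — per patient, the fraction of a pathway's genes
  carrying any somatic mutation; compared across clusters with a
  Kruskal-Wallis test, one test per pathway;
* survival — if age is nominally associated with the endpoint in an
  age-only Cox model, the cluster effect is a likelihood-ratio test of
  {cluster + age} against {age}; otherwise a plain log-rank test across
  clusters;
* other clinical variables — chi-squared for categoricals (levels carried
  by a single patient are pooled into "other"), one-way ANOVA for
  numerics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .mapping import PathwayDefinition

__all__ = [
    "benjamini_hochberg",
    "pathway_burden",
    "mutational_burden",
    "survival_association",
    "clinical_associations",
    "SurvivalResult",
]

SURVIVAL_COLUMNS = {
    "os": ("os_time", "os_event"),
    "pfs": ("pfs_time", "pfs_event"),
    "dfs": ("dfs_time", "dfs_event"),
}


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up FDR-adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def pathway_burden(mutations: pd.DataFrame, pathway: PathwayDefinition) -> pd.Series | None:
    """Fraction of the pathway's covered genes mutated, per patient.

    ``mutations`` is a patients x genes 0/1 table.  Returns None (with a
    warning) when no pathway gene is covered by the table.
    """
    covered = sorted(pathway.gene_ids & set(mutations.columns))
    if not covered:
        warnings.warn(f"pathway '{pathway.pathway_id}': no gene overlap with "
                      "mutation table; skipped")
        return None
    vals = mutations[covered].to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("mutation table entries must be 0/1")
    return pd.Series(vals.mean(axis=1), index=mutations.index, name=pathway.pathway_id)


def mutational_burden(
    mutations: pd.DataFrame,
    pathways: list[PathwayDefinition],
    labels: pd.Series,
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Kruskal-Wallis comparison of per-pathway mutational burden across
    clusters, BH-corrected across all tested pathways.

    ``labels`` is indexed by patient ID.  Returns (result table with
    columns pathway, statistic, p, p_adj; dict of per-pathway burden
    series).
    """
    labels = labels.loc[mutations.index]
    if labels.nunique() < 2:
        raise ValueError("need >= 2 clusters")
    rows = []
    burdens: dict[str, pd.Series] = {}
    for pw in pathways:
        b = pathway_burden(mutations, pw)
        if b is None:
            continue
        burdens[pw.pathway_id] = b
        groups = [b[labels == c].to_numpy() for c in sorted(labels.unique())]
        if np.ptp(np.concatenate(groups)) == 0:
            stat, p = 0.0, 1.0  # identical burden everywhere: no evidence
        else:
            stat, p = sps.kruskal(*groups)
        rows.append({"pathway": pw.pathway_id, "statistic": float(stat),
                     "p": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
    return table, burdens


@dataclass
class SurvivalResult:
    p: float
    method: str          # "age-corrected-lrt" or "logrank"
    endpoint: str
    age_p: float | None = None
    details: dict | None = None


def survival_association(
    labels: pd.Series,
    clinical: pd.DataFrame,
    endpoint: str = "os",
    age_threshold: float = 0.05,
) -> SurvivalResult:
    """Association of cluster labels with a survival endpoint.

    If age is nominally significant (p < ``age_threshold``) in an age-only
    proportional-hazards model, the reported p-value is a likelihood-ratio
    test of {cluster + age} vs {age}; otherwise a log-rank test across
    clusters.  The method tag records the branch taken.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import multivariate_logrank_test

    if endpoint not in SURVIVAL_COLUMNS:
        raise ValueError(f"unknown endpoint '{endpoint}'")
    tcol, ecol = SURVIVAL_COLUMNS[endpoint]
    if tcol not in clinical.columns or ecol not in clinical.columns:
        raise ValueError(f"clinical table lacks columns {tcol}/{ecol}")
    df = clinical.loc[labels.index, [tcol, ecol]].copy()
    df["cluster"] = labels.astype("category")
    if "age" in clinical.columns:
        df["age"] = clinical.loc[labels.index, "age"]
    df = df.dropna()
    if df["cluster"].nunique() < 2:
        raise ValueError("need >= 2 clusters")
    if df[ecol].sum() == 0:
        warnings.warn(f"endpoint '{endpoint}': all observations censored")
        return SurvivalResult(float("nan"), "undefined", endpoint)

    age_p = None
    if "age" in df.columns:
        cph_age = CoxPHFitter()
        cph_age.fit(df[[tcol, ecol, "age"]], duration_col=tcol, event_col=ecol)
        age_p = float(cph_age.summary.loc["age", "p"])

    if age_p is not None and age_p < age_threshold:
        dummies = pd.get_dummies(df["cluster"], prefix="cluster",
                                 drop_first=True, dtype=float)
        full = pd.concat([df[[tcol, ecol, "age"]], dummies], axis=1)
        cph_full = CoxPHFitter()
        cph_full.fit(full, duration_col=tcol, event_col=ecol)
        lr = 2.0 * (cph_full.log_likelihood_ - cph_age.log_likelihood_)
        dof = dummies.shape[1]
        p = float(sps.chi2.sf(max(lr, 0.0), dof))
        return SurvivalResult(p, "age-corrected-lrt", endpoint, age_p,
                              {"lr_statistic": float(lr), "df": dof})
    res = multivariate_logrank_test(df[tcol], df["cluster"], df[ecol])
    return SurvivalResult(float(res.p_value), "logrank", endpoint, age_p,
                          {"statistic": float(res.test_statistic)})


def _pool_rare_levels(col: pd.Series) -> pd.Series:
    counts = col.value_counts()
    rare = counts[counts <= 1].index
    if len(rare):
        warnings.warn(f"variable '{col.name}': pooling singleton levels "
                      f"{list(rare)} into 'other'")
        col = col.where(~col.isin(rare), other="other")
    return col


def clinical_associations(
    labels: pd.Series,
    clinical: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Chi-squared / ANOVA association of clinical variables with clusters.

    Survival endpoint columns are excluded automatically; everything else
    (or the explicit ``variables`` list) is tested — categoricals with a
    chi-squared contingency test, numerics with one-way ANOVA — and
    BH-corrected as one family.
    """
    labels = labels.loc[clinical.index.intersection(labels.index)]
    if labels.nunique() < 2:
        raise ValueError("need >= 2 clusters")
    survival_cols = {c for pair in SURVIVAL_COLUMNS.values() for c in pair}
    if variables is None:
        variables = [c for c in clinical.columns if c not in survival_cols]
    rows = []
    for var in variables:
        col = clinical.loc[labels.index, var].dropna()
        lab = labels.loc[col.index]
        if col.empty or lab.nunique() < 2:
            continue
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 5:
            groups = [col[lab == c].to_numpy() for c in sorted(lab.unique())]
            groups = [g for g in groups if len(g) > 0]
            stat, p = sps.f_oneway(*groups)
            test = "anova"
        else:
            col = _pool_rare_levels(col.astype(str))
            table = pd.crosstab(col, lab)
            if table.shape[0] < 2:
                continue
            stat, p, _, _ = sps.chi2_contingency(table)
            test = "chi2"
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out
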