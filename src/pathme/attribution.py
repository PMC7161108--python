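"""Shapley-value attribution of pathway scores to omics features.

The pathway score f(x) produced by the bottleneck unit is explained by
Shapley values: phi_i is the weighted average, over all feature subsets S
not containing i, of f(x with S u {i} present) - f(x with S present),
with weight |S|! (|F|-|S|-1)! / |F|!.  Features absent from a coalition
are replaced by a background reference (by default the training-set mean),
the usual conditional-expectation surrogate.

Exact enumeration is exponential and guarded to small feature counts; the
fast path is a seeded permutation-sampling estimator whose per-permutation
marginal contributions telescope, so the efficiency identity
sum(phi) = f(x) - f(background) holds exactly for any sample count.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .autoencoder import TrainedPathwayModel, score_patients

__all__ = [
    "Attribution",
    "exact_shapley",
    "approx_shapley",
    "attribute_view",
    "aggregate",
]

EXACT_GUARD = 15


def _as_batch_fn(f):
    """Wrap a scalar-vector function so it maps a matrix to a vector."""
    def batched(X):
        X = np.atleast_2d(X)
        out = np.asarray(f(X), dtype=float)
        if out.ndim == 0:
            return out[None]
        return out.reshape(X.shape[0])
    return batched


def exact_shapley(f, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Shapley values by full subset enumeration.

    ``f`` maps a (batch of) feature vector(s) to score(s); absent features
    are set to ``background``.  Satisfies efficiency exactly:
    sum(phi) = f(x) - f(background).
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    F = x.size
    if F > EXACT_GUARD:
        raise ValueError(
            f"{F} features exceeds the exact-enumeration guard ({EXACT_GUARD}); "
            "use approx_shapley")
    n_subsets = 1 << F
    masks = ((np.arange(n_subsets)[:, None] >> np.arange(F)) & 1).astype(bool)
    inputs = np.where(masks, x, background)
    values = np.asarray(f(inputs), dtype=float).reshape(n_subsets)

    # weight for a coalition S (not containing i): |S|! (F-|S|-1)! / F!
    w = np.array([factorial(s) * factorial(F - s - 1) / factorial(F)
                  for s in range(F)])
    sizes = masks.sum(axis=1)
    phi = np.zeros(F)
    for i in range(F):
        without = ~masks[:, i]
        s = sizes[without]
        phi[i] = np.sum(w[s] * (values[np.flatnonzero(without) | (1 << i)]
                                - values[without]))
    return phi


def approx_shapley(
    model_or_f,
    x: np.ndarray,
    background: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Permutation-sampling Shapley estimate.

    For each sampled feature ordering, features are inserted one by one and
    their marginal score changes accumulated.  Unbiased for the exact
    Shapley value; deterministic given ``seed``.  ``background`` may be a
    single reference vector or a sample of rows (its per-feature mean is
    used as the masking reference).
    """
    if isinstance(model_or_f, TrainedPathwayModel):
        trained = model_or_f
        f = _as_batch_fn(lambda X: score_patients(trained, X))
    else:
        f = _as_batch_fn(model_or_f)
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[1] != x.size:
        raise ValueError("background width does not match feature vector")
    ref = background.mean(axis=0)
    F = x.size
    rng = np.random.default_rng(seed)

    phi = np.zeros(F)
    for _ in range(n_samples):
        order = rng.permutation(F)
        # rows 0..F: background with the first t features of `order` revealed
        states = np.tile(ref, (F + 1, 1))
        for t, i in enumerate(order):
            states[t + 1:, i] = x[i]
        vals = f(states)
        phi[order] += vals[1:] - vals[:-1]
    return phi / n_samples


@dataclass
class Attribution:
    """Per-patient feature attributions for one pathway score."""

    pathway_id: str
    patients: list[str]
    features: list[str]
    modalities: dict            # feature -> modality name
    phi: np.ndarray             # patients x features, signed
    background: str = "training mean"

    def per_feature(self) -> list[tuple[str, float]]:
        feats, _ = aggregate(self.phi, self.features, self.modalities)
        return feats

    def per_modality(self) -> list[tuple[str, float]]:
        _, mods = aggregate(self.phi, self.features, self.modalities)
        return mods


def attribute_view(
    trained: TrainedPathwayModel,
    X: np.ndarray,
    patients: list[str],
    features: list[str],
    modalities: dict,
    pathway_id: str,
    n_samples: int = 200,
    seed: int = 0,
) -> Attribution:
    """Attribute every patient's pathway score to the view's features.

    Background is the per-feature mean of ``X`` (the data the model was
    trained on).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = X.mean(axis=0)
    phi = np.vstack([
        approx_shapley(trained, X[i], ref, n_samples=n_samples,
                       seed=seed + i)
        for i in range(X.shape[0])
    ])
    return Attribution(pathway_id, list(patients), list(features),
                       dict(modalities), phi)


def aggregate(phi: np.ndarray, features: list[str], modality_map: dict):
    """Mean absolute Shapley value per feature and per modality.

    The feature score is the mean over patients of |phi|; the modality
    score is the mean over all its features' per-patient |phi| values.
    Both outputs are sorted descending.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if phi.shape[1] != len(features):
        raise ValueError("phi width does not match feature list")
    unknown = [f for f in features if f not in modality_map]
    if unknown:
        raise ValueError(f"features missing from modality map: {unknown[:5]}")
    abs_phi = np.abs(phi)
    per_feature = {f: float(abs_phi[:, i].mean()) for i, f in enumerate(features)}
    per_modality: dict[str, list[float]] = {}
    for i, f in enumerate(features):
        per_modality.setdefault(modality_map[f], []).extend(abs_phi[:, i])
    per_modality = {m: float(np.mean(v)) for m, v in per_modality.items()}
    feat_sorted = sorted(per_feature.items(), key=lambda kv: -kv[1])
    mod_sorted = sorted(per_modality.items(), key=lambda kv: -kv[1])
    return feat_sorted, mod_sorted
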