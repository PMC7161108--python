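"""Sparse non-negative matrix factorization and consensus bi-clustering.

The pathway-score matrix X (P pathways x n patients, non-negative) is
factorized as X ~ B H with B >= 0 (P x m basis, pathways x clusters) and
H >= 0 (m x n coefficients, clusters x patients), minimizing

    1/2 { ||X - BH||_F^2 + eta ||B||_F^2 + beta sum_j ||H(:,j)||_1^2 }

i.e. a ridge on the basis plus a squared-l1 column sparsity on the
coefficients.  Both subproblems are exact non-negative least squares on
augmented systems (the squared-l1 term is absorbed by stacking a
sqrt(beta) row of ones under B), so alternating updates decrease the
objective monotonically.

Because a single consensus run repeats the factorization hundreds of
times, the NNLS subproblems are solved by a block-principal-pivoting
active-set method vectorized over all right-hand sides.

Cluster robustness is assessed by consensus clustering over random
restarts: the consensus matrix holds co-clustering frequencies, its
average-linkage dendrogram yields the final labels, and the cophenetic
correlation between consensus dissimilarities and dendrogram heights
drives rank (cluster-number) selection against a permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "SNMFFactorization",
    "ConsensusResult",
    "RankSelection",
    "snmf_factorize",
    "assign_clusters",
    "consensus_cluster",
    "cophenetic_correlation",
    "silhouette",
    "select_rank",
    "descriptive_features",
    "adjusted_rand_index",
]


# ---------------------------------------------------------------------------
# multi-RHS non-negative least squares (block principal pivoting)
# ---------------------------------------------------------------------------

def _solve_passive(AtA: np.ndarray, AtY: np.ndarray, passive: np.ndarray,
                   cho=None) -> np.ndarray:
    """Solve the least-squares system restricted to each column's passive set.

    Columns sharing a passive-set pattern (bit-packed) are solved in one
    batched call; the frequent all-passive pattern reuses a prefactorized
    ``cho`` of the full AtA.
    """
    from scipy.linalg import cho_solve

    m, ncol = AtY.shape
    X = np.zeros((m, ncol))
    codes = (passive * (1 << np.arange(m))[:, None]).sum(axis=0)
    full = codes == (1 << m) - 1
    if full.any():
        if cho is not None:
            X[:, full] = cho_solve(cho, AtY[:, full])
        else:
            X[:, full] = np.linalg.lstsq(AtA, AtY[:, full], rcond=None)[0]
    rest = np.flatnonzero(~full & (codes > 0))
    if rest.size:
        order = rest[np.argsort(codes[rest], kind="stable")]
        bounds = np.flatnonzero(np.diff(codes[order])) + 1
        for cols in np.split(order, bounds):
            pat = passive[:, cols[0]]
            sub = AtA[np.ix_(pat, pat)]
            rhs = AtY[np.ix_(pat, cols)]
            try:
                sol = np.linalg.solve(sub, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(sub, rhs, rcond=None)[0]
            X[np.ix_(pat, cols)] = sol
    return X


def nnls_multi(AtA: np.ndarray, AtY: np.ndarray, tol: float = 1e-12,
               max_iter: int | None = None,
               passive: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Solve min_{Z>=0} 1/2 z'AtA z - z'Aty column-wise for all columns of AtY.

    Block principal pivoting with Murty's single-exchange backup rule, which
    guarantees finite termination when AtA is positive definite.  ``passive``
    warm-starts the active sets (e.g. from the previous alternating
    iteration).  Returns (solution, final passive mask).  Dispatches to the
    compiled per-column kernel when numba is available; the vectorized numpy
    path below is the reference implementation.
    """
    from ._nnls import HAVE_NUMBA, bpp_multi

    m, ncol = AtY.shape
    if HAVE_NUMBA:
        if passive is None:
            passive = np.zeros((m, ncol), dtype=np.bool_)
        else:
            passive = passive.copy()
        X = bpp_multi(np.ascontiguousarray(AtA),
                      np.ascontiguousarray(AtY), passive)
        return X, passive

    from scipy.linalg import cho_factor

    if max_iter is None:
        max_iter = 10 * m + 100
    try:
        cho = cho_factor(AtA)
    except np.linalg.LinAlgError:
        cho = None
    if passive is None:
        passive = np.zeros((m, ncol), dtype=bool)
        X = np.zeros((m, ncol))
        Y = -AtY.copy()  # dual at X = 0
    else:
        passive = passive.copy()
        X = _solve_passive(AtA, AtY, passive, cho)
        Y = AtA @ X - AtY

    backup = np.full(ncol, 3, dtype=int)
    best_ninf = np.full(ncol, m + 1, dtype=int)

    for _ in range(max_iter):
        infeas = (passive & (X < -tol)) | (~passive & (Y < -tol))
        ninf = infeas.sum(axis=0)
        cols = ninf > 0
        if not cols.any():
            break
        improved = cols & (ninf < best_ninf)
        best_ninf[improved] = ninf[improved]
        backup[improved] = 3
        with_backup = cols & ~improved & (backup > 0)
        backup[with_backup] -= 1
        full = improved | with_backup
        passive[:, full] ^= infeas[:, full]
        for j in np.flatnonzero(cols & ~full):
            # Murty: flip only the largest infeasible index
            passive[np.flatnonzero(infeas[:, j]).max(), j] ^= True
        X = _solve_passive(AtA, AtY, passive, cho)
        Y = AtA @ X - AtY
    np.maximum(X, 0.0, out=X)
    X[~passive] = 0.0
    return X, passive


# ---------------------------------------------------------------------------
# sparse NMF
# ---------------------------------------------------------------------------

@dataclass
class SNMFFactorization:
    X: np.ndarray
    B: np.ndarray
    H: np.ndarray
    m: int
    eta: float
    beta: float
    objective: float
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def h_sparsity(self) -> float:
        """sum_j ||H(:,j)||_1^2 — the quantity the beta penalty controls."""
        return float((self.H.sum(axis=0) ** 2).sum())


def _snmf_objective(X, B, H, eta, beta) -> float:
    resid = X - B @ H
    return 0.5 * (
        float((resid ** 2).sum())
        + eta * float((B ** 2).sum())
        + beta * float((H.sum(axis=0) ** 2).sum())
    )


def snmf_factorize(
    X: np.ndarray,
    m: int,
    beta: float,
    eta: float | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SNMFFactorization:
    """Alternating-NNLS sparse NMF of a non-negative matrix.

    ``eta`` defaults to ``max(X)``.  Deterministic given ``seed`` (uniform
    random initialization of B and H).  The objective is non-increasing
    across iterations; iteration stops when its relative change falls
    below ``tol`` or at ``max_iter``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if np.min(X) < 0:
        raise ValueError("X must be elementwise non-negative")
    P, n = X.shape
    if not (1 <= m <= min(P, n)):
        raise ValueError(f"rank m={m} out of range [1, {min(P, n)}]")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if eta is None:
        eta = float(X.max())

    rng = np.random.default_rng(seed)
    B = rng.uniform(size=(P, m))
    H = rng.uniform(size=(m, n))

    ones = np.ones((m, m))
    eye = np.eye(m)
    trace: list[float] = [_snmf_objective(X, B, H, eta, beta)]
    converged = False
    it = 0
    passive_H = passive_B = None
    for it in range(1, max_iter + 1):
        # H-step: min ||[B; sqrt(beta) 1'] H - [X; 0]||  s.t. H >= 0
        AtA = B.T @ B + beta * ones
        H, passive_H = nnls_multi(AtA, B.T @ X, passive=passive_H)
        # B-step: min ||[H'; sqrt(eta) I] B' - [X'; 0]||  s.t. B >= 0
        AtA = H @ H.T + eta * eye
        Bt, passive_B = nnls_multi(AtA, H @ X.T, passive=passive_B)
        B = Bt.T
        obj = _snmf_objective(X, B, H, eta, beta)
        trace.append(obj)
        prev = trace[-2]
        if prev - obj <= tol * max(prev, 1e-300):
            converged = True
            break
    return SNMFFactorization(X, B, H, m, eta, beta, trace[-1], trace, it, converged)


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """Assign each patient (column of H) to the cluster of its largest
    coefficient.  Labels are 1-based; ties break toward the lowest row."""
    H = np.asarray(H, dtype=float)
    if np.min(H) < 0:
        raise ValueError("H must be non-negative")
    if np.any(H.sum(axis=0) == 0):
        warnings.warn("all-zero column(s) in H assigned to cluster 1")
    return H.argmax(axis=0) + 1


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    consensus_matrix: np.ndarray  # n x n, co-clustering frequencies
    labels: np.ndarray            # 1..m per patient
    m: int
    cophenetic: float
    consensus_silhouette: float
    best_run_silhouette: float
    run_objectives: list[float]
    best_run: SNMFFactorization | None = None
    n_failed: int = 0


def _connectivity(labels: np.ndarray) -> np.ndarray:
    lab = np.asarray(labels)
    return (lab[:, None] == lab[None, :]).astype(float)


def consensus_cluster(
    X: np.ndarray,
    m: int,
    beta: float,
    runs: int = 500,
    seed: int = 0,
    eta: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-5,
    keep_best_run: bool = True,
) -> ConsensusResult:
    """Consensus clustering over randomly restarted sNMF factorizations.

    The consensus matrix entry C(i,j) is the fraction of runs in which
    patients i and j were assigned to the same cluster.  Final labels come
    from average-linkage hierarchical clustering of the dissimilarity 1 - C
    cut into m clusters.  Per-run seeds derive deterministically from
    ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if runs < 2:
        raise ValueError("consensus clustering needs runs >= 2")
    n = X.shape[1]
    run_seeds = np.random.SeedSequence(seed).generate_state(runs) % (2 ** 31)

    C = np.zeros((n, n))
    objectives: list[float] = []
    best: SNMFFactorization | None = None
    n_ok = 0
    n_failed = 0
    for rs in run_seeds:
        try:
            fac = snmf_factorize(X, m, beta, eta=eta, seed=int(rs),
                                 max_iter=max_iter, tol=tol)
        except Exception as exc:  # pragma: no cover - defensive
            n_failed += 1
            warnings.warn(f"sNMF restart failed and was excluded: {exc}")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = assign_clusters(fac.H)
        C += _connectivity(labels)
        objectives.append(fac.objective)
        if best is None or fac.objective < best.objective:
            best = fac
        n_ok += 1
    if n_failed > 0.10 * runs:
        raise RuntimeError(f"{n_failed}/{runs} sNMF restarts failed")
    logging.getLogger("pathme").info(
        "consensus: m=%d beta=%g runs=%d failed=%d best_objective=%.6g",
        m, beta, n_ok, n_failed, min(objectives) if objectives else float("nan"))
    C /= n_ok
    np.fill_diagonal(C, 1.0)

    D = 1.0 - C
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=m, criterion="maxclust")

    coph = cophenetic_correlation(C)
    _, cons_sil = silhouette(labels, D)
    if keep_best_run and best is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best_labels = assign_clusters(best.H)
        diff = X.T[:, None, :] - X.T[None, :, :]
        D_eu = np.sqrt((diff ** 2).sum(axis=2))
        try:
            _, best_sil = silhouette(best_labels, D_eu)
        except ValueError:
            best_sil = float("nan")
    else:
        best_sil = float("nan")

    return ConsensusResult(C, labels, m, coph, cons_sil, best_sil,
                           objectives, best if keep_best_run else None, n_failed)


def cophenetic_correlation(C: np.ndarray) -> float:
    """Cophenetic correlation of the average-linkage dendrogram on 1 - C.

    Pearson correlation between the condensed entries of 1 - C and the
    dendrogram's cophenetic distances.  NaN (with a warning) when either
    distance vector is constant.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.shape[0] != C.shape[1] or n < 3:
        raise ValueError("C must be square with n >= 3")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    if not np.allclose(np.diag(C), 1.0):
        raise ValueError("C must have a unit diagonal")
    d = squareform(1.0 - C, checks=False)
    Z = linkage(d, method="average")
    coph_d = cophenet(Z)
    if np.std(d) == 0 or np.std(coph_d) == 0:
        warnings.warn("constant distance vector: cophenetic correlation undefined")
        return float("nan")
    return float(np.corrcoef(d, coph_d)[0, 1])


def silhouette(labels: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, float]:
    """Silhouette widths s(i) and their mean for a labeled distance matrix.

    a(i) is the mean distance of i to its co-members, b(i) the smallest
    mean distance to any other cluster; s(i) = (b - a) / max(a, b), and 0
    for members of singleton clusters.
    """
    labels = np.asarray(labels)
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0, atol=1e-8):
        raise ValueError("D must be symmetric with a zero diagonal")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")

    members = {c: np.flatnonzero(labels == c) for c in uniq}
    s = np.zeros(n)
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (len(own) - 1)
        b = min(D[i, members[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


# ---------------------------------------------------------------------------
# rank selection
# ---------------------------------------------------------------------------

@dataclass
class RankSelection:
    ranks: list[int]
    beta_grid: list[float]
    real_cophenetic: dict        # (beta, rank) -> cophenetic on the data
    perm_cophenetic: dict        # (beta, rank) -> list over permutations
    best_beta: dict              # rank -> beta maximizing real cophenetic
    upper_bound: dict            # rank -> 95% CI upper bound of permutation null
    selected_rank: int | None
    resolved: bool


def _permute_within_rows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle entries independently within every row: each pathway's score
    distribution is preserved while patient co-structure is destroyed."""
    Xp = X.copy()
    for r in range(Xp.shape[0]):
        rng.shuffle(Xp[r])
    return Xp


def select_rank(
    X: np.ndarray,
    ranks=range(2, 10),
    beta_grid=(0.01,),
    runs: int = 500,
    n_perm: int = 40,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> RankSelection:
    """Choose the number of clusters against a permutation null.

    For every candidate rank (at its best beta by cophenetic correlation),
    the cophenetic correlation on the data is compared with the upper bound
    of the 95% confidence interval of the mean cophenetic achieved on
    matrices permuted within rows (mean + 1.96 sd / sqrt(n_perm)).  The
    selected rank is the smallest one strictly exceeding its bound; if none
    does, the result is flagged unresolved.
    """
    X = np.asarray(X, dtype=float)
    ranks = list(ranks)
    beta_grid = list(beta_grid)
    ss = np.random.SeedSequence(seed)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    run_seed_pool = ss.generate_state(2 * len(ranks) * len(beta_grid) * (1 + n_perm))
    run_seed_pool = (run_seed_pool % (2 ** 31)).tolist()
    perms = [_permute_within_rows(X, perm_rng) for _ in range(n_perm)]

    real: dict = {}
    perm: dict = {}
    si = 0
    for beta in beta_grid:
        for m in ranks:
            res = consensus_cluster(X, m, beta, runs=runs, seed=run_seed_pool[si],
                                    max_iter=max_iter, tol=tol, keep_best_run=False)
            si += 1
            real[(beta, m)] = res.cophenetic
            vals = []
            for Xp in perms:
                rp = consensus_cluster(Xp, m, beta, runs=runs,
                                       seed=run_seed_pool[si], max_iter=max_iter,
                                       tol=tol, keep_best_run=False)
                si += 1
                vals.append(rp.cophenetic)
            perm[(beta, m)] = vals

    best_beta: dict = {}
    upper: dict = {}
    selected = None
    for m in ranks:
        cands = [(real[(b, m)], b) for b in beta_grid
                 if np.isfinite(real[(b, m)])]
        if not cands:
            continue
        coph, b = max(cands)
        best_beta[m] = b
        vals = np.asarray([v for v in perm[(b, m)] if np.isfinite(v)])
        if vals.size == 0:
            continue
        # 95% CI of the *mean* null cophenetic; a mean + 1.96 sd band over
        # the raw values routinely exceeds 1, which the data cophenetic
        # (capped at 1) could never beat
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        upper[m] = float(vals.mean() + 1.96 * sd / np.sqrt(vals.size))
        if selected is None and coph > upper[m]:
            selected = m
    return RankSelection(ranks, beta_grid, real, perm, best_beta, upper,
                         selected, selected is not None)


# ---------------------------------------------------------------------------
# cluster-descriptive features & evaluation
# ---------------------------------------------------------------------------

def descriptive_features(B: np.ndarray, component: int) -> list[int]:
    """Most descriptive features (rows of B) for one basis component.

    Column values are sorted by decreasing magnitude and the returned
    prefix ends at the largest drop between consecutive sorted values.
    ``component`` is 1-based, matching cluster labels.
    """
    B = np.asarray(B, dtype=float)
    m = B.shape[1]
    if not 1 <= component <= m:
        raise ValueError(f"component {component} out of range [1, {m}]")
    col = B[:, component - 1]
    if np.min(col) < 0:
        raise ValueError("B must be non-negative")
    if np.all(col == 0):
        warnings.warn(f"component {component} is all-zero: no descriptive features")
        return []
    order = np.argsort(-col, kind="stable")
    v = col[order]
    gaps = v[:-1] - v[1:]
    if len(gaps) == 0 or np.all(gaps == 0):
        if len(gaps) > 0:
            warnings.warn(f"component {component} is constant: "
                          "descriptive-feature prefix is non-discriminative")
        return order.tolist()
    cut = int(np.argmax(gaps))
    return order[: cut + 1].tolist()


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (1 = identical up
    to relabeling, ~0 expected under independence)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))
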