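"""Compiled multi-right-hand-side non-negative least squares.

Block-principal-pivoting solver for min_{z>=0} 1/2 z'(A'A)z - z'(A'y),
one small problem per column of AtY with a shared Gram matrix.  Consensus
clustering repeats the factorization hundreds of times, so the per-column
loop is JIT-compiled; linear solves use in-place Gaussian elimination with
partial pivoting and a pivot floor for degenerate (singular) passive sets.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _solve_sub(AtA, rhs, idx, k, out):
    """Solve the k x k passive subsystem into out[idx]; singular pivots
    (below 1e-13 of the largest diagonal) zero the variable."""
    A = np.empty((k, k))
    b = np.empty(k)
    for a in range(k):
        b[a] = rhs[idx[a]]
        for c in range(k):
            A[a, c] = AtA[idx[a], idx[c]]
    scale = 0.0
    for a in range(k):
        if A[a, a] > scale:
            scale = A[a, a]
    floor = 1e-13 * (scale if scale > 0 else 1.0)
    perm = np.empty(k, np.int64)
    for a in range(k):
        perm[a] = a
    for col in range(k):
        piv, pr = -1.0, col
        for r in range(col, k):
            v = abs(A[r, col])
            if v > piv:
                piv, pr = v, r
        if piv <= floor:
            for r in range(k):
                A[r, col] = 0.0
            A[col, col] = 1.0
            b[col] = 0.0
            continue
        if pr != col:
            for c in range(k):
                A[col, c], A[pr, c] = A[pr, c], A[col, c]
            b[col], b[pr] = b[pr], b[col]
        inv = 1.0 / A[col, col]
        for r in range(col + 1, k):
            f = A[r, col] * inv
            if f != 0.0:
                for c in range(col, k):
                    A[r, c] -= f * A[col, c]
                b[r] -= f * b[col]
    for col in range(k - 1, -1, -1):
        acc = b[col]
        for c in range(col + 1, k):
            acc -= A[col, c] * b[c]
        b[col] = acc / A[col, col]
    for a in range(k):
        out[idx[a]] = b[a]


@njit(cache=True)
def bpp_multi(AtA, AtY, passive):
    """Block principal pivoting for every column; ``passive`` is both the
    warm start and the returned active-set state (modified in place)."""
    m, ncol = AtY.shape
    X = np.zeros((m, ncol))
    tol = 1e-12
    x = np.empty(m)
    y = np.empty(m)
    idx = np.empty(m, np.int64)
    infeas = np.empty(m, np.bool_)
    max_it = 10 * m + 100
    for j in range(ncol):
        backup = 3
        best_ninf = m + 1
        for _ in range(max_it):
            k = 0
            for i in range(m):
                x[i] = 0.0
                if passive[i, j]:
                    idx[k] = i
                    k += 1
            if k > 0:
                _solve_sub(AtA, AtY[:, j], idx, k, x)
            for i in range(m):
                acc = -AtY[i, j]
                for c in range(m):
                    acc += AtA[i, c] * x[c]
                y[i] = acc
            ninf = 0
            last = -1
            for i in range(m):
                bad = (passive[i, j] and x[i] < -tol) or \
                      ((not passive[i, j]) and y[i] < -tol)
                infeas[i] = bad
                if bad:
                    ninf += 1
                    last = i
            if ninf == 0:
                break
            if ninf < best_ninf:
                best_ninf = ninf
                backup = 3
                for i in range(m):
                    if infeas[i]:
                        passive[i, j] = not passive[i, j]
            elif backup > 0:
                backup -= 1
                for i in range(m):
                    if infeas[i]:
                        passive[i, j] = not passive[i, j]
            else:  # Murty: flip only the largest infeasible index
                passive[last, j] = not passive[last, j]
        for i in range(m):
            X[i, j] = x[i] if (passive[i, j] and x[i] > 0.0) else 0.0
    return X
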