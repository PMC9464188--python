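"""Exact simplex-constrained least squares.

Solves, independently for every column b of B,

    minimise ||A x - b||^2   subject to   x >= 0,  sum(x) = 1.

The solver enumerates every non-empty support S of the coefficient vector,
solves the sum-to-one equality-constrained least-squares problem on S via
its KKT system, and keeps the feasible candidate with the smallest
residual. The optimal active set is among the enumerated supports, so the
returned solution is the exact global constrained minimiser (up to linear
solver round-off). Enumeration is exponential in the number of columns of
A, which is intended: cell-type deconvolution uses a handful of
compartments (upper limit 15 here).
"""
from __future__ import annotations

import itertools

import numpy as np

_MAX_TYPES = 15
_FEAS_TOL = 1e-9


def simplex_lstsq(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Simplex-constrained least squares, vectorised over columns of B.

    Parameters
    ----------
    A
        (m, k) design matrix, k <= 15.
    B
        (m, n) matrix of right-hand sides (or a length-m vector).

    Returns
    -------
    (k, n) array of coefficients; every column is non-negative and sums
    to one exactly (small negative round-off is clipped and the column
    renormalised).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    squeeze = B.ndim == 1
    if squeeze:
        B = B[:, None]
    m, k = A.shape
    if B.shape[0] != m:
        raise ValueError("A and B have incompatible numbers of rows")
    if k > _MAX_TYPES:
        raise ValueError(
            f"support enumeration not practical for {k} > {_MAX_TYPES} cell types"
        )
    n = B.shape[1]

    AtA = A.T @ A
    AtB = A.T @ B

    best_obj = np.full(n, np.inf)
    X = np.zeros((k, n))

    # smaller supports first => deterministic tie-break toward sparser solutions
    for size in range(1, k + 1):
        for idx in itertools.combinations(range(k), size):
            idx = list(idx)
            s = len(idx)
            M = np.zeros((s + 1, s + 1))
            M[:s, :s] = 2.0 * AtA[np.ix_(idx, idx)]
            M[:s, s] = 1.0
            M[s, :s] = 1.0
            rhs = np.vstack([2.0 * AtB[idx], np.ones((1, n))])
            try:
                sol = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
            Xs = sol[:s]
            feasible = (Xs >= -_FEAS_TOL).all(axis=0)
            if not feasible.any():
                continue
            resid = A[:, idx] @ Xs - B
            obj = np.einsum("ij,ij->j", resid, resid)
            obj = np.where(feasible, obj, np.inf)
            better = obj < best_obj * (1.0 - 1e-12)
            if better.any():
                best_obj = np.where(better, obj, best_obj)
                X[:, better] = 0.0
                X[np.ix_(idx, np.flatnonzero(better))] = Xs[:, better]

    X = np.clip(X, 0.0, None)
    colsum = X.sum(axis=0)
    colsum[colsum == 0.0] = 1.0
    X /= colsum
    return X[:, 0] if squeeze else X
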