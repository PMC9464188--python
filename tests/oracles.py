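"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths they check: exhaustive grid
search over the simplex, combinatorial enumeration for the
hypergeometric tail, arbitrary-precision rational summation for the
binomial tail, and a resampling oracle for the Welch t-test.
"""
from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def simplex_grid(k: int, step: float) -> np.ndarray:
    """All points of the k-simplex on a regular grid with the given step."""
    m = round(1.0 / step)
    if k == 2:
        i = np.arange(m + 1)
        return np.column_stack([i, m - i]) / m
    if k == 3:
        pts = [(i, j, m - i - j) for i in range(m + 1) for j in range(m - i + 1)]
        return np.asarray(pts, dtype=float) / m
    raise ValueError("grid oracle supports 2 or 3 mixture components")


def grid_search_proportions(A: np.ndarray, b: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Exhaustive residual minimisation over the simplex grid."""
    X = simplex_grid(A.shape[1], step)
    best, best_obj = None, np.inf
    for start in range(0, len(X), 100_000):
        chunk = X[start : start + 100_000]
        resid = A @ chunk.T - b[:, None]
        obj = np.einsum("ij,ij->j", resid, resid)
        j = int(obj.argmin())
        if obj[j] < best_obj:
            best_obj, best = float(obj[j]), chunk[j]
    return best


def hypergeom_tail_enumeration(
    universe: set, gene_set: set, de_genes: set
) -> float:
    """P(overlap >= observed) by enumerating every possible DE draw."""
    universe = sorted(universe)
    observed = len(de_genes & gene_set)
    n_de = len(de_genes)
    hits = sum(
        1
        for draw in itertools.combinations(universe, n_de)
        if len(set(draw) & gene_set) >= observed
    )
    return hits / comb(len(universe), n_de)


def binomial_tail_exact(k: int, n: int, p0: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p0), in exact rational arithmetic."""
    q = 1 - p0
    return sum(comb(n, i) * p0**i * q ** (n - i) for i in range(k, n + 1))


def permutation_welch_p(
    a: np.ndarray, b: np.ndarray, n_perm: int = 20_000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for the difference in group means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    na = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= observed - 1e-12:
            count += 1
    return count / n_perm
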