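"""Two-stage constrained deconvolution of bulk expression.

Stage 1 estimates per-sample cell-type proportions by simplex-constrained
least squares of each bulk column on reference cell-type profiles,
restricted to informative (high between-type contrast) genes. Stage 2
estimates per-gene cell-type-intrinsic expression by non-negative least
squares of each bulk gene row on the proportion matrix across samples,
with standard errors from the ordinary-least-squares covariance formula.
``deconvolve`` alternates the two stages from an initial reference until
the residual sum of squares converges, then re-estimates profiles on all
genes — the EDec-style reference-initialised refinement.

All fitting happens in linear expression space: mixing is linear in
transcript abundance, so log-scale input must be converted first
(``ExpressionMatrix.to_linear``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._lsq import simplex_lstsq
from .containers import (
    LINEAR,
    SIMPLEX,
    CellTypeProfiles,
    ExpressionMatrix,
    ProportionMatrix,
)

DEFAULT_K_INFORMATIVE = 1000
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


@dataclass
class DeconvolutionFit:
    """Result of the alternating two-stage fit."""

    proportions: ProportionMatrix
    profiles: CellTypeProfiles
    informative_genes: list[str]
    n_iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        trace = np.asarray(self.objective_trace)
        if len(trace) > 1:
            slack = 1e-9 * max(trace.max(), 1.0)
            if (np.diff(trace) > slack).any():
                raise ValueError("objective trace is not non-increasing")


def _require_linear(bulk: ExpressionMatrix) -> None:
    if bulk.scale != LINEAR:
        raise ValueError(
            "deconvolution operates on linear-scale expression; "
            "call ExpressionMatrix.to_linear() first"
        )


def select_informative_features(
    bulk: ExpressionMatrix,
    references: CellTypeProfiles,
    k: int,
    min_contrast_ratio: float = 0.0,
) -> list[str]:
    """Top-k genes by between-cell-type contrast in the references.

    The contrast score is the coefficient of variation of a gene's value
    across reference cell types (between-type spread over mean level, the
    mean acting as a noise proxy: high-expression genes need a larger
    absolute spread to count as discriminative). Only genes shared with
    the bulk matrix compete. Ties break lexicographically by gene
    identifier, so the selection is deterministic.

    ``min_contrast_ratio`` additionally drops selected genes whose score
    falls below that fraction of the median score of the strongest genes
    (top min(k, 50)). With 0 the selection is a pure top-k; a positive
    value keeps the list from being padded with genes whose apparent
    contrast is indistinguishable from noise when fewer than ``k``
    genuinely discriminative genes exist.
    """
    shared = references.gene_ids.intersection(bulk.gene_ids)
    if len(shared) == 0:
        raise ValueError("no genes shared between bulk and references")
    if k > len(shared):
        raise ValueError(f"k={k} exceeds {len(shared)} shared genes")

    vals = references.values.loc[shared].to_numpy()
    mean = vals.mean(axis=1)
    spread = vals.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(mean > 0, spread / mean, 0.0)
    if score.max() <= 1e-12:
        raise ValueError(
            "degenerate references: no between-cell-type contrast on shared genes"
        )

    ranked = sorted(zip(shared, score), key=lambda gs: (-gs[1], gs[0]))
    top = ranked[:k]
    if min_contrast_ratio > 0.0:
        head = [s for _, s in top[: min(k, 50)]]
        floor = min_contrast_ratio * float(np.median(head))
        kept = [(g, s) for g, s in top if s >= floor]
        # never fall below a workable design: keep at least the strongest genes
        minimum = min(len(top), max(10, 2 * references.n_cell_types))
        top = kept if len(kept) >= minimum else top[:minimum]
    return [g for g, _ in top]


def estimate_proportions(
    bulk: ExpressionMatrix,
    profiles: CellTypeProfiles,
    genes: list[str] | None = None,
) -> ProportionMatrix:
    """Stage 1: per-sample simplex-constrained least squares.

    Each bulk column (restricted to ``genes``) is regressed on the profile
    columns subject to non-negativity and sum-to-one; the exact
    constrained minimiser is returned (see :mod:`pdxmatch._lsq`).
    """
    _require_linear(bulk)
    if profiles.n_cell_types < 2:
        raise ValueError("need at least two cell types")
    if genes is None:
        genes = list(profiles.gene_ids.intersection(bulk.gene_ids))
        if not genes:
            raise ValueError("no genes shared between bulk and profiles")
    A = profiles.values.loc[genes].to_numpy()
    if np.linalg.matrix_rank(A) < profiles.n_cell_types:
        warnings.warn(
            "rank-deficient profile submatrix; proportions may be non-unique",
            stacklevel=2,
        )

    data = bulk.data.loc[genes]
    keep = data.to_numpy().sum(axis=0) > 0.0
    if not keep.all():
        dropped = list(bulk.sample_ids[~keep])
        warnings.warn(f"dropping all-zero samples: {dropped}", stacklevel=2)
        data = data.loc[:, keep]

    X = simplex_lstsq(A, data.to_numpy())
    df = pd.DataFrame(X.T, index=data.columns, columns=profiles.cell_types)
    return ProportionMatrix(df, row_constraint=SIMPLEX)


def estimate_profiles(
    bulk: ExpressionMatrix, proportions: ProportionMatrix
) -> CellTypeProfiles:
    """Stage 2: per-gene non-negative least squares across samples.

    For gene g, solves min ||P x_g - y_g||^2 over x_g >= 0, where P is
    the samples x cell-types proportion matrix and y_g the bulk row.
    Standard errors come from the unconstrained OLS covariance,
    s_g^2 (P'P)^-1, with the residual variance s_g^2 = RSS_g / (n - K);
    entries clipped at the non-negativity bound keep the same formula and
    are flagged in ``at_bound``.
    """
    _require_linear(bulk)
    samples = proportions.sample_ids
    missing = samples.difference(bulk.sample_ids)
    if len(missing):
        raise ValueError(f"proportion samples absent from bulk: {list(missing)[:5]}")
    P = proportions.data.loc[samples].to_numpy()
    n, K = P.shape
    if n <= K:
        raise ValueError(
            f"under-determined: {n} samples for {K} cell types (need more samples)"
        )

    Y = bulk.data.loc[:, samples].to_numpy()
    G = Y.shape[0]
    gram = P.T @ P
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        warnings.warn("singular proportion design; using pseudo-inverse", stacklevel=2)
        gram_inv = np.linalg.pinv(gram)
    diag = np.clip(np.diag(gram_inv), 0.0, None)

    values = np.empty((G, K))
    rss = np.empty(G)
    for gi in range(G):
        x, rnorm = nnls(P, Y[gi])
        values[gi] = x
        rss[gi] = rnorm * rnorm

    s2 = rss / (n - K)
    stderr = np.sqrt(np.outer(s2, diag))
    at_bound = values == 0.0

    idx = bulk.gene_ids
    cols = proportions.data.columns
    return CellTypeProfiles(
        values=pd.DataFrame(values, index=idx, columns=cols),
        stderr=pd.DataFrame(stderr, index=idx, columns=cols),
        at_bound=pd.DataFrame(at_bound, index=idx, columns=cols),
        n_samples=n,
    )


def deconvolve(
    bulk: ExpressionMatrix,
    initial_profiles: CellTypeProfiles,
    k: int = DEFAULT_K_INFORMATIVE,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    min_contrast_ratio: float = 0.25,
) -> DeconvolutionFit:
    """Alternating two-stage deconvolution from an initial reference.

    Iterates Stage 1 and Stage 2 on the informative-gene submatrix until
    the relative change of the residual sum of squares falls below
    ``tol`` (or ``max_iter`` alternations). Because each half-step solves
    its constrained subproblem exactly, the objective is monotone
    non-increasing. The converged proportions are then used for a final
    Stage-2 fit on all genes.

    The informative set is the top-k contrast genes filtered by
    ``min_contrast_ratio`` (see :func:`select_informative_features`).
    The filter matters for the refinement's identifiability: alternating
    updates on genes without real between-type contrast let the
    factorisation absorb cell-type-extrinsic expression heterogeneity
    (e.g. distinct cancer-cell states) into the proportion estimates,
    drifting away from the reference-anchored solution even as the
    residual keeps improving. Set it to 0 for a pure top-k selection.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    _require_linear(bulk)

    shared = initial_profiles.gene_ids.intersection(bulk.gene_ids)
    genes = select_informative_features(
        bulk, initial_profiles, min(k, len(shared)),
        min_contrast_ratio=min_contrast_ratio,
    )

    data = bulk.data
    keep = data.to_numpy().sum(axis=0) > 0.0
    if not keep.all():
        dropped = list(bulk.sample_ids[~keep])
        warnings.warn(f"dropping all-zero samples: {dropped}", stacklevel=2)
        bulk = ExpressionMatrix(data.loc[:, keep], scale=LINEAR)

    bulk_sel = ExpressionMatrix(bulk.data.loc[genes], scale=LINEAR)
    profiles_sel = initial_profiles.restrict(genes)

    trace: list[float] = []
    converged = False
    proportions: ProportionMatrix | None = None
    scale = float(np.square(bulk_sel.data.to_numpy()).sum()) or 1.0

    for _ in range(max_iter):
        proportions = estimate_proportions(bulk_sel, profiles_sel, genes)
        profiles_sel = estimate_profiles(bulk_sel, proportions)
        resid = (
            bulk_sel.data.to_numpy()
            - profiles_sel.values.to_numpy() @ proportions.data.to_numpy().T
        )
        obj = float(np.square(resid).sum())
        if trace:
            rel = abs(trace[-1] - obj) / max(trace[-1], 1e-300)
            trace.append(obj)
            if rel < tol:
                converged = True
                break
        else:
            trace.append(obj)
            if obj <= 1e-24 * scale:
                converged = True
                break

    assert proportions is not None
    profiles_all = estimate_profiles(bulk, proportions)
    return DeconvolutionFit(
        proportions=proportions,
        profiles=profiles_all,
        informative_genes=genes,
        n_iterations=len(trace),
        converged=converged,
        objective_trace=trace,
    )
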