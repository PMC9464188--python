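"""Signature-based immune cell-fraction estimation.

A quanTIseq-style step: given a marker-gene x immune-cell-type signature
matrix (TIL10-like, supplied by the user — the real signature is not
bundled), each bulk sample's expression over the signature genes is
decomposed by constrained least squares into non-negative immune
fractions plus an explicit uncharacterised remainder ("other"), modelled
as a pseudo-cell-type whose signature is the per-gene median of the bulk
cohort. Immune fractions and the remainder live on the unit simplex, so
the named fractions sum to at most one.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from ._lsq import simplex_lstsq
from .containers import (
    LINEAR,
    OTHER,
    SUB_SIMPLEX,
    ExpressionMatrix,
    ProportionMatrix,
)

#: immune marker panel used for heatmap-style expression summaries
DEFAULT_MARKER_PANEL: dict[str, tuple[str, ...]] = {
    "Tregs": ("FOXP3", "CTLA4", "HPGD", "IKZF2"),
    "CD4 T cells": ("GZMB", "NKG7", "CD40LG"),
    "M2 macrophages": ("CD163",),
    "M1 macrophages": ("CD68", "CD86"),
    "B cells": ("MS4A1",),
}


@dataclass
class SignatureMatrix:
    """Marker genes x immune cell types signature.

    Invariants: non-negative, no all-zero rows or columns, and every cell
    type has at least one marker gene whose maximal value is in that type.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size == 0:
            raise ValueError("empty signature matrix")
        if (vals < 0).any():
            raise ValueError("signature values must be non-negative")
        if (vals.sum(axis=1) == 0).any():
            raise ValueError("signature contains an all-zero marker gene row")
        if (vals.sum(axis=0) == 0).any():
            raise ValueError("signature contains an all-zero cell-type column")
        argmax = vals.argmax(axis=1)
        missing = [
            ct for j, ct in enumerate(self.data.columns) if not (argmax == j).any()
        ]
        if missing:
            raise ValueError(
                f"cell types without a maximal marker gene: {missing}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


def load_marker_panel(path) -> dict[str, tuple[str, ...]]:
    """Read a marker panel from a YAML mapping of group -> gene list."""
    raw = yaml.safe_load(open(path))
    panel = {str(k): tuple(map(str, v)) for k, v in raw.items()}
    _validate_panel(panel)
    return panel


def _validate_panel(panel) -> None:
    seen: set[str] = set()
    for genes in panel.values():
        for g in genes:
            if g in seen:
                raise ValueError(f"gene {g!r} appears twice in the marker panel")
            seen.add(g)


def estimate_immune_fractions(
    bulk: ExpressionMatrix, signature: SignatureMatrix
) -> ProportionMatrix:
    """Per-sample immune fractions with an explicit 'other' remainder.

    Solves, for each sample, non-negative least squares of the bulk
    sub-vector over the shared signature genes on the signature columns
    plus the background pseudo-type, constrained to the unit simplex. The
    background (``other``) column is the per-gene median of the bulk
    cohort over the signature genes, which makes the non-immune remainder
    explicit rather than absorbing it into the immune coefficients.
    """
    if bulk.scale != LINEAR:
        raise ValueError("bulk must be linear scale; call to_linear() first")
    shared = [g for g in signature.gene_ids if g in bulk.gene_ids]
    if not shared:
        raise ValueError("no signature genes found in the bulk matrix")
    coverage = len(shared) / len(signature.gene_ids)
    if coverage < 0.30:
        warnings.warn(
            f"only {coverage:.0%} of signature genes found in bulk",
            stacklevel=2,
        )

    S = signature.data.loc[shared].to_numpy()
    B = bulk.data.loc[shared].to_numpy()
    background = np.median(B, axis=1)
    A = np.column_stack([S, background])

    X = simplex_lstsq(A, B)  # (K+1) x n

    # a sample with zero signature expression has no immune evidence at all
    zero = B.sum(axis=0) == 0.0
    if zero.any():
        X[:, zero] = 0.0
        X[-1, zero] = 1.0

    df = pd.DataFrame(
        X.T,
        index=bulk.sample_ids,
        columns=[*signature.cell_types, OTHER],
    )
    return ProportionMatrix(df, row_constraint=SUB_SIMPLEX)


def total_immune_fraction(proportions: ProportionMatrix) -> pd.Series:
    """Per-sample total immune infiltration: sum of all non-'other' fractions."""
    cols = [c for c in proportions.data.columns if c != OTHER]
    total = proportions.data[cols].sum(axis=1)
    total.name = "total_immune_fraction"
    return total


@dataclass
class MarkerTable:
    """Marker-panel expression for heatmap export.

    ``values`` has a (panel group, gene) row MultiIndex and samples
    ordered by group label then identifier; entries are log2(x + 1) for
    display. ``missing`` lists panel genes absent from the bulk matrix.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    missing: list[str]


def marker_expression_table(
    bulk: ExpressionMatrix,
    panel: dict[str, tuple[str, ...]] | None = None,
    group_labels: pd.Series | None = None,
) -> MarkerTable:
    """Panel-gene expression with samples grouped for heatmap export."""
    panel = DEFAULT_MARKER_PANEL if panel is None else panel
    _validate_panel(panel)
    lin = bulk.to_linear()

    rows, row_index, missing = [], [], []
    for group, genes in panel.items():
        for g in genes:
            if g in lin.gene_ids:
                rows.append(np.log2(lin.data.loc[g].to_numpy() + 1.0))
                row_index.append((group, g))
            else:
                missing.append(g)
    if not rows:
        raise ValueError("no marker panel genes found in the bulk matrix")

    table = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(row_index, names=["group", "gene_id"]),
        columns=lin.sample_ids,
    )
    if group_labels is None:
        group_labels = pd.Series("all", index=lin.sample_ids)
    group_labels = group_labels.reindex(lin.sample_ids)
    order = sorted(lin.sample_ids, key=lambda s: (str(group_labels[s]), str(s)))
    return MarkerTable(
        values=table[order],
        sample_groups=group_labels[order],
        missing=missing,
    )
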