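"""Core data containers shared across the pipeline.

All matrices are pandas DataFrames with explicit identifier axes:
expression is genes x samples, proportions are samples x cell types,
cell-type profiles are genes x cell types. Containers validate their
invariants on construction so downstream code can assume them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2P1 = "log2p1"

SIMPLEX = "simplex"
SUB_SIMPLEX = "sub_simplex_with_other"

#: column name of the uncharacterised (non-immune) remainder compartment
OTHER = "other"

_SIMPLEX_TOL = 1e-6


def _first_negative(df: pd.DataFrame) -> tuple[str, str] | None:
    vals = df.to_numpy()
    bad = np.argwhere(vals < 0)
    if bad.size == 0:
        return None
    i, j = bad[0]
    return str(df.index[i]), str(df.columns[j])


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples expression matrix.

    Parameters
    ----------
    data
        DataFrame with unique gene identifiers as the index and unique
        sample identifiers as columns. Values must be non-negative and
        complete (no NaN).
    scale
        ``"linear"`` for transcript-abundance-proportional values or
        ``"log2p1"`` for log2(x + 1)-transformed values. Mixing is linear
        in abundance, so deconvolution requires linear scale; use
        :meth:`to_linear` to convert.
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2P1):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        if self.data.isna().to_numpy().any():
            raise ValueError("expression matrix contains missing values")
        loc = _first_negative(self.data)
        if loc is not None:
            raise ValueError(
                f"negative expression value at gene {loc[0]!r}, sample {loc[1]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy; log2(x+1) values are inverted as 2**x - 1."""
        if self.scale == LINEAR:
            return self
        return ExpressionMatrix(np.power(2.0, self.data) - 1.0, scale=LINEAR)

    def to_log2p1(self) -> "ExpressionMatrix":
        if self.scale == LOG2P1:
            return self
        return ExpressionMatrix(np.log2(self.data + 1.0), scale=LOG2P1)


@dataclass
class ProportionMatrix:
    """Samples x cell-type fraction matrix on the unit simplex.

    With ``row_constraint="simplex"`` the columns are cell types and every
    row sums to one. With ``row_constraint="sub_simplex_with_other"`` the
    matrix carries an explicit ``"other"`` column holding the remainder, so
    rows including ``other`` still sum to one while the named cell-type
    fractions sum to at most one.
    """

    data: pd.DataFrame
    row_constraint: str = SIMPLEX

    def __post_init__(self) -> None:
        if self.row_constraint not in (SIMPLEX, SUB_SIMPLEX):
            raise ValueError(f"unknown row constraint {self.row_constraint!r}")
        if self.row_constraint == SUB_SIMPLEX and OTHER not in self.data.columns:
            raise ValueError("sub-simplex proportions require an 'other' column")
        vals = self.data.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("proportions contain missing values")
        if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
            raise ValueError("proportions outside [0, 1]")
        sums = vals.sum(axis=1)
        if np.abs(sums - 1.0).max() > _SIMPLEX_TOL:
            worst = self.data.index[int(np.abs(sums - 1.0).argmax())]
            raise ValueError(f"proportion row {worst!r} does not sum to 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> list[str]:
        """Named cell types (excludes the 'other' remainder)."""
        return [c for c in self.data.columns if c != OTHER]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


@dataclass
class CellTypeProfiles:
    """Genes x cell-type intrinsic expression profiles.

    ``stderr`` carries per-entry standard errors when the profiles were
    estimated (Stage 2); reference or archetype profiles may omit it.
    ``at_bound`` flags entries whose non-negativity constraint was active
    in the fit (the estimate was clipped at zero). ``n_samples`` records
    the number of samples the fit used, needed downstream for the
    degrees of freedom of profile-contrast t-tests.
    """

    values: pd.DataFrame
    stderr: pd.DataFrame | None = None
    at_bound: pd.DataFrame | None = None
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("cell-type profiles must be non-negative")
        for name, df in (("stderr", self.stderr), ("at_bound", self.at_bound)):
            if df is not None and (
                not df.index.equals(self.values.index)
                or not df.columns.equals(self.values.columns)
            ):
                raise ValueError(f"{name} not aligned with profile values")
        if self.stderr is not None and (self.stderr.to_numpy() < 0).any():
            raise ValueError("standard errors must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]

    def column(self, cell_type: str) -> pd.Series:
        if cell_type not in self.values.columns:
            raise KeyError(f"cell type {cell_type!r} not in profiles")
        return self.values[cell_type]

    def restrict(self, gene_ids) -> "CellTypeProfiles":
        """Profiles restricted to ``gene_ids`` (order preserved)."""
        return CellTypeProfiles(
            values=self.values.loc[gene_ids],
            stderr=None if self.stderr is None else self.stderr.loc[gene_ids],
            at_bound=None if self.at_bound is None else self.at_bound.loc[gene_ids],
            n_samples=self.n_samples,
        )
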