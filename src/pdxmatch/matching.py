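"""PDX cancer-cell archetype matching and the engraftment-bias test.

Each xenograft cancer-cell expression profile is correlated (Pearson, on
log2(x+1) values over a shared gene set) against the hot and cold
cancer-cell archetype profiles; the ratio r_cold / r_hot assigns the
model to an archetype (ratio > 1 means cold; an exact tie counts as hot,
the conservative direction). The cohort-level excess of cold matches is
tested with an exact binomial test against the null that a fraction p0
(default 0.64, the cold/basal share expected if xenografts sampled the
primary tumour population without bias) of models match the cold profile.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellTypeProfiles, ExpressionMatrix

MIN_GENES = 50
DEFAULT_P0 = 0.64


def _cancer_series(profile, cancer_type: str = "cancer") -> pd.Series:
    if isinstance(profile, CellTypeProfiles):
        return profile.column(cancer_type)
    if isinstance(profile, pd.Series):
        return profile
    raise TypeError("archetype profile must be CellTypeProfiles or pandas Series")


def correlate_to_archetypes(
    pdx: ExpressionMatrix,
    hot_profile,
    cold_profile,
    gene_subset=None,
    cancer_type: str = "cancer",
    min_genes: int = MIN_GENES,
) -> pd.DataFrame:
    """Pearson correlation of each PDX column with both archetypes.

    Values are log2(x+1)-transformed before correlating; the same shared
    gene set (intersection of PDX genes, both archetypes, and the
    optional subset) is used against both archetypes. Fewer than
    ``min_genes`` shared genes is an error, as is a zero-variance PDX
    column (its correlation is undefined).
    """
    hot = _cancer_series(hot_profile, cancer_type)
    cold = _cancer_series(cold_profile, cancer_type)
    lin = pdx.to_linear()

    shared = lin.gene_ids.intersection(hot.index).intersection(cold.index)
    if gene_subset is not None:
        shared = shared.intersection(pd.Index(gene_subset))
    if len(shared) < min_genes:
        raise ValueError(
            f"only {len(shared)} shared genes; need at least {min_genes} to correlate"
        )

    X = np.log2(lin.data.loc[shared].to_numpy() + 1.0)  # genes x samples
    h = np.log2(hot.loc[shared].to_numpy() + 1.0)
    c = np.log2(cold.loc[shared].to_numpy() + 1.0)

    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    zero_var = sx == 0.0
    if zero_var.any():
        bad = list(lin.sample_ids[zero_var])
        raise ValueError(f"zero-variance PDX columns (correlation undefined): {bad}")

    def corr(v: np.ndarray) -> np.ndarray:
        vc = v - v.mean()
        sv = np.sqrt((vc**2).sum())
        if sv == 0.0:
            raise ValueError("zero-variance archetype profile on the shared genes")
        return (Xc * vc[:, None]).sum(axis=0) / (sx * sv)

    return pd.DataFrame(
        {"r_hot": corr(h), "r_cold": corr(c), "n_genes_used": len(shared)},
        index=lin.sample_ids,
    )


def classify_pdx(correlations: pd.DataFrame) -> pd.DataFrame:
    """Assign hot/cold labels from the correlation pair.

    When both correlations are positive the ratio r_cold / r_hot decides
    (cold iff ratio > 1; a tie is hot). When the signs differ the
    positive correlation wins and the ratio is undefined (NaN). When both
    are non-positive the less negative correlation wins, again with an
    undefined ratio.
    """
    r_hot = correlations["r_hot"].to_numpy()
    r_cold = correlations["r_cold"].to_numpy()

    both_pos = (r_hot > 0) & (r_cold > 0)
    ratio = np.where(both_pos, r_cold / np.where(r_hot > 0, r_hot, 1.0), np.nan)
    label = np.where(
        both_pos,
        np.where(ratio > 1.0, "cold", "hot"),
        np.where(r_cold > r_hot, "cold", "hot"),
    )

    out = correlations.copy()
    out["ratio"] = ratio
    out["label"] = label
    return out


@dataclass
class BiasTestResult:
    """Exact binomial test of the cold-match count."""

    k_cold: int
    n: int
    p0: float
    alternative: str
    p_value: float


def engraftment_bias_test(
    k_cold: int,
    n: int,
    p0: float = DEFAULT_P0,
    alternative: str = "greater",
) -> BiasTestResult:
    """Exact binomial test of k_cold successes in n trials against p0.

    ``greater`` sums the binomial probability mass function from k_cold
    to n directly (no normal approximation); ``two_sided`` uses the
    minimum-likelihood rule, summing the mass of every outcome no more
    likely than the observed one.
    """
    if not (0 <= k_cold <= n) or n <= 0:
        raise ValueError(f"invalid counts: k_cold={k_cold}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must lie strictly in (0, 1), got {p0}")
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    def pmf(i: int) -> float:
        return math.comb(n, i) * p0**i * (1.0 - p0) ** (n - i)

    if alternative == "greater":
        p = sum(pmf(i) for i in range(k_cold, n + 1))
    else:
        observed = pmf(k_cold)
        p = sum(pmf(i) for i in range(n + 1) if pmf(i) <= observed * (1.0 + 1e-7))
    return BiasTestResult(
        k_cold=k_cold, n=n, p0=p0, alternative=alternative, p_value=min(p, 1.0)
    )


@dataclass
class MatchHistogram:
    """Binned correlation ratios with the hot/cold split.

    ``counts`` has one row per bin with separate hot and cold columns;
    matches whose ratio is undefined (mixed or non-positive correlation
    signs) are tallied per label in ``overflow``. ``cold_share_percent``
    is the cohort-level cold share rounded to the nearest integer.
    """

    bin_edges: np.ndarray
    counts: pd.DataFrame
    overflow: dict[str, int]
    n: int
    n_cold: int
    cold_share_percent: int


def match_histogram(matches: pd.DataFrame, n_bins: int = 20) -> MatchHistogram:
    """Histogram of correlation ratios, split by assigned label."""
    defined = matches["ratio"].notna()
    if not defined.any():
        raise ValueError("no matches with a defined correlation ratio")
    ratios = matches.loc[defined, "ratio"]
    edges = np.histogram_bin_edges(ratios.to_numpy(), bins=n_bins)

    counts = {}
    for label in ("hot", "cold"):
        vals = ratios[matches.loc[defined, "label"] == label].to_numpy()
        counts[label], _ = np.histogram(vals, bins=edges)
    overflow = (
        matches.loc[~defined, "label"].value_counts().reindex(["hot", "cold"], fill_value=0)
    )

    n = len(matches)
    n_cold = int((matches["label"] == "cold").sum())
    return MatchHistogram(
        bin_edges=edges,
        counts=pd.DataFrame(counts),
        overflow={"hot": int(overflow["hot"]), "cold": int(overflow["cold"])},
        n=n,
        n_cold=n_cold,
        cold_share_percent=int(round(100.0 * n_cold / n)),
    )


def select_match_genes(
    de_result: pd.DataFrame | None,
    hot_profile,
    cold_profile,
    cancer_type: str = "cancer",
    min_genes: int = MIN_GENES,
) -> list[str] | None:
    """Gene subset for archetype correlation.

    Prefers the differentially expressed genes (maximal archetype
    contrast) when at least ``min_genes`` of them pass; otherwise returns
    None, meaning all shared genes.
    """
    if de_result is None:
        return None
    passing = de_result.index[de_result["passes"]].tolist()
    return passing if len(passing) >= min_genes else None
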