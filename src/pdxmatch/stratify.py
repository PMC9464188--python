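"""Hot/cold immune stratification, differential expression, enrichment.

Tumours are ranked by immune fraction and the bottom and top quartiles
labelled cold and hot. Cancer-cell-intrinsic profiles are then estimated
separately per group (Stage-2 deconvolution on the group's samples), and
genes differing at least 5-fold between the two cancer profiles at
p < 0.05 (Welch t on the Stage-2 standard errors) are called
differentially expressed. Gene-set over-representation among the DE genes
uses the upper-tail hypergeometric test; group differences in immune
cell-type fractions use two-sided Welch t-tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    OTHER,
    CellTypeProfiles,
    ExpressionMatrix,
    ProportionMatrix,
)
from .deconvolution import estimate_profiles

COLD, HOT, INTERMEDIATE = "cold", "hot", "intermediate"

DEFAULT_FOLD_THRESHOLD = 5.0
DEFAULT_ALPHA = 0.05
#: pseudo-value guarding fold-change division by zero (one linear unit)
FOLD_EPS = 1.0


@dataclass
class HotColdPartition:
    """Quartile partition of samples by immune fraction."""

    labels: pd.Series  # values in {hot, cold, intermediate}
    cold_threshold: float
    hot_threshold: float
    source: str = "edec_stage1"

    def __post_init__(self) -> None:
        if self.cold_threshold > self.hot_threshold:
            raise ValueError("cold_threshold must be <= hot_threshold")
        bad = set(self.labels.unique()) - {HOT, COLD, INTERMEDIATE}
        if bad:
            raise ValueError(f"unknown partition labels: {bad}")

    def samples(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def partition_hot_cold(
    immune_fractions: pd.Series,
    lower_q: float = 0.25,
    upper_q: float = 0.75,
    source: str = "edec_stage1",
) -> HotColdPartition:
    """Label the bottom ``lower_q`` of samples cold and the top ``1-upper_q`` hot.

    Samples are ranked by immune fraction with ties broken by sample
    identifier; exactly floor(n * lower_q) samples are labelled cold and
    floor(n * (1 - upper_q)) hot, the remainder intermediate.
    """
    n = len(immune_fractions)
    if n < 8:
        raise ValueError(f"need >= 8 samples for quartile stratification, got {n}")
    if not (0.0 < lower_q <= upper_q < 1.0):
        raise ValueError("require 0 < lower_q <= upper_q < 1")

    order = sorted(immune_fractions.index, key=lambda s: (immune_fractions[s], str(s)))
    n_cold = math.floor(n * lower_q)
    n_hot = math.floor(n * (1.0 - upper_q))

    labels = pd.Series(INTERMEDIATE, index=immune_fractions.index, name="label")
    cold_ids = order[:n_cold]
    hot_ids = order[n - n_hot :] if n_hot else []
    labels[cold_ids] = COLD
    labels[hot_ids] = HOT
    cold_threshold = float(immune_fractions[cold_ids[-1]]) if n_cold else float("-inf")
    hot_threshold = float(immune_fractions[hot_ids[0]]) if n_hot else float("inf")
    return HotColdPartition(
        labels=labels,
        cold_threshold=cold_threshold,
        hot_threshold=max(hot_threshold, cold_threshold),
        source=source,
    )


def groupwise_cancer_profiles(
    bulk: ExpressionMatrix,
    proportions: ProportionMatrix,
    partition: HotColdPartition,
) -> tuple[CellTypeProfiles, CellTypeProfiles]:
    """Stage-2 profiles estimated independently on hot and cold samples.

    Intermediate samples contribute to neither estimate. Returns
    (hot, cold); each carries standard errors and its group size.
    """
    out = []
    k = len(proportions.data.columns)
    for label in (HOT, COLD):
        ids = partition.samples(label)
        if len(ids) <= k:
            raise ValueError(
                f"{label} group has {len(ids)} samples, need more than {k} cell types"
            )
        sub_props = ProportionMatrix(
            proportions.data.loc[ids], row_constraint=proportions.row_constraint
        )
        sub_bulk = ExpressionMatrix(bulk.data.loc[:, ids], scale=bulk.scale)
        out.append(estimate_profiles(sub_bulk, sub_props))
    return out[0], out[1]


def differential_expression(
    hot: CellTypeProfiles,
    cold: CellTypeProfiles,
    cancer_type: str = "cancer",
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Gene-level contrast of the hot vs cold cancer-cell profiles.

    fold_change = (hot + 1) / (cold + 1) in linear units (the pseudo-value
    guards division by zero); the t statistic is the profile difference
    over the combined Stage-2 standard error with Welch-Satterthwaite
    degrees of freedom from the two group fits. A gene passes when the
    fold change is at least ``fold_threshold`` in either direction and
    p < ``alpha`` (raw p-values by default; ``fdr=True`` adds a
    Benjamini-Hochberg ``q_value`` column and gates ``passes`` on it).
    """
    for name, prof in (("hot", hot), ("cold", cold)):
        if prof.stderr is None:
            raise ValueError(f"{name} profiles carry no standard errors")
        if prof.n_samples is None:
            raise ValueError(f"{name} profiles carry no sample count")
    genes = hot.gene_ids.intersection(cold.gene_ids)
    if len(genes) == 0:
        raise ValueError("no genes shared between hot and cold profiles")

    h = hot.values.loc[genes, cancer_type].to_numpy()
    c = cold.values.loc[genes, cancer_type].to_numpy()
    se_h = hot.stderr.loc[genes, cancer_type].to_numpy()
    se_c = cold.stderr.loc[genes, cancer_type].to_numpy()
    df_h = hot.n_samples - hot.n_cell_types
    df_c = cold.n_samples - cold.n_cell_types
    if df_h <= 0 or df_c <= 0:
        raise ValueError("non-positive degrees of freedom in group fits")

    var = se_h**2 + se_c**2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(var > 0, (h - c) / np.sqrt(var), 0.0)
        df = np.where(
            var > 0,
            var**2 / (se_h**4 / df_h + se_c**4 / df_c + 1e-300),
            1.0,
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero combined SE: identical estimates -> no evidence; differing -> certain
    p = np.where(var > 0, p, np.where(h == c, 1.0, 0.0))

    fold = (h + FOLD_EPS) / (c + FOLD_EPS)
    big_fold = (fold >= fold_threshold) | (fold <= 1.0 / fold_threshold)

    result = pd.DataFrame(
        {"fold_change": fold, "t_statistic": t, "p_value": p},
        index=genes,
    )
    if fdr:
        result["q_value"] = multipletests(p, method="fdr_bh")[1]
        result["passes"] = big_fold & (result["q_value"].to_numpy() < alpha)
    else:
        result["passes"] = big_fold & (p < alpha)
    return result


@dataclass
class EnrichmentRecord:
    """Hypergeometric over-representation of one gene set."""

    set_size: int
    de_overlap: int
    p_value: float
    universe_size: int
    n_de: int


def enrichment_test(
    de_genes: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentRecord:
    """Upper-tail hypergeometric test P(X >= overlap).

    Drawing ``|de_genes|`` genes without replacement from a universe
    containing ``|gene_set|`` successes; both inputs are intersected with
    the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty enrichment universe")
    de = set(de_genes) & universe
    gs = set(gene_set) & universe
    overlap = len(de & gs)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(gs), len(de)))
    return EnrichmentRecord(
        set_size=len(gs),
        de_overlap=overlap,
        p_value=p,
        universe_size=len(universe),
        n_de=len(de),
    )


def enrichment_table(
    de_genes: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Run :func:`enrichment_test` for every named gene set."""
    universe = set(universe)
    rows = {
        name: vars(enrichment_test(de_genes, genes, universe))
        for name, genes in collections.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_set"
    return out.sort_values("p_value")


def compare_group_proportions(
    immune_props: ProportionMatrix,
    groups: HotColdPartition | pd.Series,
    include_other: bool = False,
) -> pd.DataFrame:
    """Two-sided Welch t-test of cell-type fractions between two groups.

    ``groups`` is either a hot/cold partition (intermediate samples are
    dropped) or any binary label series — e.g. engrafted vs not. Returns
    one row per cell type with group means, t statistic, and p-value.
    """
    if isinstance(groups, HotColdPartition):
        labels = groups.labels[groups.labels.isin([HOT, COLD])]
    else:
        labels = groups.dropna()
    labels = labels[labels.index.isin(immune_props.sample_ids)]
    names = sorted(map(str, labels.unique()))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    a_ids = labels.index[labels.astype(str) == names[0]]
    b_ids = labels.index[labels.astype(str) == names[1]]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs at least 2 samples")

    cols = [c for c in immune_props.data.columns if include_other or c != OTHER]
    rows = {}
    for ct in cols:
        a = immune_props.data.loc[a_ids, ct].to_numpy()
        b = immune_props.data.loc[b_ids, ct].to_numpy()
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            # no within-group variance: identical means carry no evidence
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows[ct] = {
            f"mean_{names[0]}": a.mean(),
            f"mean_{names[1]}": b.mean(),
            "t_statistic": float(t),
            "p_value": float(p),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cell_type"
    return out
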