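"""Ground-truth cohort simulation.

Emulates the generative structure that reference-based deconvolution
assumes: each bulk tumour is a convex mixture of cell-type-intrinsic
expression profiles with Dirichlet-distributed proportions, multiplied by
i.i.d. log-normal noise. Two cancer-cell archetypes ("hot" and "cold")
differ in a planted gene set; an immune-fraction gradient separates hot
from cold samples; PDX-like profiles are noisy copies of one archetype
with no immune or stromal content (ideal post-separation purity, as after
human/mouse read splitting).

Every generator is deterministic under a fixed ``SimulationConfig.seed``;
independent named substreams keep the reference profiles, archetypes,
cohort draw, and PDX draw individually reproducible.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    SIMPLEX,
    CellTypeProfiles,
    ExpressionMatrix,
    ProportionMatrix,
)
from .immune import SignatureMatrix

_STREAMS = {"references": 0, "archetypes": 1, "cohort": 2, "pdx": 3, "signature": 4}

#: quanTIseq-style ten immune cell types used for the synthetic signature
TIL10_CELL_TYPES = (
    "B cells",
    "M1 macrophages",
    "M2 macrophages",
    "Monocytes",
    "Neutrophils",
    "NK cells",
    "CD4 T cells",
    "CD8 T cells",
    "Tregs",
    "Dendritic cells",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design the pipeline targets: a TCGA-sized
    triple-negative cohort split into immune-hot and immune-cold halves
    (Dirichlet mean immune fraction 0.45 vs 0.05), 438 planted
    archetype-distinguishing genes at a 5-fold difference, and a PDX
    cohort of 166 models of which 94% derive from the cold archetype.

    ``archetype_fold_max`` is ``None`` for planting at exactly
    ``archetype_fold_change``; when set, per-gene planted folds are drawn
    log-uniformly from [fold_change, fold_max], i.e. genes differ by *at
    least* the stated fold.
    """

    n_genes: int = 2000
    cell_types: tuple[str, ...] = ("cancer", "immune", "stroma")
    n_hot: int = 50
    n_cold: int = 50
    n_pdx: int = 166
    pdx_cold_fraction: float = 0.94
    n_archetype_de_genes: int = 438
    archetype_fold_change: float = 5.0
    archetype_fold_max: float | None = None
    dirichlet_hot: tuple[float, ...] = (10.0, 11.25, 3.75)
    dirichlet_cold: tuple[float, ...] = (20.0, 1.25, 3.75)
    noise_cv: float = 0.05
    marker_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.cell_types)
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(set(self.cell_types)) != k or k < 1:
            raise ValueError("cell_types must be distinct and non-empty")
        for name in ("dirichlet_hot", "dirichlet_cold"):
            conc = getattr(self, name)
            if len(conc) != k or any(a <= 0 for a in conc):
                raise ValueError(
                    f"{name} must be strictly positive with one entry per cell type"
                )
        if not (0.0 <= self.pdx_cold_fraction <= 1.0):
            raise ValueError("pdx_cold_fraction must lie in [0, 1]")
        if self.archetype_fold_change < 1.0:
            raise ValueError("archetype_fold_change must be >= 1")
        if self.archetype_fold_max is not None and (
            self.archetype_fold_max < self.archetype_fold_change
        ):
            raise ValueError("archetype_fold_max must be >= archetype_fold_change")
        if not (0 <= self.n_archetype_de_genes <= self.n_genes):
            raise ValueError("n_archetype_de_genes must lie in [0, n_genes]")
        if self.noise_cv < 0.0:
            raise ValueError("noise_cv must be >= 0")
        if not (0.0 < self.marker_fraction and
                round(self.marker_fraction * self.n_genes) * k <= self.n_genes):
            raise ValueError(
                "marker_fraction too large: disjoint marker blocks do not fit"
            )

    def gene_ids(self) -> pd.Index:
        width = max(5, len(str(self.n_genes)))
        return pd.Index([f"G{i:0{width}d}" for i in range(self.n_genes)], name="gene_id")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        d["dirichlet_hot"] = list(self.dirichlet_hot)
        d["dirichlet_cold"] = list(self.dirichlet_cold)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("cell_types", "dirichlet_hot", "dirichlet_cold"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ArchetypePair:
    """Hot and cold cancer-cell profiles plus the planted-difference table."""

    hot: pd.Series
    cold: pd.Series
    planted: pd.DataFrame  # index: gene_id; columns: direction ('up_hot'/'up_cold'), fold

    def __iter__(self):
        return iter((self.hot, self.cold))


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated cohort."""

    true_proportions: ProportionMatrix | None = None
    archetype_labels: pd.Series | None = None
    pdx_labels: pd.Series | None = None
    planted_de_genes: frozenset = field(default_factory=frozenset)
    reference_profiles: CellTypeProfiles | None = None
    archetypes: ArchetypePair | None = None

    def __post_init__(self) -> None:
        if self.true_proportions is not None:
            sums = self.true_proportions.data.to_numpy().sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError("truth proportions must sum to 1 within 1e-9")
        if self.reference_profiles is not None and self.planted_de_genes:
            missing = self.planted_de_genes - set(self.reference_profiles.gene_ids)
            if missing:
                raise ValueError(f"planted genes absent from references: {sorted(missing)[:5]}")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.seed) % (2**31), _STREAMS[stream]))
    )


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal factors with unit mean and the given CV."""
    if cv == 0.0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def marker_blocks(config: SimulationConfig) -> dict[str, list[str]]:
    """Disjoint marker-gene blocks, one per cell type (first K*m genes)."""
    m = int(round(config.marker_fraction * config.n_genes))
    genes = config.gene_ids()
    return {
        ct: list(genes[k * m : (k + 1) * m]) for k, ct in enumerate(config.cell_types)
    }


def generate_reference_profiles(config: SimulationConfig) -> CellTypeProfiles:
    """One non-negative intrinsic profile per cell type.

    Non-marker genes share a log-normal base level across cell types with
    mild jitter (CV ~10%), so they carry little between-type contrast.
    Each cell type owns a disjoint marker block (``marker_fraction`` of
    genes) expressed at least 10-fold above its level in every other type.
    """
    rng = _rng(config, "references")
    K = len(config.cell_types)
    m = int(round(config.marker_fraction * config.n_genes))
    if m < 1:
        raise ValueError("n_genes too small to allocate marker blocks")

    base = rng.lognormal(mean=3.0, sigma=1.0, size=config.n_genes)
    jitter = rng.lognormal(mean=0.0, sigma=0.1, size=(config.n_genes, K))
    values = base[:, None] * jitter

    for k in range(K):
        block = slice(k * m, (k + 1) * m)
        own = base[block] * rng.lognormal(mean=np.log(30.0), sigma=0.3, size=m)
        # >= 10-fold margin over every other type, by construction
        values[block, :] = own[:, None] / (10.0 * rng.uniform(1.0, 5.0, size=(m, K)))
        values[block, k] = own

    df = pd.DataFrame(values, index=config.gene_ids(), columns=list(config.cell_types))
    return CellTypeProfiles(values=df)


def generate_cancer_archetypes(
    base: CellTypeProfiles, config: SimulationConfig
) -> ArchetypePair:
    """Plant the hot/cold cancer-cell difference.

    Both archetypes start as copies of the cancer reference profile. In
    ``n_archetype_de_genes`` genes (drawn from non-marker genes with
    above-median cancer expression, so the difference is detectable) one
    copy is multiplied by the configured fold: half of the planted genes
    up in hot, half up in cold. All other genes are identical.
    """
    if "cancer" not in base.cell_types:
        raise ValueError("reference profiles must contain a 'cancer' cell type")
    rng = _rng(config, "archetypes")
    cancer = base.column("cancer")

    K = len(config.cell_types)
    m = int(round(config.marker_fraction * config.n_genes))
    eligible = cancer.iloc[K * m :]
    detectable = eligible[eligible >= eligible.median()]
    n_de = config.n_archetype_de_genes
    if n_de > len(detectable):
        raise ValueError(
            f"cannot plant {n_de} genes: only {len(detectable)} eligible "
            "non-marker genes with detectable cancer expression"
        )
    chosen = rng.choice(detectable.index.to_numpy(), size=n_de, replace=False)
    n_up_hot = n_de // 2
    directions = np.array(["up_hot"] * n_up_hot + ["up_cold"] * (n_de - n_up_hot))

    if config.archetype_fold_max is None:
        folds = np.full(n_de, config.archetype_fold_change)
    else:
        folds = np.exp(
            rng.uniform(
                np.log(config.archetype_fold_change),
                np.log(config.archetype_fold_max),
                size=n_de,
            )
        )

    hot = cancer.copy()
    cold = cancer.copy()
    hot.loc[chosen[:n_up_hot]] *= folds[:n_up_hot]
    cold.loc[chosen[n_up_hot:]] *= folds[n_up_hot:]

    planted = pd.DataFrame(
        {"direction": directions, "fold": folds},
        index=pd.Index(chosen, name="gene_id"),
    )
    return ArchetypePair(hot=hot, cold=cold, planted=planted)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Bulk tumour cohort: convex mixtures with per-sample archetype cancer.

    Hot samples draw proportions from ``dirichlet_hot`` (immune-heavy) and
    mix the hot cancer archetype; cold samples use ``dirichlet_cold`` and
    the cold archetype. Log-normal noise with the configured CV is applied
    multiplicatively after mixing.
    """
    refs = generate_reference_profiles(config)
    pair = generate_cancer_archetypes(refs, config)
    rng = _rng(config, "cohort")

    n = config.n_hot + config.n_cold
    labels = np.array(["hot"] * config.n_hot + ["cold"] * config.n_cold)
    width = max(4, len(str(n)))
    sample_ids = pd.Index([f"T{i:0{width}d}" for i in range(n)], name="sample_id")

    P = np.vstack(
        [
            rng.dirichlet(config.dirichlet_hot, size=config.n_hot),
            rng.dirichlet(config.dirichlet_cold, size=config.n_cold),
        ]
    )  # n x K, column order == config.cell_types

    cancer_idx = list(config.cell_types).index("cancer")
    other_idx = [j for j in range(len(config.cell_types)) if j != cancer_idx]
    other_mat = refs.values.to_numpy()[:, other_idx]  # g x (K-1)

    hot_vec = pair.hot.to_numpy()
    cold_vec = pair.cold.to_numpy()
    cancer_mat = np.where((labels == "hot")[None, :], hot_vec[:, None], cold_vec[:, None])

    mean = cancer_mat * P[:, cancer_idx][None, :] + other_mat @ P[:, other_idx].T
    bulk = mean * _noise(rng, config.noise_cv, mean.shape)

    expr = ExpressionMatrix(
        pd.DataFrame(bulk, index=config.gene_ids(), columns=sample_ids)
    )
    truth = SyntheticTruth(
        true_proportions=ProportionMatrix(
            pd.DataFrame(P, index=sample_ids, columns=list(config.cell_types)),
            row_constraint=SIMPLEX,
        ),
        archetype_labels=pd.Series(labels, index=sample_ids, name="archetype"),
        planted_de_genes=frozenset(pair.planted.index),
        reference_profiles=refs,
        archetypes=pair,
    )
    return expr, truth


def generate_pdx_profiles(
    config: SimulationConfig, archetypes: ArchetypePair
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """PDX-like cancer-cell profiles: noisy copies of one archetype.

    A ``pdx_cold_fraction`` share of the ``n_pdx`` columns (rounded to the
    nearest integer) derives from the cold archetype, the rest from hot.
    Columns carry zero immune/stromal content, emulating ideal
    post-separation purity.
    """
    rng = _rng(config, "pdx")
    n = config.n_pdx
    n_cold = int(round(n * config.pdx_cold_fraction))
    labels = np.array(["cold"] * n_cold + ["hot"] * (n - n_cold))
    width = max(3, len(str(max(n, 1))))
    sample_ids = pd.Index([f"X{i:0{width}d}" for i in range(n)], name="sample_id")

    src = np.where(
        (labels == "cold")[None, :],
        archetypes.cold.to_numpy()[:, None],
        archetypes.hot.to_numpy()[:, None],
    )
    values = src * _noise(rng, config.noise_cv, src.shape)

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=archetypes.cold.index, columns=sample_ids)
    )
    truth = SyntheticTruth(
        pdx_labels=pd.Series(labels, index=sample_ids, name="archetype"),
        planted_de_genes=frozenset(archetypes.planted.index),
        archetypes=archetypes,
    )
    return expr, truth


#: fixed intra-immune composition of the simulated cohorts (sums to 1)
DEFAULT_IMMUNE_COMPOSITION: dict[str, float] = {
    "B cells": 0.08,
    "M1 macrophages": 0.10,
    "M2 macrophages": 0.18,
    "Monocytes": 0.12,
    "Neutrophils": 0.08,
    "NK cells": 0.07,
    "CD4 T cells": 0.15,
    "CD8 T cells": 0.12,
    "Tregs": 0.06,
    "Dendritic cells": 0.04,
}


def generate_immune_signature(
    config: SimulationConfig,
    references: CellTypeProfiles | None = None,
    composition: dict[str, float] | None = None,
) -> SignatureMatrix:
    """TIL10-like signature consistent with the cohort's immune profile.

    The immune marker-block genes are partitioned across the ten immune
    subtypes; each gene's signature value in its own subtype is the
    cohort immune-profile value divided by that subtype's share of the
    immune compartment (``composition``), and zero elsewhere. The
    cohort's aggregate immune profile is then exactly the
    composition-weighted mixture of the subtype columns, so
    signature-based fractions recover subtype share x immune proportion.
    """
    if "immune" not in config.cell_types:
        raise ValueError("config has no 'immune' cell type")
    if references is None:
        references = generate_reference_profiles(config)
    composition = dict(composition or DEFAULT_IMMUNE_COMPOSITION)
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"immune composition must sum to 1, got {total}")

    genes = marker_blocks(config)["immune"]
    types = list(composition)
    if len(genes) < len(types):
        raise ValueError(
            f"{len(genes)} immune marker genes cannot cover {len(types)} subtypes"
        )
    imm = references.column("immune").loc[genes]

    values = np.zeros((len(genes), len(types)))
    # round-robin assignment: every subtype owns ~equal numbers of markers
    for i in range(len(genes)):
        t = i % len(types)
        values[i, t] = imm.iloc[i] / composition[types[t]]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=types)
    return SignatureMatrix(df)


def generate_signature_matrix(
    cell_types: tuple[str, ...] = TIL10_CELL_TYPES,
    n_markers_per_type: int = 8,
    seed: int = 0,
) -> SignatureMatrix:
    """Synthetic TIL10-like immune signature for tests and simulations.

    Each immune cell type owns ``n_markers_per_type`` marker genes with a
    high log-normal level in that type and at most ~10% of it elsewhere.
    This is a synthetic stand-in with the structural properties of the
    real ten-cell-type signature, not its content.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed) % (2**31), _STREAMS["signature"])))
    K = len(cell_types)
    rows = []
    gene_ids = []
    for k in range(K):
        for j in range(n_markers_per_type):
            own = rng.lognormal(mean=np.log(100.0), sigma=0.25)
            row = own * rng.uniform(0.01, 0.10, size=K)
            row[k] = own
            rows.append(row)
            gene_ids.append(f"SIG{k:02d}_{j:02d}")
    df = pd.DataFrame(
        np.array(rows), index=pd.Index(gene_ids, name="gene_id"), columns=list(cell_types)
    )
    return SignatureMatrix(df)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialise ground truth (proportions, labels, planted genes) as JSON."""
    payload: dict = {"planted_de_genes": sorted(truth.planted_de_genes)}
    if truth.true_proportions is not None:
        payload["true_proportions"] = {
            sid: {ct: float(v) for ct, v in row.items()}
            for sid, row in truth.true_proportions.data.iterrows()
        }
    if truth.archetype_labels is not None:
        payload["archetype_labels"] = truth.archetype_labels.to_dict()
    if truth.pdx_labels is not None:
        payload["pdx_labels"] = truth.pdx_labels.to_dict()
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
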