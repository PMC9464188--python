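"""End-to-end pipeline orchestration with manifest tracking.

Runs the full analysis sequence — deconvolve, immune fractions, hot/cold
partition, group-wise cancer profiles, differential expression, gene-set
enrichment, PDX matching, engraftment-bias test — writing each stage's
artifacts under the output directory and a JSON manifest with per-file
checksums. Inputs are either file paths or, when absent, a synthetic
cohort generated from the embedded simulation configuration (its ground
truth is written alongside so results are auditable).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .deconvolution import (
    DEFAULT_K_INFORMATIVE,
    DEFAULT_TOL,
    deconvolve,
)
from .immune import estimate_immune_fractions, total_immune_fraction
from .matching import (
    DEFAULT_P0,
    classify_pdx,
    correlate_to_archetypes,
    engraftment_bias_test,
    match_histogram,
    select_match_genes,
)
from .stratify import (
    DEFAULT_ALPHA,
    DEFAULT_FOLD_THRESHOLD,
    compare_group_proportions,
    differential_expression,
    enrichment_table,
    groupwise_cancer_profiles,
    partition_hot_cold,
)
from .synthetic import (
    SimulationConfig,
    generate_cohort,
    generate_pdx_profiles,
    generate_immune_signature,
    write_truth,
)

logger = logging.getLogger("pdxmatch")

STAGES = (
    "deconvolve",
    "immune",
    "partition",
    "profiles",
    "de",
    "enrich",
    "match",
    "bias_test",
)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    File inputs (bulk, signature, references, GMT, PDX) may all be None,
    in which case a synthetic cohort is generated from ``simulation``
    (seeded from ``seed``). Thresholds default to the analysis design:
    quartile hot/cold split, 5-fold + p<0.05 differential expression,
    binomial null p0=0.64 with the one-sided (greater) alternative.
    """

    outdir: Path = Path("pdxmatch_run")
    bulk_path: str | None = None
    signature_path: str | None = None
    references_path: str | None = None
    gmt_path: str | None = None
    pdx_path: str | None = None
    bulk_scale: str = "linear"
    pdx_scale: str = "linear"
    simulation: SimulationConfig | None = None
    lower_q: float = 0.25
    upper_q: float = 0.75
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    p0: float = DEFAULT_P0
    alternative: str = "greater"
    correlation_gene_mode: str = "all"  # or "de_genes"
    partition_source: str = "edec_stage1"  # or "signature_total"
    run_enrichment: bool = True
    k_informative: int = DEFAULT_K_INFORMATIVE
    max_iter: int = 100
    tol: float = DEFAULT_TOL
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.lower_q <= self.upper_q < 1.0):
            raise ValueError("quartile bounds must satisfy 0 < lower_q <= upper_q < 1")
        if self.fold_threshold < 1.0 or not (0.0 < self.alpha < 1.0):
            raise ValueError("invalid DE thresholds")
        if not (0.0 < self.p0 < 1.0):
            raise ValueError("p0 must lie in (0, 1)")
        if self.alternative not in ("greater", "two_sided"):
            raise ValueError(f"unknown alternative {self.alternative!r}")
        if self.correlation_gene_mode not in ("de_genes", "all"):
            raise ValueError("correlation_gene_mode must be 'de_genes' or 'all'")
        if self.partition_source not in ("edec_stage1", "signature_total"):
            raise ValueError("partition_source must be 'edec_stage1' or 'signature_total'")
        synthetic = self.bulk_path is None
        for name in ("bulk_path", "signature_path", "references_path", "pdx_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.run_enrichment and not synthetic and self.gmt_path is None:
            raise ValueError("enrichment enabled but no GMT path configured")
        if self.gmt_path is not None and not Path(self.gmt_path).exists():
            raise FileNotFoundError(f"gmt_path: {self.gmt_path}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            for key in ("cell_types", "dirichlet_hot", "dirichlet_cold"):
                sim[key] = list(sim[key])
            d["simulation"] = sim
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in d and d["simulation"] is not None:
            sim = d["simulation"]
            for key in ("cell_types", "dirichlet_hot", "dirichlet_cold"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["simulation"] = SimulationConfig(**sim)
        if "outdir" in d:
            d["outdir"] = Path(d["outdir"])
        return cls(**d)


@dataclass
class RunManifest:
    """Record of a pipeline run: config, stage outputs, checksums, logs."""

    config: dict
    version: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    inputs: dict = field(default_factory=dict)
    status: str = "running"

    def completed_stages(self) -> list[str]:
        return [s["name"] for s in self.stages if s["status"] == "completed"]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


class _StageRunner:
    def __init__(self, manifest: RunManifest, outdir: Path):
        self.manifest = manifest
        self.outdir = outdir

    def run(self, name: str, fn):
        record = {"name": name, "status": "running", "started": time.time(), "outputs": {}}
        self.manifest.stages.append(record)
        try:
            outputs = fn() or []
            record["outputs"] = {str(p): io.sha256_of_file(p) for p in outputs}
            record["status"] = "completed"
        except Exception as exc:
            record["status"] = "failed"
            record["error"] = f"{type(exc).__name__}: {exc}"
            self.manifest.status = f"failed at {name}"
            self.manifest.write(self.outdir / "manifest.json")
            raise
        finally:
            record["finished"] = time.time()
        logger.info("stage %s completed (%d outputs)", name, len(record["outputs"]))


def _prepare_inputs(config: PipelineConfig, outdir: Path, manifest: RunManifest):
    """Load file inputs, or synthesise a cohort when none are configured."""
    if config.bulk_path is not None:
        bulk = io.read_expression_matrix(config.bulk_path, scale=config.bulk_scale)
        signature = (
            io.read_signature_matrix(config.signature_path)
            if config.signature_path
            else None
        )
        references = (
            io.read_profiles(str(config.references_path).removesuffix(".values.tsv"))
            if config.references_path
            else None
        )
        pdx = (
            io.read_expression_matrix(config.pdx_path, scale=config.pdx_scale)
            if config.pdx_path
            else None
        )
        gene_sets = io.read_gmt(config.gmt_path) if config.gmt_path else None
        return bulk, references, signature, pdx, gene_sets, None

    sim = config.simulation or SimulationConfig(seed=config.seed)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    bulk, truth = generate_cohort(sim)
    pdx, pdx_truth = generate_pdx_profiles(sim, truth.archetypes)
    signature = generate_immune_signature(sim, truth.reference_profiles)
    gene_sets = _synthetic_gene_sets(sim, truth)

    io.write_expression_matrix(bulk, indir / "bulk.tsv")
    io.write_expression_matrix(pdx, indir / "pdx.tsv")
    io.write_signature_matrix(signature, indir / "signature.tsv")
    io.write_gmt(gene_sets, indir / "gene_sets.gmt")
    truth.pdx_labels = pdx_truth.pdx_labels
    write_truth(truth, indir / "truth.json")
    sim.to_yaml(indir / "simulation.yaml")
    manifest.inputs = {
        str(p): io.sha256_of_file(p)
        for p in sorted(indir.iterdir())
    }
    return bulk, truth.reference_profiles, signature, pdx, gene_sets, truth


def _synthetic_gene_sets(sim: SimulationConfig, truth) -> dict[str, list[str]]:
    """Gene sets for the synthetic enrichment stage: planted + random."""
    planted = truth.archetypes.planted
    sets = {
        "planted_up_hot": sorted(planted.index[planted["direction"] == "up_hot"]),
        "planted_up_cold": sorted(planted.index[planted["direction"] == "up_cold"]),
        "planted_all": sorted(planted.index),
    }
    rng = np.random.default_rng(np.random.SeedSequence((sim.seed % (2**31), 99)))
    genes = sim.gene_ids().to_numpy()
    for i in range(5):
        sets[f"random_set_{i}"] = sorted(rng.choice(genes, size=50, replace=False))
    return sets


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all eight analysis stages and write a manifest.

    Any stage failure halts the run; the manifest (written on both
    success and failure) records the failure point.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__, seed=config.seed)
    runner = _StageRunner(manifest, outdir)

    bulk, references, signature, pdx, gene_sets, truth = _prepare_inputs(
        config, outdir, manifest
    )
    if references is None:
        raise ValueError("deconvolution requires reference profiles")

    state: dict = {}

    def stage_deconvolve():
        fit = deconvolve(
            bulk, references, k=config.k_informative,
            max_iter=config.max_iter, tol=config.tol,
        )
        state["fit"] = fit
        io.write_proportions(fit.proportions, outdir / "proportions.tsv")
        paths = io.write_profiles(fit.profiles, outdir / "profiles")
        summary = outdir / "deconvolution.json"
        summary.write_text(json.dumps({
            "n_iterations": fit.n_iterations,
            "converged": fit.converged,
            "objective_trace": fit.objective_trace,
            "n_informative_genes": len(fit.informative_genes),
        }, indent=1))
        return [outdir / "proportions.tsv", *paths, summary]

    def stage_immune():
        if signature is None:
            raise ValueError("immune stage requires a signature matrix")
        fractions = estimate_immune_fractions(bulk, signature)
        state["immune_fractions"] = fractions
        io.write_proportions(fractions, outdir / "immune_fractions.tsv")
        return [outdir / "immune_fractions.tsv"]

    def stage_partition():
        if config.partition_source == "edec_stage1":
            props = state["fit"].proportions
            if "immune" not in props.data.columns:
                raise ValueError(
                    "partition_source=edec_stage1 needs an 'immune' cell type"
                )
            fractions = props.data["immune"]
        else:
            fractions = total_immune_fraction(state["immune_fractions"])
        partition = partition_hot_cold(
            fractions, config.lower_q, config.upper_q, source=config.partition_source
        )
        state["partition"] = partition
        io.write_partition(partition, outdir / "partition.tsv")
        comparison = compare_group_proportions(state["immune_fractions"], partition)
        comparison.to_csv(outdir / "immune_group_comparison.tsv", sep="\t")
        return [outdir / "partition.tsv", outdir / "immune_group_comparison.tsv"]

    def stage_profiles():
        hot, cold = groupwise_cancer_profiles(
            bulk, state["fit"].proportions, state["partition"]
        )
        state["hot_profiles"], state["cold_profiles"] = hot, cold
        return [
            *io.write_profiles(hot, outdir / "hot_profiles"),
            *io.write_profiles(cold, outdir / "cold_profiles"),
        ]

    def stage_de():
        de = differential_expression(
            state["hot_profiles"], state["cold_profiles"],
            fold_threshold=config.fold_threshold, alpha=config.alpha,
        )
        state["de"] = de
        de.to_csv(outdir / "differential_expression.tsv", sep="\t", index_label="gene_id")
        return [outdir / "differential_expression.tsv"]

    def stage_enrich():
        if gene_sets is None:
            raise ValueError("enrichment requires a GMT file")
        de = state["de"]
        universe = de.index
        table = enrichment_table(de.index[de["passes"]], gene_sets, universe)
        table.to_csv(outdir / "enrichment.tsv", sep="\t")
        return [outdir / "enrichment.tsv"]

    def stage_match():
        if pdx is None:
            raise ValueError("matching requires a PDX expression matrix")
        subset = None
        if config.correlation_gene_mode == "de_genes":
            subset = select_match_genes(
                state.get("de"), state["hot_profiles"], state["cold_profiles"]
            )
            logger.info(
                "correlation gene set: %s",
                "all shared genes" if subset is None else f"{len(subset)} DE genes",
            )
        corrs = correlate_to_archetypes(
            pdx, state["hot_profiles"], state["cold_profiles"], gene_subset=subset
        )
        matches = classify_pdx(corrs)
        state["matches"] = matches
        io.write_match_results(matches, outdir / "matches.tsv")
        hist = match_histogram(matches)
        hist_df = pd.DataFrame(
            {
                "bin_left": hist.bin_edges[:-1],
                "bin_right": hist.bin_edges[1:],
                "hot": hist.counts["hot"].to_numpy(),
                "cold": hist.counts["cold"].to_numpy(),
            }
        )
        hist_df.to_csv(outdir / "match_histogram.tsv", sep="\t", index=False)
        return [outdir / "matches.tsv", outdir / "match_histogram.tsv"]

    def stage_bias_test():
        matches = state["matches"]
        k_cold = int((matches["label"] == "cold").sum())
        result = engraftment_bias_test(
            k_cold, len(matches), p0=config.p0, alternative=config.alternative
        )
        state["bias"] = result
        payload = dataclasses.asdict(result)
        payload["cold_share_percent"] = int(round(100.0 * k_cold / len(matches)))
        (outdir / "bias_test.json").write_text(json.dumps(payload, indent=1))
        return [outdir / "bias_test.json"]

    stage_fns = {
        "deconvolve": stage_deconvolve,
        "immune": stage_immune,
        "partition": stage_partition,
        "profiles": stage_profiles,
        "de": stage_de,
        "enrich": stage_enrich,
        "match": stage_match,
        "bias_test": stage_bias_test,
    }
    for name in STAGES:
        if name == "enrich" and not config.run_enrichment:
            continue
        runner.run(name, stage_fns[name])

    manifest.status = "completed"
    manifest.write(outdir / "manifest.json")
    return manifest
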