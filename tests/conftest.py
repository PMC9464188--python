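import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from pdxmatch import (
    HotColdPartition,
    SimulationConfig,
    classify_pdx,
    correlate_to_archetypes,
    deconvolve,
    differential_expression,
    generate_cohort,
    generate_pdx_profiles,
    groupwise_cancer_profiles,
    partition_hot_cold,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_genes=300,
        n_hot=15,
        n_cold=15,
        n_pdx=20,
        n_archetype_de_genes=30,
        noise_cv=0.05,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def recovery_run():
    """Parameter-recovery benchmark: 3 cell types, n=100, noise CV 5%.

    No archetype difference is planted so the single generating cancer
    profile is the unambiguous Stage-2 truth.
    """
    cfg = SimulationConfig(n_archetype_de_genes=0, noise_cv=0.05, seed=11)
    bulk, truth = generate_cohort(cfg)
    fit = deconvolve(bulk, truth.reference_profiles, k=1000, max_iter=100)
    return cfg, bulk, truth, fit


@pytest.fixture(scope="session")
def de_run():
    """DE-recovery benchmark: 438 genes planted at >= 5-fold, 50 per group."""
    cfg = SimulationConfig(archetype_fold_max=20.0, noise_cv=0.05, seed=12)
    bulk, truth = generate_cohort(cfg)
    fit = deconvolve(bulk, truth.reference_profiles, k=1000, max_iter=100)
    partition = HotColdPartition(
        labels=truth.archetype_labels.rename("label"),
        cold_threshold=0.0,
        hot_threshold=1.0,
    )
    hot, cold = groupwise_cancer_profiles(bulk, fit.proportions, partition)
    de = differential_expression(hot, cold)
    return cfg, bulk, truth, fit, de


@pytest.fixture(scope="session")
def e2e_run():
    """End-to-end benchmark: 166 PDX, 94% cold-derived, noise CV 10%."""
    cfg = SimulationConfig(noise_cv=0.1, seed=13)
    bulk, truth = generate_cohort(cfg)
    pdx, pdx_truth = generate_pdx_profiles(cfg, truth.archetypes)
    fit = deconvolve(bulk, truth.reference_profiles, k=1000, max_iter=100)
    partition = partition_hot_cold(fit.proportions.data["immune"])
    hot, cold = groupwise_cancer_profiles(bulk, fit.proportions, partition)
    matches = classify_pdx(correlate_to_archetypes(pdx, hot, cold))
    return {
        "cfg": cfg,
        "bulk": bulk,
        "truth": truth,
        "pdx": pdx,
        "pdx_truth": pdx_truth,
        "fit": fit,
        "partition": partition,
        "hot": hot,
        "cold": cold,
        "matches": matches,
    }
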