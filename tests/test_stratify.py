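"""Quartile partition, group-wise profiles, DE, enrichment, group tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pdxmatch import (
    CellTypeProfiles,
    HotColdPartition,
    ProportionMatrix,
    SimulationConfig,
    compare_group_proportions,
    differential_expression,
    enrichment_test,
    estimate_profiles,
    generate_cohort,
    groupwise_cancer_profiles,
    partition_hot_cold,
)
from pdxmatch.containers import SUB_SIMPLEX

from oracles import hypergeom_tail_enumeration, permutation_welch_p


class TestPartition:
    def test_eight_sample_quartiles(self):
        fractions = pd.Series(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8],
            index=[f"s{i}" for i in range(8)],
        )
        part = partition_hot_cold(fractions)
        assert set(part.samples("cold")) == {"s0", "s1"}
        assert set(part.samples("hot")) == {"s6", "s7"}
        assert (part.labels == "intermediate").sum() == 4
        assert part.cold_threshold == 0.2 and part.hot_threshold == 0.7

    def test_ties_break_deterministically_by_identifier(self):
        fractions = pd.Series(0.5, index=[f"s{i}" for i in range(9)])
        part = partition_hot_cold(fractions)
        assert list(part.samples("cold")) == ["s0", "s1"]
        assert list(part.samples("hot")) == ["s7", "s8"]

    def test_fewer_than_eight_samples_is_an_error(self):
        with pytest.raises(ValueError, match=">= 8"):
            partition_hot_cold(pd.Series([0.1] * 7, index=list("abcdefg")))

    @given(st.integers(8, 60), st.integers(0, 100))
    def test_quartile_sizes_are_always_floor_n_over_4(self, n, seed):
        rng = np.random.default_rng(seed)
        fractions = pd.Series(rng.random(n), index=[f"s{i:03d}" for i in range(n)])
        part = partition_hot_cold(fractions)
        assert (part.labels == "cold").sum() == n // 4
        assert (part.labels == "hot").sum() == n // 4

    def test_recovers_true_archetype_labels_on_synthetic_cohort(self, recovery_run):
        cfg, bulk, truth, fit = recovery_run
        part = partition_hot_cold(fit.proportions.data["immune"])
        labelled = part.labels[part.labels != "intermediate"]
        agreement = (labelled == truth.archetype_labels[labelled.index]).mean()
        assert agreement >= 0.95


class TestGroupwiseProfiles:
    def test_no_planted_difference_gives_equal_cancer_profiles(self, small_cfg):
        cfg = SimulationConfig(
            **{**vars(small_cfg), "noise_cv": 0.0, "n_archetype_de_genes": 0}
        )
        bulk, truth = generate_cohort(cfg)
        part = HotColdPartition(
            labels=truth.archetype_labels.rename("label"),
            cold_threshold=0.0,
            hot_threshold=1.0,
        )
        hot, cold = groupwise_cancer_profiles(bulk, truth.true_proportions, part)
        diff = (hot.values["cancer"] - cold.values["cancer"]).abs()
        scale = cold.values["cancer"].clip(lower=1e-12)
        assert (diff / scale).max() < 1e-6

    def test_planted_fivefold_ratio_is_recovered(self):
        cfg = SimulationConfig(noise_cv=0.05, seed=14)  # exact 5-fold planting
        bulk, truth = generate_cohort(cfg)
        part = HotColdPartition(
            labels=truth.archetype_labels.rename("label"),
            cold_threshold=0.0,
            hot_threshold=1.0,
        )
        hot, cold = groupwise_cancer_profiles(bulk, truth.true_proportions, part)
        planted = truth.archetypes.planted
        up_hot = planted.index[planted["direction"] == "up_hot"]
        ratio = hot.values.loc[up_hot, "cancer"] / cold.values.loc[up_hot, "cancer"]
        assert abs(np.median(ratio) - 5.0) / 5.0 < 0.20
        assert (np.abs(ratio - 5.0) / 5.0 < 0.20).mean() > 0.9

    def test_intermediate_samples_do_not_contribute(self, small_cfg, small_cohort):
        bulk, truth = small_cohort
        labels = truth.archetype_labels.rename("label").copy()
        # corrupt three samples, then mark them intermediate: result unchanged
        part_full = HotColdPartition(labels=labels, cold_threshold=0, hot_threshold=1)
        drop = labels.index[:3]
        labels2 = labels.copy()
        labels2[drop] = "intermediate"
        corrupted = bulk.data.copy()
        corrupted[drop] = corrupted[drop] * 1000.0
        from pdxmatch import ExpressionMatrix

        hot_a, cold_a = groupwise_cancer_profiles(
            ExpressionMatrix(corrupted), truth.true_proportions,
            HotColdPartition(labels=labels2, cold_threshold=0, hot_threshold=1),
        )
        labels3 = labels[~labels.index.isin(drop)]
        hot_b, cold_b = groupwise_cancer_profiles(
            ExpressionMatrix(bulk.data.drop(columns=drop)),
            ProportionMatrix(truth.true_proportions.data.drop(index=drop)),
            HotColdPartition(labels=labels3, cold_threshold=0, hot_threshold=1),
        )
        pd.testing.assert_frame_equal(hot_a.values, hot_b.values)
        pd.testing.assert_frame_equal(cold_a.values, cold_b.values)

    def test_group_smaller_than_cell_types_errors_with_group_name(self, small_cohort):
        bulk, truth = small_cohort
        labels = pd.Series(
            ["hot"] * 2 + ["cold"] * 28, index=truth.archetype_labels.index
        )
        with pytest.raises(ValueError, match="hot group"):
            groupwise_cancer_profiles(
                bulk, truth.true_proportions,
                HotColdPartition(labels=labels, cold_threshold=0, hot_threshold=1),
            )


def _profiles(values, se, n_samples=28):
    genes = [f"g{i}" for i in range(len(values))]
    v = pd.DataFrame({"cancer": values}, index=genes)
    s = pd.DataFrame({"cancer": se}, index=genes)
    return CellTypeProfiles(values=v, stderr=s, n_samples=n_samples)


class TestDifferentialExpression:
    def test_identical_profiles_yield_no_calls(self):
        prof = _profiles([10.0, 20.0, 30.0], [1.0, 1.0, 1.0])
        de = differential_expression(prof, prof)
        assert de["passes"].sum() == 0
        assert (de["p_value"] == 1.0).all()

    def test_pseudocount_fold_rule_at_the_boundary(self):
        hot = _profiles([50.0, 60.0], [0.1, 0.1])
        cold = _profiles([10.0, 10.0], [0.1, 0.1])
        de = differential_expression(hot, cold)
        assert de.loc["g0", "fold_change"] == pytest.approx(51 / 11)
        assert not de.loc["g0", "passes"]  # 4.64 < 5
        assert de.loc["g1", "fold_change"] == pytest.approx(61 / 11)
        assert de.loc["g1", "passes"] and de.loc["g1", "p_value"] < 0.05

    def test_downregulated_direction_also_passes(self):
        hot = _profiles([10.0], [0.1])
        cold = _profiles([100.0], [0.1])
        de = differential_expression(hot, cold)
        assert de.loc["g0", "fold_change"] < 1 / 5 and de.loc["g0", "passes"]

    def test_welch_statistic_matches_scipy_tail(self):
        hot = _profiles([60.0], [2.0], n_samples=28)
        cold = _profiles([10.0], [1.5], n_samples=23)
        de = differential_expression(hot, cold)
        t = (60 - 10) / np.sqrt(2.0**2 + 1.5**2)
        df = (2.0**2 + 1.5**2) ** 2 / (2.0**4 / 25 + 1.5**4 / 20)
        assert de.loc["g0", "t_statistic"] == pytest.approx(t)
        assert de.loc["g0", "p_value"] == pytest.approx(2 * stats.t.sf(t, df), rel=1e-9)

    def test_pass_set_is_invariant_to_gene_order(self):
        rng = np.random.default_rng(0)
        hot = _profiles(rng.lognormal(3, 1, 40), rng.uniform(0.5, 2, 40))
        cold = _profiles(rng.lognormal(3, 1, 40), rng.uniform(0.5, 2, 40))
        de = differential_expression(hot, cold)
        perm = rng.permutation(40)
        hot_p = CellTypeProfiles(
            values=hot.values.iloc[perm], stderr=hot.stderr.iloc[perm], n_samples=28
        )
        cold_p = CellTypeProfiles(
            values=cold.values.iloc[perm], stderr=cold.stderr.iloc[perm], n_samples=28
        )
        de_p = differential_expression(hot_p, cold_p)
        assert set(de.index[de["passes"]]) == set(de_p.index[de_p["passes"]])

    def test_recovery_of_planted_genes(self, de_run):
        """Recall >= 0.9 and FPR <= 0.01 on 438 planted >= 5-fold genes."""
        cfg, bulk, truth, fit, de = de_run
        planted = set(truth.planted_de_genes)
        hits = set(de.index[de["passes"]])
        recall = len(hits & planted) / len(planted)
        unplanted = set(de.index) - planted
        fpr = len(hits & unplanted) / len(unplanted)
        assert recall >= 0.9
        assert fpr <= 0.01

    def test_missing_standard_errors_are_rejected(self):
        prof = CellTypeProfiles(pd.DataFrame({"cancer": [1.0]}, index=["g0"]))
        with pytest.raises(ValueError, match="standard errors"):
            differential_expression(prof, prof)


class TestEnrichment:
    def test_closed_form_full_overlap(self):
        universe = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(5)}
        rec = enrichment_test(gene_set, gene_set, universe)
        assert rec.p_value == pytest.approx(1 / 252, rel=1e-12)
        assert rec.de_overlap == 5 and rec.universe_size == 10

    def test_zero_overlap_has_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        rec = enrichment_test({"g0", "g1"}, {"g8", "g9"}, universe)
        assert rec.de_overlap == 0 and rec.p_value == 1.0

    @pytest.mark.parametrize(
        "u,s,d", [(20, 6, 7), (12, 4, 6), (10, 5, 5)],
    )
    def test_matches_exhaustive_enumeration(self, u, s, d):
        universe = {f"g{i}" for i in range(u)}
        gene_set = {f"g{i}" for i in range(s)}
        de = {f"g{i}" for i in range(u - d, u)}
        rec = enrichment_test(de, gene_set, universe)
        oracle = hypergeom_tail_enumeration(universe, gene_set, de)
        assert rec.p_value == pytest.approx(oracle, rel=1e-9)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            enrichment_test({"a"}, {"a"}, set())


class TestGroupComparison:
    def _props(self, values: dict, index) -> ProportionMatrix:
        df = pd.DataFrame(values, index=index)
        df["other"] = 1.0 - df.sum(axis=1)
        return ProportionMatrix(df, row_constraint=SUB_SIMPLEX)

    def test_identical_groups_have_p_one(self):
        idx = [f"s{i}" for i in range(8)]
        props = self._props({"Tregs": [0.1, 0.2, 0.15, 0.12] * 2}, idx)
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=idx)
        res = compare_group_proportions(props, labels)
        assert res.loc["Tregs", "p_value"] == pytest.approx(1.0)

    def test_strong_treg_shift_is_detected(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(50)]
        tregs = np.concatenate(
            [
                np.clip(rng.normal(0.10, 0.02, 25), 0, 1),
                np.clip(rng.normal(0.01, 0.02, 25), 0, 1),
            ]
        )
        props = self._props({"Tregs": tregs}, idx)
        labels = pd.Series(["hot"] * 25 + ["cold"] * 25, index=idx)
        res = compare_group_proportions(props, labels)
        assert res.loc["Tregs", "p_value"] < 0.001

    def test_single_cell_type_gives_single_row(self):
        idx = [f"s{i}" for i in range(8)]
        props = self._props({"Tregs": [0.1, 0.2, 0.15, 0.3, 0.1, 0.05, 0.2, 0.25]}, idx)
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=idx)
        res = compare_group_proportions(props, labels)
        assert list(res.index) == ["Tregs"]

    def test_tiny_group_is_an_error(self):
        idx = [f"s{i}" for i in range(5)]
        props = self._props({"Tregs": [0.1, 0.2, 0.15, 0.3, 0.1]}, idx)
        labels = pd.Series(["a"] * 1 + ["b"] * 4, index=idx)
        with pytest.raises(ValueError, match="at least 2"):
            compare_group_proportions(props, labels)

    @pytest.mark.parametrize("loc_shift", [0.0, 0.01, 0.03])
    def test_welch_p_matches_permutation_oracle(self, loc_shift):
        rng = np.random.default_rng(42)
        a = rng.normal(0.10 + loc_shift, 0.03, 25)
        b = rng.normal(0.10, 0.03, 25)
        welch_p = stats.ttest_ind(a, b, equal_var=False).pvalue
        perm_p = permutation_welch_p(a, b, n_perm=20_000, seed=1)
        assert abs(welch_p - perm_p) < 0.01
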