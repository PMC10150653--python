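import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emtstrat import (
    ConfigError,
    InsufficientDataError,
    ScoreTable,
    ThresholdConfig,
    classify_emt,
    cross_tabulate,
    expression_by_stratum,
    mcam_tripartition,
    subpopulation_correlation,
)
from conftest import make_matrix
from oracles import groupby_loop_summary, spearman_rank_formula


def score_table(semt, obs_kind="cell", **extra):
    df = pd.DataFrame({"sEMT": semt, **extra},
                      index=pd.Index([f"c{i}" for i in range(len(semt))], name="obs_id"))
    scale = "log_normalized" if obs_kind == "cell" else "linear"
    return ScoreTable(scores=df, scale=scale, obs_kind=obs_kind)


class TestClassifyEmt:
    @pytest.mark.parametrize("semt,expected", [
        (-0.01, "low"), (3.0, "med"), (7.2, "high"),
        (0.0, "med"), (5.0, "high"),  # half-open boundaries: no gap, no overlap
        (4.99, "med"),
    ])
    def test_cell_thresholds(self, semt, expected):
        strata = classify_emt(score_table([semt]), ThresholdConfig.cell_defaults())
        assert strata["emt_class"].iloc[0] == expected

    @pytest.mark.parametrize("semt,expected", [
        (3000.0, "med"), (1999.9, "low"), (5000.0, "high"), (6200.0, "high"),
    ])
    def test_bulk_thresholds(self, semt, expected):
        strata = classify_emt(
            score_table([semt], obs_kind="bulk_sample"), ThresholdConfig.bulk_defaults()
        )
        assert strata["emt_class"].iloc[0] == expected

    def test_scale_mismatch_refused(self):
        with pytest.raises(ConfigError):
            classify_emt(score_table([1.0], obs_kind="bulk_sample"),
                         ThresholdConfig.cell_defaults())
        # explicit override allowed
        classify_emt(score_table([1.0], obs_kind="bulk_sample"),
                     ThresholdConfig.cell_defaults(), override_scale_check=True)

    @given(st.floats(-20, 20), st.floats(0.01, 10))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_score(self, semt, bump):
        order = {"low": 0, "med": 1, "high": 2}
        th = ThresholdConfig.cell_defaults()
        a = classify_emt(score_table([semt]), th)["emt_class"].iloc[0]
        b = classify_emt(score_table([semt + bump]), th)["emt_class"].iloc[0]
        assert order[b] >= order[a]

    def test_every_observation_classified(self, rng):
        semt = rng.normal(0, 4, 500)
        strata = classify_emt(score_table(semt), ThresholdConfig.cell_defaults())
        assert strata["emt_class"].notna().all()


class TestMcamTripartition:
    def _classes(self, values, groups=None):
        expr = pd.Series(values, index=[f"c{i}" for i in range(len(values))])
        g = pd.Series(groups or ["g"] * len(values), index=expr.index)
        return mcam_tripartition(expr, g)["mcam_class"]

    def test_all_non_expressers(self):
        assert list(self._classes([0.0, 0.0, 0.0])) == ["neg"] * 3

    def test_odd_expresser_count_extra_cell_to_low(self):
        cls = self._classes([0.0, 0.4, 1.2, 3.3])
        assert list(cls) == ["neg", "low", "low", "high"]

    def test_even_split(self):
        cls = self._classes([0.5, 1.0, 2.0, 4.0])
        assert list(cls) == ["low", "low", "high", "high"]

    def test_groups_partitioned_independently(self):
        cls = self._classes([0.0, 1.0, 2.0, 0.0, 5.0, 6.0],
                            groups=["a", "a", "a", "b", "b", "b"])
        assert list(cls) == ["neg", "low", "high", "neg", "low", "high"]

    def test_ties_at_median_broken_by_input_order(self):
        cls = self._classes([2.0, 2.0, 2.0, 2.0])
        assert list(cls) == ["low", "low", "high", "high"]

    @given(st.integers(0, 2**31 - 1), st.integers(1, 60))
    @settings(max_examples=60, deadline=None)
    def test_partition_invariants(self, seed, n):
        rng = np.random.default_rng(seed)
        values = np.round(rng.exponential(1.0, n) * (rng.random(n) > 0.4), 2)
        groups = rng.choice(["a", "b", "c"], size=n)
        expr = pd.Series(values, index=[f"c{i}" for i in range(n)])
        result = mcam_tripartition(expr, pd.Series(groups, index=expr.index))
        cls = result["mcam_class"]
        assert cls.notna().all()  # exhaustive
        for g in np.unique(groups):
            sub = cls[groups == g]
            vals = expr[groups == g]
            n_low, n_high = (sub == "low").sum(), (sub == "high").sum()
            assert n_low - n_high in (0, 1)
            assert (vals[sub == "neg"] <= 0).all()
            expressers = vals[sub != "neg"]
            assert (expressers > 0).all()
            low_vals, high_vals = vals[sub == "low"], vals[sub == "high"]
            if len(low_vals) and len(high_vals):
                # order property can only break when a tie spans the boundary
                if low_vals.max() > high_vals.min():
                    assert low_vals.max() == high_vals.min()


class TestCrossTabulate:
    def test_one_cell_per_combination_identity(self):
        emt = ["low", "low", "low", "med", "med", "med", "high", "high", "high"]
        mcam = ["neg", "low", "high"] * 3
        sinv = np.arange(9.0)
        scsc = np.arange(9.0) * 2
        strata = pd.DataFrame(
            {"emt_class": emt, "mcam_class": mcam},
            index=pd.Index([f"c{i}" for i in range(9)], name="obs_id"),
        )
        scores = score_table(np.zeros(9), sInv=sinv, sCSC=scsc)
        summary = cross_tabulate(strata, scores)
        assert (summary["n_cells"] == 1).all()
        for i in range(9):
            row = summary.loc[(emt[i], mcam[i])]
            assert row["mean_sInv"] == sinv[i]
            assert row["mean_sCSC"] == scsc[i]

    def test_matches_groupby_loop_and_conserves_n(self, rng):
        n = 200
        emt = rng.choice(["low", "med", "high"], n)
        mcam = rng.choice(["neg", "low", "high"], n)
        sinv, scsc = rng.random(n), rng.random(n)
        strata = pd.DataFrame(
            {"emt_class": emt, "mcam_class": mcam},
            index=pd.Index([f"c{i}" for i in range(n)], name="obs_id"),
        )
        scores = score_table(np.zeros(n), sInv=sinv, sCSC=scsc)
        summary = cross_tabulate(strata, scores)
        assert summary["n_cells"].sum() == n
        expected = groupby_loop_summary(emt, mcam, sinv, scsc)
        for key, (cnt, mi, mc) in expected.items():
            row = summary.loc[key]
            assert row["n_cells"] == cnt
            assert row["mean_sInv"] == pytest.approx(mi)
            assert row["mean_sCSC"] == pytest.approx(mc)

    def test_empty_combinations_reported_with_nan_means(self):
        strata = pd.DataFrame(
            {"emt_class": ["low"], "mcam_class": ["neg"]},
            index=pd.Index(["c0"], name="obs_id"),
        )
        scores = score_table([0.0], sInv=[1.0], sCSC=[2.0])
        summary = cross_tabulate(strata, scores)
        assert len(summary) == 9
        assert summary.loc[("high", "high"), "n_cells"] == 0
        assert np.isnan(summary.loc[("high", "high"), "mean_sInv"])


class TestSubpopulationCorrelation:
    def _summary(self, sinv, scsc):
        idx = pd.MultiIndex.from_product(
            [["low", "med", "high"], ["neg", "low", "high"]],
            names=["emt_class", "mcam_class"],
        )[: len(sinv)]
        return pd.DataFrame(
            {"n_cells": 5, "mean_sInv": sinv, "mean_sCSC": scsc}, index=idx
        )

    def test_monotone_means_give_one(self):
        sinv = np.arange(9.0)
        assert subpopulation_correlation(self._summary(sinv, sinv**2 + 1)).r == 1.0

    def test_reversed_pair_matches_rank_formula(self):
        sinv = list(range(1, 10))
        scsc = [1, 2, 3, 4, 5, 6, 7, 9, 8]  # one reversed pair
        res = subpopulation_correlation(self._summary(sinv, scsc))
        assert res.r == pytest.approx(spearman_rank_formula(sinv, scsc))
        assert res.r == pytest.approx(1 - 6 * 2 / (9 * 80))

    def test_two_defined_rows_rejected(self):
        summary = self._summary([1.0, 2.0, 3.0], [1.0, 2.0, np.nan])
        with pytest.raises(InsufficientDataError):
            subpopulation_correlation(summary)


class TestExpressionByStratum:
    def _strata(self, emt):
        return pd.DataFrame(
            {"emt_class": emt},
            index=pd.Index([f"c{i}" for i in range(len(emt))], name="obs_id"),
        )

    def test_constant_gene_all_p_one(self):
        emt = ["low"] * 3 + ["med"] * 3 + ["high"] * 3
        m = make_matrix(np.full((9, 1), 2.0), gene_ids=["MCAM"])
        result = expression_by_stratum(m, "MCAM", self._strata(emt))
        for res in result.comparisons.values():
            assert res.p_two_tailed == pytest.approx(1.0)

    def test_class_indexed_gene_orders_means(self):
        emt = ["low"] * 4 + ["med"] * 4 + ["high"] * 4
        values = np.array([0.0] * 4 + [1.0] * 4 + [2.0] * 4)[:, None]
        m = make_matrix(values, gene_ids=["TWIST1"])
        result = expression_by_stratum(m, "TWIST1", self._strata(emt))
        means = [result.values[c].mean() for c in ("low", "med", "high")]
        assert means[0] < means[1] < means[2]

    def test_class_counts_conserved(self, rng):
        semt = rng.normal(1.0, 3.0, 60)
        table = score_table(semt)
        strata = classify_emt(table, ThresholdConfig.cell_defaults())
        m = make_matrix(rng.random((60, 1)), gene_ids=["QKI"],
                        obs_ids=list(strata.index))
        result = expression_by_stratum(m, "QKI", strata)
        for cls in ("low", "med", "high"):
            assert len(result.values[cls]) == (strata["emt_class"] == cls).sum()
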