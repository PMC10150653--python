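import numpy as np
import pandas as pd
import pytest

from emtstrat import (
    ConfigError,
    SyntheticConfig,
    ThresholdConfig,
    calibrate_emt_thresholds,
    classify_emt,
    cross_tabulate,
    mann_whitney_two_tailed,
    proportion_expressing,
    score_all,
    simulate_bulk,
    simulate_cells,
    simulate_methylation,
    simulate_methylation_cohort,
    spearman_with_ci,
    stratify_cells,
)
from emtstrat.scoring import score_signature
from emtstrat.stats import methylation_expression_correlation, methylation_mean_m


def three_sd_band(p, n):
    sd = np.sqrt(p * (1 - p) / n)
    return p - 3 * sd, p + 3 * sd


class TestConfig:
    def test_bad_weights_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(emt_mixture_weights=(0.5, 0.5, 0.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_malignant=-1)

    def test_mcam_base_calibration_is_analytic(self):
        cfg = SyntheticConfig()
        for cell_type, target in (
            ("malignant", cfg.mcam_expressing_target_malignant),
            ("normal_epithelial", cfg.mcam_expressing_target_normal),
        ):
            base = cfg.mcam_expressing_base(cell_type)
            assert base + cfg.mcam_expressing_slope * cfg.mean_latent_t(cell_type) == (
                pytest.approx(target)
            )


class TestSimulateCellsStructure:
    def test_same_config_and_seed_identical(self, small_config):
        m1, a1, t1 = simulate_cells(small_config)
        m2, a2, t2 = simulate_cells(small_config)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert m1.obs_ids == m2.obs_ids and m1.gene_ids == m2.gene_ids
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(a1, a2)

    def test_different_seeds_differ(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        m1, _, _ = simulate_cells(small_config)
        m2, _, _ = simulate_cells(other)
        assert not np.array_equal(m1.values, m2.values)

    def test_latent_class_fractions_match_weights(self, small_config):
        _, ann, truth = simulate_cells(small_config)
        mal = truth[ann["cell_type"] == "malignant"]
        n = len(mal)
        for k, w in enumerate(small_config.emt_mixture_weights, start=1):
            lo, hi = three_sd_band(w, n)
            assert lo <= (mal["latent_class"] == k).mean() <= hi

    def test_mcam_expressing_fractions_calibrated(self, small_config):
        matrix, ann, _ = simulate_cells(small_config)
        for cell_type, target in (
            ("malignant", small_config.mcam_expressing_target_malignant),
            ("normal_epithelial", small_config.mcam_expressing_target_normal),
        ):
            subset = list(ann.index[ann["cell_type"] == cell_type])
            frac, _, n = proportion_expressing(matrix, "MCAM", subset)
            lo, hi = three_sd_band(target, n)
            assert lo <= frac <= hi, (cell_type, frac)

    def test_vascular_cells_express_their_markers(self, small_config):
        matrix, ann, _ = simulate_cells(small_config)
        ec = list(ann.index[ann["cell_type"] == "endothelial"])
        pvc = list(ann.index[ann["cell_type"] == "perivascular"])
        assert proportion_expressing(matrix, "KDR", ec)[0] > 0.95
        assert proportion_expressing(matrix, "CSPG4", pvc)[0] > 0.95
        assert proportion_expressing(matrix, "MCAM", ec)[0] > 0.95
        caf = list(ann.index[ann["cell_type"] == "CAF"])
        assert proportion_expressing(matrix, "VIM", caf)[0] == 0.0

    def test_epcam_higher_in_malignant_than_normal(self, small_config):
        matrix, ann, _ = simulate_cells(small_config)
        mal = list(ann.index[ann["cell_type"] == "malignant"])
        norm = list(ann.index[ann["cell_type"] == "normal_epithelial"])
        epcam = matrix.gene_values("EPCAM")
        idx = {o: i for i, o in enumerate(matrix.obs_ids)}
        res = mann_whitney_two_tailed(
            epcam[[idx[o] for o in mal]], epcam[[idx[o] for o in norm]]
        )
        assert res.p_two_tailed < 1e-6
        assert epcam[[idx[o] for o in mal]].mean() > epcam[[idx[o] for o in norm]].mean()


@pytest.fixture(scope="module")
def scored():
    cfg = SyntheticConfig(
        seed=11, n_malignant=6000, n_normal_epithelial=500,
        n_endothelial=50, n_perivascular=50, n_caf=50, n_immune=50,
        n_decoy_genes=20,
    )
    matrix, ann, truth = simulate_cells(cfg)
    mal = list(ann.index[ann["cell_type"] == "malignant"])
    mm = matrix.subset_obs(mal)
    scores = score_all(mm, cfg.signature_registry())
    return cfg, mm, scores, truth.loc[mal]


class TestParameterRecovery:

    def test_semt_tracks_latent_position(self, scored):
        _, _, scores, truth = scored
        r = spearman_with_ci(scores.scores["sEMT"], truth["latent_t"]).r
        assert r >= 0.8

    def test_percentile_calibrated_class_recovery(self, scored):
        cfg, _, scores, truth = scored
        th = calibrate_emt_thresholds(scores.scores["sEMT"], cfg.emt_mixture_weights)
        pred = classify_emt(scores, th)["emt_class"].map({"low": 1, "med": 2, "high": 3})
        acc = (pred.to_numpy() == truth["latent_class"].to_numpy()).mean()
        assert acc >= 0.85

    def test_mcam_level_rises_with_slope(self):
        # monotone coupling: mean MCAM among EMT-high expressers grows with c
        means = []
        for c in (1.0, 3.0, 6.0):
            cfg = SyntheticConfig(
                seed=5, n_malignant=5000, n_normal_epithelial=0,
                n_endothelial=0, n_perivascular=0, n_caf=0, n_immune=0,
                n_decoy_genes=5, mcam_level_slope=c,
            )
            matrix, _, truth = simulate_cells(cfg)
            mcam = matrix.gene_values("MCAM")
            high = (truth["latent_class"] == 3).to_numpy()
            expressed = mcam > 0
            means.append(mcam[high & expressed].mean())
        assert means[0] < means[1] < means[2]


class TestSimulateBulk:
    def test_deterministic(self, small_config):
        m1, t1 = simulate_bulk(small_config)
        m2, t2 = simulate_bulk(small_config)
        np.testing.assert_array_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_sang_recovers_vascular_fraction(self, small_config):
        matrix, truth = simulate_bulk(small_config)
        sang = score_signature(matrix, small_config.signature_registry()["sAng"])
        r = spearman_with_ci(sang.scores["sAng"], truth["vascular_fraction"]).r
        assert r >= 0.8

    def test_mcam_tracks_angiogenesis(self, small_config):
        matrix, _ = simulate_bulk(small_config)
        sang = score_signature(matrix, small_config.signature_registry()["sAng"])
        r = spearman_with_ci(sang.scores["sAng"], matrix.gene_values("MCAM")).r
        assert r > 0.5

    def test_no_vasculature_no_mcam(self):
        cfg = SyntheticConfig(
            seed=3, n_bulk=50, vascular_beta=(1e-4, 1e4),
            mcam_expressing_target_malignant=0.0,
            mcam_expressing_target_normal=0.0,
            mcam_expressing_slope=0.0,
            mcam_level_slope=0.0, mcam_level_intercept=0.0,
        )
        matrix, truth = simulate_bulk(cfg)
        assert truth["vascular_fraction"].max() < 0.01
        # MCAM stays at the noise floor relative to expressed genes
        assert matrix.gene_values("MCAM").max() < 0.05 * matrix.gene_values("VIM").mean()

    def test_bulk_semt_spans_linear_range(self, small_config):
        matrix, _ = simulate_bulk(small_config)
        reg = small_config.signature_registry()
        semt = score_signature(matrix, reg["sEMT"]).scores["sEMT"]
        assert semt.max() > 2000  # bulk thresholds are meaningful on this scale
        assert semt.min() < 2000


class TestSimulateMethylation:
    def test_noiseless_limit_exact(self):
        cfg = SyntheticConfig(seed=1, meth_probe_sd=0.0)
        expr = pd.Series([0.0, 1.0, 2.0], index=["a", "b", "c"])
        table = simulate_methylation(cfg, expr)
        expected = cfg.meth_a - cfg.meth_b * expr.to_numpy()
        np.testing.assert_allclose(
            table.M, np.broadcast_to(expected[:, None], table.M.shape)
        )

    def test_zero_coupling_uncorrelated(self):
        cfg = SyntheticConfig(seed=2, meth_b=0.0, meth_n_tumour=120, meth_n_normal=80)
        table, expr = simulate_methylation_cohort(cfg)
        summary = methylation_mean_m(table)
        r = methylation_expression_correlation(summary, expr).r
        assert abs(r) < 0.3

    def test_default_coupling_strongly_negative(self, small_config):
        table, expr = simulate_methylation_cohort(small_config)
        summary = methylation_mean_m(table)
        assert methylation_expression_correlation(summary, expr).r < -0.5

    def test_tumour_higher_m_than_normal(self, small_config):
        table, _ = simulate_methylation_cohort(small_config)
        summary = methylation_mean_m(table)
        t = summary.loc[summary["group"] == "tumour", "mean_M"]
        n = summary.loc[summary["group"] == "normal", "mean_M"]
        assert t.mean() > n.mean()
        assert mann_whitney_two_tailed(t, n).p_two_tailed < 1e-6


class TestHybridPeakMode:
    def test_max_combined_score_in_high_low_cell(self):
        cfg = SyntheticConfig(
            seed=13, n_malignant=8000, n_normal_epithelial=0,
            n_endothelial=0, n_perivascular=0, n_caf=0, n_immune=0,
            n_decoy_genes=10, hybrid_peak=True,
        )
        matrix, ann, _ = simulate_cells(cfg)
        scores = score_all(matrix, cfg.signature_registry())
        strata = stratify_cells(matrix, scores, ThresholdConfig.cell_defaults())
        summary = cross_tabulate(strata, scores)
        combined = summary["mean_sInv"] + summary["mean_sCSC"]
        assert combined.idxmax() == ("high", "low")


class TestThresholdCalibration:
    def test_cuts_sit_at_cumulative_weight_quantiles(self, rng):
        semt = rng.normal(0, 3, 10_000)
        th = calibrate_emt_thresholds(semt, (0.78, 0.18, 0.04))
        assert th.emt_low_upper == pytest.approx(np.quantile(semt, 0.78))
        assert th.emt_high_lower == pytest.approx(np.quantile(semt, 0.96))
        assert th.emt_low_upper < th.emt_high_lower

    def test_bad_weights_rejected(self):
        with pytest.raises(ConfigError):
            calibrate_emt_thresholds([1.0, 2.0], (0.5, 0.1, 0.1))
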