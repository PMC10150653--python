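"""Synthetic single-cell, bulk and methylation data with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale, with full ground truth for recovery tests:

* Malignant cells sit on a latent EMT position t in [0, 1] drawn from a
  three-component Beta mixture (weights 0.78 / 0.18 / 0.04 for the
  epithelial-like, hybrid and mesenchymal-like classes); normal epithelial
  cells are all epithelial-like (component 1).
* Epithelial marker genes decline linearly with t and mesenchymal markers
  rise with t; values are truncated-Gaussian on the log-normalised scale
  with mean-dependent dropout (a value is zeroed with probability
  1 - min(1, mu/d0)), the standard sparse single-cell convention.
* MCAM is sparse in the epithelial lineage: a Bernoulli gate whose
  probability rises with t, calibrated analytically so ~4% of malignant
  and ~10% of normal epithelial cells express it; the expressed level also
  rises with t.  Endothelial and perivascular cells express MCAM (and
  KDR / CSPG4 respectively) at a high vascular mean.
* Invasion and stemness signature genes rise with t; in ``hybrid_peak``
  mode they instead peak near t = 0.75, which reproduces qualitatively the
  observation that the mesenchymal-like / MCAM-low subpopulation carries
  the highest invasion + stemness means.
* Bulk samples are cell-type mixtures: a vascular fraction v ~ Beta(2, 8)
  split across endothelial/perivascular compartments, the remainder across
  malignant / normal epithelium / stroma; angiogenesis genes and MCAM
  track v, and per-sample malignant EMT composition varies via a Dirichlet
  draw so the bulk EMT score spans the 0-10,000 linear range the bulk
  thresholds (2,000 / 5,000) assume.
* Methylation: per sample, nine probe M-values ~ N(a - b * expression,
  probe sd) — promoter methylation inversely coupled to expression.

Identical config + seed gives byte-identical outputs (one seeded
generator, fixed draw order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError
from .types import (
    EMT_EPITHELIAL_GENES,
    EMT_MESENCHYMAL_GENES,
    ExpressionMatrix,
    GeneSignature,
    MethylationTable,
    SignatureRegistry,
    ThresholdConfig,
)

# marker genes with a defined role in the generator
MARKER_DECLINING = ("OVOL2", "ESRP1")        # epithelial-phenotype regulators
MARKER_RISING = ("TWIST1", "QKI", "S100A4")  # mesenchymal-phenotype regulators
VASCULAR_MARKERS = ("KDR", "CSPG4")          # endothelial / perivascular


@dataclass
class SyntheticConfig:
    """All generator knobs, with study-condition defaults."""

    seed: int = 0
    # cell counts per type
    n_malignant: int = 20_000
    n_normal_epithelial: int = 3_000
    n_endothelial: int = 1_000
    n_perivascular: int = 500
    n_caf: int = 1_000
    n_immune: int = 4_000
    # latent EMT mixture: weights and Beta(alpha, beta) component params
    emt_mixture_weights: tuple[float, float, float] = (0.78, 0.18, 0.04)
    emt_component_params: tuple[tuple[float, float], ...] = (
        (1.5, 10.0), (6.0, 6.0), (12.0, 2.0),
    )
    # expression model
    epithelial_amplitude: float = 2.0   # m_E: epithelial gene mean = m_E * (1 - t)
    mesenchymal_amplitude: float = 2.0  # m_M: mesenchymal gene mean = m_M * t
    noise_sd: float = 0.4
    dropout_d0: float = 2.0             # P(zeroed) = 1 - min(1, mu / d0)
    # MCAM sparsity and level
    mcam_expressing_target_malignant: float = 0.04
    mcam_expressing_target_normal: float = 0.10
    mcam_expressing_slope: float = 0.15   # expressing prob = base_ct + slope * t
    mcam_level_slope: float = 3.0         # expressed-cell mean = c * t + intercept
    mcam_level_intercept: float = 0.2
    vascular_mcam_mean: float = 3.5
    # other marker genes
    marker_amplitude: float = 2.0
    epcam_malignant_mean: float = 2.5
    epcam_normal_mean: float = 1.5
    # invasion / stemness / angiogenesis signature genes
    invasion_amplitude: float = 2.0
    hybrid_peak: bool = False            # peak sInv/sCSC genes at t ~ 0.75
    hybrid_peak_center: float = 0.75
    hybrid_peak_width: float = 0.12
    n_inv_genes: int = 10
    n_csc_genes: int = 20                # includes MMP1, shared with the EMT signature
    n_ang_genes: int = 10
    vascular_ang_amplitude: float = 3.0
    n_decoy_genes: int = 200
    decoy_mean: float = 0.5
    # bulk mixtures
    n_bulk: int = 500
    vascular_beta: tuple[float, float] = (2.0, 8.0)
    bulk_scale: float = 1000.0
    bulk_noise_sigma: float = 0.1        # multiplicative log-normal sigma
    bulk_emt_concentration: float = 2.0  # Dirichlet concentration on the mixture weights
    stroma_mesenchymal_amplitude: float = 3.0
    bulk_remainder_fractions: tuple[float, float, float] = (0.6, 0.1, 0.3)
    # methylation
    meth_a: float = 2.0                  # mean M = a - b * expression
    meth_b: float = 1.5
    meth_probe_sd: float = 0.3
    n_probes: int = 9
    meth_n_tumour: int = 120
    meth_n_normal: int = 60
    meth_tumour_expr_mean: float = 0.6
    meth_normal_expr_mean: float = 1.6
    meth_expr_sd: float = 0.4

    def __post_init__(self) -> None:
        w = np.asarray(self.emt_mixture_weights, dtype=float)
        if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("emt_mixture_weights must be 3 non-negative values summing to 1")
        if len(self.emt_component_params) != 3 or any(
            a <= 0 or b <= 0 for a, b in self.emt_component_params
        ):
            raise ConfigError("emt_component_params must be 3 positive (alpha, beta) pairs")
        for name in (
            "n_malignant", "n_normal_epithelial", "n_endothelial",
            "n_perivascular", "n_caf", "n_immune", "n_bulk", "n_probes",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in (
            "epithelial_amplitude", "mesenchymal_amplitude", "noise_sd",
            "dropout_d0", "meth_probe_sd", "bulk_noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        fr = np.asarray(self.bulk_remainder_fractions, dtype=float)
        if fr.size != 3 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ConfigError("bulk_remainder_fractions must be 3 fractions summing to 1")

    # ---- derived quantities ------------------------------------------------

    def component_means(self) -> np.ndarray:
        return np.array([a / (a + b) for a, b in self.emt_component_params])

    def mean_latent_t(self, cell_type: str) -> float:
        """Expected latent EMT position for a cell type's mixture."""
        means = self.component_means()
        if cell_type == "malignant":
            return float(np.dot(self.emt_mixture_weights, means))
        if cell_type == "normal_epithelial":
            return float(means[0])
        raise ConfigError(f"no latent EMT for cell type {cell_type!r}")

    def mcam_expressing_base(self, cell_type: str) -> float:
        """Calibrated Bernoulli-gate intercept.

        Chosen so E[base + slope * t] equals the target expressing fraction
        under the configured latent mixture (4% malignant, 10% normal
        epithelium by default), for any mixture config.
        """
        target = (
            self.mcam_expressing_target_malignant
            if cell_type == "malignant"
            else self.mcam_expressing_target_normal
        )
        return target - self.mcam_expressing_slope * self.mean_latent_t(cell_type)

    def gene_panel(self) -> dict[str, list[str]]:
        """Ordered gene groups of the synthetic panel."""
        inv = [f"INV{i:02d}" for i in range(1, self.n_inv_genes + 1)]
        csc = [f"CSC{i:02d}" for i in range(1, self.n_csc_genes)] + ["MMP1"]
        ang = [f"ANG{i:02d}" for i in range(1, self.n_ang_genes + 1)]
        decoys = [f"DECOY{i:03d}" for i in range(1, self.n_decoy_genes + 1)]
        return {
            "epithelial": list(EMT_EPITHELIAL_GENES),
            "mesenchymal": list(EMT_MESENCHYMAL_GENES),
            "markers": ["MCAM", "EPCAM", *VASCULAR_MARKERS, *MARKER_DECLINING, *MARKER_RISING],
            "inv": inv,
            "csc": csc,
            "ang": ang,
            "decoy": decoys,
        }

    def all_genes(self) -> list[str]:
        genes: list[str] = []
        for group in self.gene_panel().values():
            genes.extend(g for g in group if g not in genes)  # MMP1 appears once
        return genes

    def signature_registry(self) -> SignatureRegistry:
        """Registry matching the synthetic panel: built-in sEMT plus mean
        signatures over the synthetic invasion/stemness/angiogenesis genes."""
        panel = self.gene_panel()
        reg = SignatureRegistry.with_defaults()
        reg.add(GeneSignature("sInv", "mean", tuple(panel["inv"])))
        reg.add(GeneSignature("sCSC", "mean", tuple(panel["csc"])))
        reg.add(GeneSignature("sAng", "mean", tuple(panel["ang"])))
        return reg

    def to_dict(self) -> dict:
        return asdict(self)


# ---- core sampling helpers -------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mean, sd: float, size) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf) — strictly positive draws."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if sd == 0:
        return np.maximum(mean, np.finfo(float).tiny)
    a = (0.0 - mean) / sd
    u = rng.uniform(scipy.stats.norm.cdf(a), 1.0, size=size)
    return mean + sd * scipy.stats.norm.ppf(u)


def _noisy_dropout_block(
    rng: np.random.Generator, mu: np.ndarray, sd: float, d0: float
) -> np.ndarray:
    """value = dropout(max(0, mu + N(0, sd))); P(keep) = min(1, mu/d0)."""
    values = np.maximum(0.0, mu + rng.normal(0.0, sd, size=mu.shape))
    keep = rng.random(mu.shape) < np.minimum(1.0, mu / d0)
    return values * keep


def _latent_emt(
    rng: np.random.Generator, config: SyntheticConfig, n: int, force_class_1: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (class in {1,2,3}, t in [0,1]) for n epithelial-lineage cells."""
    if force_class_1:
        classes = np.ones(n, dtype=int)
    else:
        classes = rng.choice([1, 2, 3], size=n, p=list(config.emt_mixture_weights))
    t = np.empty(n)
    for k, (a, b) in enumerate(config.emt_component_params, start=1):
        mask = classes == k
        t[mask] = rng.beta(a, b, size=int(mask.sum()))
    return classes, t


def _inv_csc_profile(config: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    """Mean profile of invasion/stemness genes as a function of t."""
    if config.hybrid_peak:
        return np.exp(-((t - config.hybrid_peak_center) ** 2)
                      / (2.0 * config.hybrid_peak_width ** 2))
    return t


# ---- simulators ------------------------------------------------------------


def simulate_cells(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the single-cell atlas structure.

    Returns ``(matrix, annotation, truth)``: a log-normalised cell x gene
    matrix, a per-cell annotation (cell_type, patient_id, subtype) and the
    ground truth (latent_class, latent_t; NaN outside the epithelial
    lineage).
    """
    rng = np.random.default_rng(config.seed)
    panel = config.gene_panel()
    genes = config.all_genes()
    gene_idx = {g: j for j, g in enumerate(genes)}
    cols = {grp: np.array([gene_idx[g] for g in gs]) for grp, gs in panel.items()}

    blocks = [
        ("malignant", config.n_malignant),
        ("normal_epithelial", config.n_normal_epithelial),
        ("endothelial", config.n_endothelial),
        ("perivascular", config.n_perivascular),
        ("CAF", config.n_caf),
        ("immune", config.n_immune),
    ]
    n_total = sum(n for _, n in blocks)
    values = np.zeros((n_total, len(genes)))
    cell_types: list[str] = []
    latent_class = np.full(n_total, np.nan)
    latent_t = np.full(n_total, np.nan)

    row = 0
    for cell_type, n in blocks:
        if n == 0:
            continue
        sl = slice(row, row + n)
        cell_types.extend([cell_type] * n)
        mu = np.zeros((n, len(genes)))

        if cell_type in ("malignant", "normal_epithelial"):
            classes, t = _latent_emt(
                rng, config, n, force_class_1=(cell_type == "normal_epithelial")
            )
            latent_class[sl] = classes
            latent_t[sl] = t
            mu[:, cols["epithelial"]] = (config.epithelial_amplitude * (1.0 - t))[:, None]
            mu[:, cols["mesenchymal"]] = (config.mesenchymal_amplitude * t)[:, None]
            mu[:, [gene_idx[g] for g in MARKER_DECLINING]] = (
                config.marker_amplitude * (1.0 - t)
            )[:, None]
            mu[:, [gene_idx[g] for g in MARKER_RISING]] = (
                config.marker_amplitude * t
            )[:, None]
            epcam = (
                config.epcam_malignant_mean
                if cell_type == "malignant"
                else config.epcam_normal_mean
            )
            mu[:, gene_idx["EPCAM"]] = epcam
            profile = _inv_csc_profile(config, t)
            mu[:, cols["inv"]] = (config.invasion_amplitude * profile)[:, None]
            mu[:, cols["csc"]] = (config.invasion_amplitude * profile)[:, None]
        elif cell_type == "endothelial":
            mu[:, gene_idx["KDR"]] = config.vascular_mcam_mean
            mu[:, cols["ang"]] = config.vascular_ang_amplitude
        elif cell_type == "perivascular":
            mu[:, gene_idx["CSPG4"]] = config.vascular_mcam_mean
            mu[:, cols["ang"]] = config.vascular_ang_amplitude
        # CAF / immune: no signature genes

        mu[:, cols["decoy"]] = config.decoy_mean
        block = _noisy_dropout_block(rng, mu, config.noise_sd, config.dropout_d0)

        # MCAM overrides the generic scheme: Bernoulli gate + positive level
        mcam = np.zeros(n)
        if cell_type in ("malignant", "normal_epithelial"):
            base = config.mcam_expressing_base(cell_type)
            p_express = np.clip(
                base + config.mcam_expressing_slope * latent_t[sl], 0.0, 1.0
            )
            gate = rng.random(n) < p_express
            level_mean = (
                config.mcam_level_slope * latent_t[sl] + config.mcam_level_intercept
            )
            mcam[gate] = _truncated_normal(
                rng, level_mean[gate], config.noise_sd, int(gate.sum())
            )
        elif cell_type in ("endothelial", "perivascular"):
            mcam = _truncated_normal(rng, config.vascular_mcam_mean, config.noise_sd, n)
        block[:, gene_idx["MCAM"]] = mcam

        # MMP1 is both a mesenchymal EMT gene and a stemness-signature gene;
        # in the epithelial lineage the mesenchymal rule (mu = m_M * t) wins.
        if cell_type in ("malignant", "normal_epithelial"):
            mmp1_mu = config.mesenchymal_amplitude * latent_t[sl]
            block[:, gene_idx["MMP1"]] = _noisy_dropout_block(
                rng, mmp1_mu[:, None], config.noise_sd, config.dropout_d0
            )[:, 0]

        values[sl] = block
        row += n

    obs_ids = [f"cell{i:06d}" for i in range(n_total)]
    matrix = ExpressionMatrix(
        obs_ids=obs_ids, gene_ids=genes, values=values,
        scale="log_normalized", obs_kind="cell",
    )
    annotation = pd.DataFrame(
        {
            "cell_type": cell_types,
            "patient_id": "synthetic_patient",
            "subtype": "synthetic",
        },
        index=pd.Index(obs_ids, name="obs_id"),
    )
    truth = pd.DataFrame(
        {
            "cell_type": cell_types,
            "latent_class": latent_class,
            "latent_t": latent_t,
        },
        index=pd.Index(obs_ids, name="obs_id"),
    )
    return matrix, annotation, truth


def simulate_bulk(config: SyntheticConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate bulk tumours as cell-type mixtures on a linear scale.

    Returns ``(matrix, truth)`` where truth holds each sample's vascular
    fraction v and mean malignant EMT position t̄.
    """
    rng = np.random.default_rng(config.seed + 1)
    panel = config.gene_panel()
    genes = config.all_genes()
    gene_idx = {g: j for j, g in enumerate(genes)}
    n = config.n_bulk
    if n == 0:
        raise ConfigError("n_bulk must be positive")

    v = rng.beta(*config.vascular_beta, size=n)
    # per-sample malignant EMT composition: Dirichlet around the cohort weights
    alpha = config.bulk_emt_concentration * np.asarray(config.emt_mixture_weights)
    sample_weights = rng.dirichlet(alpha, size=n)
    t_bar = sample_weights @ config.component_means()

    f_mal, f_norm, f_stroma = config.bulk_remainder_fractions
    r = 1.0 - v
    w_mal, w_norm, w_stroma = f_mal * r, f_norm * r, f_stroma * r
    w_ec = w_pvc = v / 2.0
    t_norm = config.mean_latent_t("normal_epithelial")

    profile = np.zeros((n, len(genes)))

    def add(gene_list, contribution):
        idx = [gene_idx[g] for g in gene_list]
        profile[:, idx] += np.asarray(contribution)[:, None]

    add(panel["epithelial"],
        w_mal * config.epithelial_amplitude * (1 - t_bar)
        + w_norm * config.epithelial_amplitude * (1 - t_norm))
    add(panel["mesenchymal"],
        w_mal * config.mesenchymal_amplitude * t_bar
        + w_norm * config.mesenchymal_amplitude * t_norm
        + w_stroma * config.stroma_mesenchymal_amplitude)
    add(MARKER_DECLINING, w_mal * config.marker_amplitude * (1 - t_bar))
    add(MARKER_RISING,
        w_mal * config.marker_amplitude * t_bar
        + w_stroma * config.marker_amplitude * 0.5)
    add(["EPCAM"],
        w_mal * config.epcam_malignant_mean + w_norm * config.epcam_normal_mean)
    add(["KDR"], w_ec * config.vascular_mcam_mean)
    add(["CSPG4"], w_pvc * config.vascular_mcam_mean)
    add(panel["ang"], (w_ec + w_pvc) * config.vascular_ang_amplitude)
    inv_profile = _inv_csc_profile(config, t_bar)
    add(panel["inv"], w_mal * config.invasion_amplitude * inv_profile)
    add([g for g in panel["csc"] if g != "MMP1"],
        w_mal * config.invasion_amplitude * inv_profile)
    add(panel["decoy"], np.full(n, config.decoy_mean))
    # MCAM: vascular compartments plus the expressing malignant/normal fraction
    mal_base = config.mcam_expressing_base("malignant")
    norm_base = config.mcam_expressing_base("normal_epithelial")
    p_mal = np.clip(mal_base + config.mcam_expressing_slope * t_bar, 0, 1)
    mcam_level_mal = config.mcam_level_slope * t_bar + config.mcam_level_intercept
    p_norm = np.clip(norm_base + config.mcam_expressing_slope * t_norm, 0, 1)
    mcam_level_norm = config.mcam_level_slope * t_norm + config.mcam_level_intercept
    add(["MCAM"],
        (w_ec + w_pvc) * config.vascular_mcam_mean
        + w_mal * p_mal * mcam_level_mal
        + w_norm * p_norm * mcam_level_norm)

    noise = rng.lognormal(0.0, config.bulk_noise_sigma, size=profile.shape)
    values = config.bulk_scale * profile * noise

    sample_ids = [f"tumour{i:04d}" for i in range(n)]
    matrix = ExpressionMatrix(
        obs_ids=sample_ids, gene_ids=genes, values=values,
        scale="linear", obs_kind="bulk_sample",
    )
    truth = pd.DataFrame(
        {"vascular_fraction": v, "mean_malignant_t": t_bar},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return matrix, truth


def simulate_methylation(
    config: SyntheticConfig,
    expression: pd.Series,
    groups: pd.Series | None = None,
) -> MethylationTable:
    """Simulate probe-level promoter methylation coupled to expression.

    Each sample gets ``n_probes`` M-values drawn N(a - b * expression,
    probe sd): higher expression, lower methylation.  ``groups`` labels
    samples tumour/normal (default: all tumour).
    """
    rng = np.random.default_rng(config.seed + 2)
    expression = pd.Series(expression, dtype=float)
    if groups is None:
        groups = pd.Series("tumour", index=expression.index)
    mean_m = config.meth_a - config.meth_b * expression.to_numpy()
    M = mean_m[:, None] + rng.normal(
        0.0, config.meth_probe_sd, size=(len(expression), config.n_probes)
    )
    return MethylationTable(
        sample_ids=[str(s) for s in expression.index],
        groups=[str(g) for g in groups.loc[expression.index]],
        probe_ids=[f"cg{i:03d}" for i in range(1, config.n_probes + 1)],
        M=M,
        expression=dict(zip((str(s) for s in expression.index), expression)),
    )


def simulate_methylation_cohort(
    config: SyntheticConfig,
) -> tuple[MethylationTable, pd.Series]:
    """Tumour + normal methylation cohort with matched expression.

    Tumour samples draw lower promoter-region expression than normals
    (hence higher M on average).  Returns (table, expression series).
    """
    rng = np.random.default_rng(config.seed + 3)
    n_t, n_n = config.meth_n_tumour, config.meth_n_normal
    expr = np.concatenate([
        np.maximum(0.0, rng.normal(config.meth_tumour_expr_mean, config.meth_expr_sd, n_t)),
        np.maximum(0.0, rng.normal(config.meth_normal_expr_mean, config.meth_expr_sd, n_n)),
    ])
    ids = [f"T{i:03d}" for i in range(n_t)] + [f"N{i:03d}" for i in range(n_n)]
    groups = pd.Series(["tumour"] * n_t + ["normal"] * n_n, index=ids)
    expression = pd.Series(expr, index=ids)
    return simulate_methylation(config, expression, groups), expression


def calibrate_emt_thresholds(
    semt_values, weights=(0.78, 0.18, 0.04), obs_kind: str = "cell"
) -> ThresholdConfig:
    """Set class boundaries from the score distribution itself.

    Boundaries are the empirical quantiles at the cumulative mixture
    weights (78th and 96th percentiles by default) — the documented
    recalibration procedure when the fixed 0/5 cuts do not suit a dataset's
    score distribution.
    """
    semt_values = np.asarray(semt_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.size != 3 or abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError("weights must be 3 values summing to 1")
    low_upper, high_lower = np.quantile(semt_values, [w[0], w[0] + w[1]])
    return ThresholdConfig(
        emt_low_upper=float(low_upper),
        emt_high_lower=float(high_lower),
        obs_kind=obs_kind,
    )
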