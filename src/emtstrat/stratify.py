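"""EMT-spectrum classes and the MCAM tri-partition.

Cells (or bulk tumours) are placed on the EMT spectrum by thresholding
their EMT score into three classes enriched for epithelial-like, hybrid
E/M and mesenchymal-like states:

    low  : sEMT <  emt_low_upper        (cell default 0; bulk 2,000)
    med  : emt_low_upper <= sEMT < emt_high_lower
    high : sEMT >= emt_high_lower       (cell default 5; bulk 5,000)

Intervals are half-open so every real score is classified and the mapping
is monotone in the score.

Within any grouping (by default the EMT class), cells are tri-partitioned
by MCAM expression: non-expressers (value <= detection threshold) are
``neg``; the remaining expressers are ranked ascending and split into two
equal halves, ``low`` then ``high``, with the extra cell of an odd count
going to ``low``.  Ties at the median boundary are broken by stable input
order, making the partition deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError, MissingGeneError
from .stats import ComparisonResult, CorrelationResult, mann_whitney_two_tailed, spearman_with_ci
from .types import ExpressionMatrix, ScoreTable, ThresholdConfig

EMT_CLASSES = ("low", "med", "high")
MCAM_CLASSES = ("neg", "low", "high")


def classify_emt(
    scores: ScoreTable,
    thresholds: ThresholdConfig,
    score_column: str = "sEMT",
    override_scale_check: bool = False,
) -> pd.DataFrame:
    """Assign each scored observation an EMT class.

    Returns a DataFrame indexed by obs_id with an ``emt_class`` column.
    Refuses cell thresholds on a bulk score table (and vice versa) unless
    ``override_scale_check`` — the 0/5 and 2,000/5,000 boundaries live on
    different scales.
    """
    if score_column not in scores.scores.columns:
        raise InsufficientDataError(f"score column {score_column!r} not present")
    if thresholds.obs_kind != scores.obs_kind and not override_scale_check:
        raise ConfigError(
            f"thresholds were set for obs_kind={thresholds.obs_kind!r} but the "
            f"score table is obs_kind={scores.obs_kind!r}; pass "
            "override_scale_check=True only if this is intentional"
        )
    s = scores.scores[score_column].to_numpy(dtype=float)
    emt = np.where(
        s < thresholds.emt_low_upper, "low",
        np.where(s < thresholds.emt_high_lower, "med", "high"),
    )
    return pd.DataFrame(
        {"emt_class": pd.Categorical(emt, categories=list(EMT_CLASSES))},
        index=scores.scores.index.copy(),
    )


def mcam_tripartition(
    expr: pd.Series,
    group_ids: pd.Series,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Tri-partition observations into MCAM neg / low / high within groups.

    ``expr`` holds per-observation MCAM expression, ``group_ids`` the
    grouping label (typically the EMT class) with the same index.  Empty
    groups yield no rows.  Returns a DataFrame indexed like ``expr`` with
    columns ``mcam_class`` and ``group_id``.
    """
    detection = 0.0 if thresholds is None else thresholds.detection_threshold
    expr = pd.Series(expr).astype(float)
    group_ids = pd.Series(group_ids)
    if not expr.index.equals(group_ids.index):
        group_ids = group_ids.reindex(expr.index)
        if group_ids.isna().any():
            raise InsufficientDataError("every observation needs a group_id")

    mcam_class = pd.Series(index=expr.index, dtype=object)
    for _, idx in expr.groupby(group_ids, observed=True).groups.items():
        values = expr.loc[idx]
        expressing = values > detection
        mcam_class.loc[idx[~expressing]] = "neg"
        expressers = values[expressing]
        k = len(expressers)
        if k == 0:
            continue
        # stable sort: ties at the median boundary resolve by input order
        order = expressers.to_numpy().argsort(kind="stable")
        n_low = (k + 1) // 2  # odd count -> extra cell to low
        low_ids = expressers.index[order[:n_low]]
        high_ids = expressers.index[order[n_low:]]
        mcam_class.loc[low_ids] = "low"
        mcam_class.loc[high_ids] = "high"
    return pd.DataFrame(
        {
            "mcam_class": pd.Categorical(mcam_class, categories=list(MCAM_CLASSES)),
            "group_id": group_ids,
        }
    )


def stratify_cells(
    matrix: ExpressionMatrix,
    scores: ScoreTable,
    thresholds: ThresholdConfig,
    mcam_gene: str = "MCAM",
) -> pd.DataFrame:
    """Full strata table: EMT class plus within-class MCAM tri-partition."""
    if not matrix.has_gene(mcam_gene):
        raise MissingGeneError([mcam_gene])
    strata = classify_emt(scores, thresholds)
    mcam = pd.Series(matrix.gene_values(mcam_gene), index=pd.Index(matrix.obs_ids))
    mcam = mcam.loc[strata.index]
    tri = mcam_tripartition(mcam, strata["emt_class"], thresholds)
    strata["mcam_class"] = tri["mcam_class"]
    strata["group_id"] = strata["emt_class"].astype(str)
    return strata


def cross_tabulate(strata: pd.DataFrame, scores: ScoreTable) -> pd.DataFrame:
    """Nine-subpopulation summary: n, mean sInv and mean sCSC per
    (emt_class, mcam_class) cell.

    Empty combinations appear with n = 0 and NaN means.  The n column sums
    to the number of partitioned observations.
    """
    for col in ("sInv", "sCSC"):
        if col not in scores.scores.columns:
            raise InsufficientDataError(f"score column {col!r} required for the summary")
    joined = strata[["emt_class", "mcam_class"]].join(
        scores.scores[["sInv", "sCSC"]], how="inner"
    )
    if len(joined) < len(strata):
        raise InsufficientDataError("some stratified observations lack scores")
    grouped = joined.groupby(["emt_class", "mcam_class"], observed=False)
    summary = grouped.agg(
        n_cells=("sInv", "size"),
        mean_sInv=("sInv", "mean"),
        mean_sCSC=("sCSC", "mean"),
    )
    full_index = pd.MultiIndex.from_product(
        [list(EMT_CLASSES), list(MCAM_CLASSES)], names=["emt_class", "mcam_class"]
    )
    summary = summary.reindex(full_index)
    summary["n_cells"] = summary["n_cells"].fillna(0).astype(int)
    return summary


def subpopulation_correlation(summary: pd.DataFrame) -> CorrelationResult:
    """Spearman correlation of mean sInv vs mean sCSC across subpopulations."""
    defined = summary.dropna(subset=["mean_sInv", "mean_sCSC"])
    if len(defined) < 3:
        raise InsufficientDataError(
            f"need >= 3 subpopulations with defined means, got {len(defined)}"
        )
    return spearman_with_ci(defined["mean_sInv"], defined["mean_sCSC"])


@dataclass(frozen=True)
class StratumExpression:
    """Per-EMT-class expression of one gene plus pairwise comparisons."""

    gene: str
    values: dict[str, np.ndarray]           # emt_class -> values
    comparisons: dict[tuple[str, str], ComparisonResult]


def expression_by_stratum(
    matrix: ExpressionMatrix, gene: str, strata: pd.DataFrame
) -> StratumExpression:
    """Expression of one gene split by EMT class, with the three pairwise
    two-tailed Mann-Whitney comparisons (low-med, med-high, low-high).

    Used to check that independent EMT regulators (OVOL2, TWIST1, ESRP1,
    QKI, S100A4) and MCAM itself track the score-defined classes.
    """
    expr = pd.Series(matrix.gene_values(gene), index=pd.Index(matrix.obs_ids))
    expr = expr.loc[strata.index]
    values = {
        cls: expr[strata["emt_class"] == cls].to_numpy() for cls in EMT_CLASSES
    }
    comparisons = {}
    for a, b in (("low", "med"), ("med", "high"), ("low", "high")):
        if values[a].size and values[b].size:
            comparisons[(a, b)] = mann_whitney_two_tailed(values[a], values[b])
    return StratumExpression(gene=gene, values=values, comparisons=comparisons)


def strata_to_tsv(strata: pd.DataFrame, path) -> None:
    strata.to_csv(path, sep="\t", index_label="obs_id")


def summary_to_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", float_format="%.10g")
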