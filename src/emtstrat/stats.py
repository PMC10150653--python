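"""Nonparametric comparisons and correlation used across the analysis.

Conventions, chosen to match the mainstream statistics packages the field
relies on:

* Two-tailed exact p-values are 2 x the one-tail probability, capped at 1.
* Mann-Whitney: the U statistic of the first sample; exact p when
  n1 + n2 <= 25 and there are no ties across the pooled sample, otherwise
  a normal approximation with tie correction and continuity correction.
* Wilcoxon matched-pairs signed-rank: W = min of the two signed-rank sums
  over nonzero differences; exact p for <= 25 nonzero differences (a
  midrank convolution handles tied |d| exactly — equivalent to enumerating
  all 2^n sign patterns), otherwise the tie-corrected normal
  approximation.  Zero differences are dropped; all-zero input is a
  degenerate-data error rather than p = 1.
* Spearman: r on average ranks; p from the t approximation
  t = r * sqrt((n-2)/(1-r^2)); the 95% CI from the Fisher z transform,
  z +/- z_{1-alpha/2}/sqrt(n-3).  r = +/-1 yields the degenerate CI [r, r]
  and the smallest positive float as p (the Fisher z is infinite; NaN
  must never be emitted).

The ``method`` field of every comparison records whether the exact or the
approximate path produced the p-value, so results stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateDataError, InsufficientDataError
from .types import ExpressionMatrix, MethylationTable

EXACT_LIMIT = 25  # combined-n boundary between exact and normal-approximation p


@dataclass(frozen=True)
class ComparisonResult:
    test: str           # "mann_whitney" | "wilcoxon_paired"
    statistic: float    # U for Mann-Whitney, W for Wilcoxon
    p_two_tailed: float
    n1: int
    n2: int
    method: str         # "exact" | "normal_approx"

    def __post_init__(self) -> None:
        assert 0.0 < self.p_two_tailed <= 1.0


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    def __post_init__(self) -> None:
        assert self.ci_low <= self.r <= self.ci_high


def _as_clean_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise InsufficientDataError(f"{name}: empty sample")
    if not np.all(np.isfinite(arr)):
        raise DegenerateDataError(f"{name}: non-finite values")
    return arr


def mann_whitney_two_tailed(x, y) -> ComparisonResult:
    """Two-tailed Mann-Whitney U test (U reported for the first sample)."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= EXACT_LIMIT and not has_ties
    res = scipy.stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return ComparisonResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_two_tailed=min(1.0, max(float(res.pvalue), np.finfo(float).tiny)),
        n1=int(x.size),
        n2=int(y.size),
        method="exact" if exact else "normal_approx",
    )


def _wilcoxon_exact_p(ranks: np.ndarray, w: float) -> float:
    """Exact two-tailed p for signed-rank sum W = min(R+, R-).

    Convolves the characteristic polynomial prod_i (1 + z^{2 r_i}) over the
    midranks (doubled so tied midranks like 1.5 become integers), which
    counts sign patterns by their positive-rank sum — identical to the full
    2^n enumeration but polynomial time.  By symmetry of R+ and R-,
    p = min(1, 2 * P(R+ <= w)).
    """
    doubled = np.rint(2 * ranks).astype(int)
    dist = np.zeros(doubled.sum() + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    dist /= 2.0 ** len(doubled)
    w2 = int(np.rint(2 * w))
    return min(1.0, 2.0 * float(dist[: w2 + 1].sum()))


def wilcoxon_paired_two_tailed(x, y) -> ComparisonResult:
    """Two-tailed Wilcoxon matched-pairs signed-rank test."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size:
        raise InsufficientDataError(
            f"paired samples differ in length ({x.size} vs {y.size})"
        )
    if x.size < 2:
        raise InsufficientDataError("need at least 2 pairs")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = scipy.stats.rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    w = min(r_plus, r_minus)
    if d.size <= EXACT_LIMIT:
        p = _wilcoxon_exact_p(ranks, w)
        method = "exact"
    else:
        res = scipy.stats.wilcoxon(
            x, y, zero_method="wilcox", correction=True, method="approx",
        )
        p = float(res.pvalue)
        method = "normal_approx"
    return ComparisonResult(
        test="wilcoxon_paired",
        statistic=w,
        p_two_tailed=min(1.0, max(p, np.finfo(float).tiny)),
        n1=int(x.size),
        n2=int(y.size),
        method=method,
    )


def spearman_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Spearman rank correlation with Fisher-z confidence interval."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size:
        raise InsufficientDataError(f"x and y differ in length ({x.size} vs {y.size})")
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateDataError("correlation undefined for a constant variable")
    r = float(scipy.stats.spearmanr(x, y).statistic)

    tiny = float(np.finfo(float).tiny)
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return CorrelationResult(r=r, ci_low=r, ci_high=r, p=tiny, n=n)

    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), df=n - 2))
    p = min(1.0, max(p, tiny))
    if n >= 4:
        z = np.arctanh(r)
        half = scipy.stats.norm.ppf(1.0 - alpha / 2.0) / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    else:
        ci_low, ci_high = -1.0, 1.0  # CI undefined below n=4; report the full range
    return CorrelationResult(r=r, ci_low=ci_low, ci_high=ci_high, p=p, n=n)


def proportion_expressing(
    matrix: ExpressionMatrix,
    gene: str,
    obs_subset=None,
    detection_threshold: float = 0.0,
) -> tuple[float, int, int]:
    """Fraction of observations expressing ``gene`` (value > threshold).

    Returns (fraction, n_expressing, n_total) over ``obs_subset`` (all
    observations by default).
    """
    values = matrix.gene_values(gene)
    if obs_subset is not None:
        index = {o: i for i, o in enumerate(matrix.obs_ids)}
        rows = [index[o] for o in obs_subset]
        if not rows:
            raise InsufficientDataError("empty observation subset")
        values = values[rows]
    n_total = int(values.size)
    n_expr = int(np.sum(values > detection_threshold))
    return n_expr / n_total, n_expr, n_total


def methylation_mean_m(table: MethylationTable) -> pd.DataFrame:
    """Per-sample mean M-value over available (non-NaN) probes.

    Returns a DataFrame indexed by sample_id with columns ``group`` and
    ``mean_M``.  Samples with no available probes are excluded (the index
    simply omits them); the tumour-vs-normal comparison is a separate call
    to :func:`mann_whitney_two_tailed` on the two groups.
    """
    available = ~np.isnan(table.M)
    counts = available.sum(axis=1)
    sums = np.where(available, table.M, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_m = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    df = pd.DataFrame(
        {"group": table.groups, "mean_M": mean_m},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    dropped = df.index[~np.isfinite(df["mean_M"])]
    if len(dropped):
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d sample(s) with no available probes: %s",
            len(dropped), ", ".join(dropped),
        )
        df = df.loc[np.isfinite(df["mean_M"])]
    return df


def methylation_group_comparison(summary: pd.DataFrame) -> ComparisonResult:
    """Tumour vs normal comparison of per-sample mean M-values."""
    tumour = summary.loc[summary["group"] == "tumour", "mean_M"]
    normal = summary.loc[summary["group"] == "normal", "mean_M"]
    return mann_whitney_two_tailed(tumour, normal)


def methylation_expression_correlation(
    summary: pd.DataFrame, expression: pd.Series | dict
) -> CorrelationResult:
    """Spearman correlation of per-sample mean M with matched expression.

    ``expression`` maps sample_id -> expression value; samples without a
    match on either side are dropped (and logged).  Requires >= 4 matched
    pairs.
    """
    expr = pd.Series(expression, dtype=float)
    matched = summary.index.intersection(expr.index)
    dropped = len(summary.index.union(expr.index)) - len(matched)
    if dropped:
        import logging

        logging.getLogger(__name__).info("dropped %d unmatched sample(s)", dropped)
    if len(matched) < 4:
        raise InsufficientDataError(
            f"need >= 4 matched samples for correlation, got {len(matched)}"
        )
    return spearman_with_ci(summary.loc[matched, "mean_M"], expr.loc[matched])
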