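"""Pooled targeted-bisulfite differential methylation statistics.

Works on per-CpG methylated/total read counts from pooled amplicon
bisulfite sequencing (Bismark-coverage-like tables), where each pool of
age-matched contributors is one library and the pool-level methylation
proportion approximates the group mean. The same operations serve RRBS
data via a stricter QC preset (>50 reads per CpG and >10 CpGs per tRNA).

Statistics:

* coverage QC (default minimum 25 reads per CpG in every compared pool);
* pairwise age-group comparison per tRNA region — a paired t-test pairing
  CpG sites across the two groups (pools averaged within group), plus
  per-CpG two-sample tests combined by Fisher's method (with an optional
  Brown-type dependence adjustment);
* one-sided Wilcoxon rank-sum group comparisons with a Hodges-Lehmann
  shift estimate and one-sided confidence bound;
* per-CpG simple linear regression on pool age, in both orientations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CpGCount",
    "PairwiseDiffResult",
    "RankSumResult",
    "coverage_filter",
    "rrbs_filter",
    "pairwise_region_test",
    "combine_pvalues",
    "brown_combine_pvalues",
    "rank_sum_compare",
    "fit_pool_age_regression",
    "read_bismark_cov",
    "methylation_proportions",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["chrom", "pos", "meth_reads", "total_reads"]


@dataclass(frozen=True)
class CpGCount:
    """Methylated/total read counts for one CpG in one pool."""

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int
    pool_id: str = ""
    pool_age: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.meth_reads <= self.total_reads):
            raise ValueError("require 0 <= meth_reads <= total_reads")

    @property
    def proportion(self) -> float:
        return self.meth_reads / self.total_reads


@dataclass
class PairwiseDiffResult:
    """Region-level differential methylation between two age groups."""

    trna: str
    comparison: str
    num_cpgs: int
    delta: float  # mean over CpGs of (group_b - group_a), proportions
    paired_t_p: float
    per_cpg_p: list[float] = field(default_factory=list)
    combined_p: float = 1.0
    combined_method: str = "fisher"
    flag: str = ""  # "", "zero_variance", "single_cpg"


@dataclass
class RankSumResult:
    """One-sided Wilcoxon rank-sum comparison of two value sets."""

    statistic: float  # W: rank-sum U of the first sample (R convention)
    p_value: float
    shift_estimate: float  # Hodges-Lehmann median of pairwise differences
    conf_bound: float  # one-sided confidence bound on the shift
    alternative: str


def read_bismark_cov(path: str | Path, pool_id: str = "", pool_age: float = np.nan) -> pd.DataFrame:
    """Read a Bismark coverage-style TSV into a tidy count table.

    Expected columns: chrom, start, end, methylation %, count methylated,
    count unmethylated (no header). Returns chrom, pos (1-based = start),
    meth_reads, total_reads, pool_id, pool_age.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "pct", "meth", "unmeth"],
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(int),
            "meth_reads": df["meth"].astype(int),
            "total_reads": (df["meth"] + df["unmeth"]).astype(int),
            "pool_id": pool_id,
            "pool_age": pool_age,
        }
    )
    return out


def coverage_filter(counts: pd.DataFrame, min_reads: int = 25) -> pd.DataFrame:
    """Drop CpG records with fewer than ``min_reads`` total reads."""
    return counts[counts["total_reads"] >= min_reads].reset_index(drop=True)


def rrbs_filter(
    counts: pd.DataFrame,
    min_reads: int = 50,
    min_cpgs_per_trna: int = 10,
    trna_col: str = "trna",
) -> pd.DataFrame:
    """RRBS QC preset: >50 reads per CpG and strictly >10 data points per tRNA.

    ``min_reads`` is inclusive on reads (>=50 would be >49; the preset
    keeps records with total_reads > ``min_reads``); a tRNA is retained only
    if it keeps strictly more than ``min_cpgs_per_trna`` CpG data points.
    """
    kept = counts[counts["total_reads"] > min_reads]
    sizes = kept.groupby(trna_col)["pos"].transform("size")
    return kept[sizes > min_cpgs_per_trna].reset_index(drop=True)


def methylation_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot a count table to a CpG x pool matrix of methylation proportions.

    Technical replicates of a pool (duplicate pool_id/pos rows) have their
    reads summed before the proportion is taken.
    """
    agg = (
        counts.groupby(["chrom", "pos", "pool_id"])[["meth_reads", "total_reads"]]
        .sum()
        .reset_index()
    )
    agg["proportion"] = agg["meth_reads"] / agg["total_reads"]
    return agg.pivot_table(
        index=["chrom", "pos"], columns="pool_id", values="proportion"
    )


def combine_pvalues(ps: Sequence[float]) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi2(2k); a single p is returned
    as itself. Zero p-values are clipped to a tiny positive floor (1e-300)
    so the chi-square tail stays representable."""
    ps = list(ps)
    if not ps:
        raise ValueError("no p-values to combine")
    arr = np.asarray(ps, dtype=float)
    if (arr <= 0).any():
        logger.warning("p-value <= 0 clipped before Fisher combination")
        arr = np.clip(arr, 1e-300, 1.0)
    if (arr > 1).any():
        raise ValueError("p-values must be <= 1")
    if len(arr) == 1:
        return float(arr[0])
    x = -2.0 * np.log(arr).sum()
    return float(stats.chi2.sf(x, 2 * len(arr)))


def brown_combine_pvalues(ps: Sequence[float], values: np.ndarray) -> float:
    """Brown's dependence-adjusted Fisher combination.

    ``values`` is a k x m matrix (one row per test, columns are the shared
    observations, e.g. per-CpG methylation across pools) whose empirical
    correlations drive the adjustment: X = -2 sum(ln p) is referred to a
    scaled chi-square with matched first two moments.
    """
    ps_arr = np.clip(np.asarray(ps, dtype=float), 1e-300, 1.0)
    k = len(ps_arr)
    if k == 0:
        raise ValueError("no p-values to combine")
    if k == 1:
        return float(ps_arr[0])
    corr = np.corrcoef(np.asarray(values, dtype=float))
    corr = np.nan_to_num(corr, nan=0.0)
    # Brown's polynomial approximation of cov(-2 ln p_i, -2 ln p_j)
    cov_sum = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            r = corr[i, j]
            cov_sum += (
                r * (3.263 + r * (0.710 + 0.027 * r))
                if r >= 0
                else r * (3.263 - r * (0.710 - 0.027 * r))
            )
    mean_x = 2.0 * k
    var_x = 4.0 * k + 2.0 * cov_sum
    scale = var_x / (2.0 * mean_x)
    df = 2.0 * mean_x**2 / var_x
    x = -2.0 * np.log(ps_arr).sum()
    return float(stats.chi2.sf(x / scale, df))


def pairwise_region_test(
    proportions: pd.DataFrame,
    group_a_pools: Sequence[str],
    group_b_pools: Sequence[str],
    trna: str = "",
    comparison: str = "",
    dependence_adjusted: bool = False,
) -> PairwiseDiffResult:
    """Differential methylation of one tRNA region between two age groups.

    ``proportions`` is a CpG x pool matrix (see
    :func:`methylation_proportions`) restricted to one region. Only CpGs
    with data in every compared pool are used. The primary p pairs CpG
    sites across the two group means (paired t over CpGs); per-CpG
    two-sample t-tests across pools are additionally combined by Fisher's
    method (Brown-adjusted when requested). Delta is the mean over CpGs of
    group_b minus group_a — older minus younger when b is the older group.
    """
    cols = list(group_a_pools) + list(group_b_pools)
    missing = [c for c in cols if c not in proportions.columns]
    if missing:
        raise ValueError(f"pools missing from proportion matrix: {missing}")
    sub = proportions[cols].dropna()
    if sub.empty:
        raise ValueError("no shared CpGs passing QC in both groups")
    a = sub[list(group_a_pools)].to_numpy()
    b = sub[list(group_b_pools)].to_numpy()
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    diffs = mean_b - mean_a
    delta = float(diffs.mean())
    k = len(diffs)

    flag = ""
    # per-CpG two-sample tests across pools
    per_cpg_p: list[float] = []
    for i in range(k):
        if np.allclose(a[i].std(), 0) and np.allclose(b[i].std(), 0) and np.allclose(
            a[i].mean(), b[i].mean()
        ):
            per_cpg_p.append(1.0)
            continue
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # near-identical data
            res = stats.ttest_ind(b[i], a[i], equal_var=True)
        per_cpg_p.append(float(res.pvalue) if np.isfinite(res.pvalue) else 1.0)

    if k == 1:
        # single-CpG region: the unpaired per-CpG test is the region test
        return PairwiseDiffResult(
            trna=trna,
            comparison=comparison,
            num_cpgs=1,
            delta=delta,
            paired_t_p=per_cpg_p[0],
            per_cpg_p=per_cpg_p,
            combined_p=per_cpg_p[0],
            flag="single_cpg",
        )

    if np.allclose(diffs.std(ddof=1), 0.0):
        # all CpGs shifted identically: zero variance of paired differences.
        # Identical profiles -> no evidence (p = 1); a constant non-zero
        # shift is the p -> 0 limit of the paired t.
        flag = "zero_variance"
        paired_p = 1.0 if np.allclose(diffs, 0.0) else np.nextafter(0, 1)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            paired_p = float(stats.ttest_rel(mean_b, mean_a).pvalue)

    if dependence_adjusted:
        combined = brown_combine_pvalues(per_cpg_p, sub.to_numpy())
        method = "brown"
    else:
        combined = combine_pvalues(per_cpg_p)
        method = "fisher"
    return PairwiseDiffResult(
        trna=trna,
        comparison=comparison,
        num_cpgs=k,
        delta=delta,
        paired_t_p=paired_p,
        per_cpg_p=per_cpg_p,
        combined_p=combined,
        combined_method=method,
        flag=flag,
    )


def rank_sum_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "greater",
    conf_level: float = 0.95,
) -> RankSumResult:
    """One-sided Wilcoxon rank-sum comparison of ``values_a`` vs ``values_b``.

    ``alternative="greater"`` tests whether a tends to exceed b (scipy and R
    ``wilcox.test(a, b)`` convention; the W statistic is the Mann-Whitney U
    of the first sample, so printed W values from R are directly
    comparable). P-values are exact for small samples without ties, else a
    tie-corrected normal approximation. Also returns the Hodges-Lehmann
    shift estimate (median of pairwise differences a_i - b_j) and a
    one-sided confidence bound for the shift obtained by inverting the
    rank-sum test with a normal quantile.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in {"greater", "less"}:
        raise ValueError("alternative must be 'greater' or 'less'")
    if len(a) == len(b) and np.all(a == b[0]) and np.all(b == b[0]):
        return RankSumResult(
            statistic=float(len(a) * len(b) / 2.0),
            p_value=1.0,
            shift_estimate=0.0,
            conf_bound=0.0,
            alternative=alternative,
        )
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)

    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    hl = float(np.median(diffs))
    m, n = len(a), len(b)
    mu = m * n / 2.0
    sigma = np.sqrt(m * n * (m + n + 1) / 12.0)
    z = stats.norm.ppf(conf_level)
    if alternative == "greater":
        k = int(np.floor(mu - z * sigma))
        k = min(max(k, 0), m * n - 1)
        bound = float(diffs[k])  # lower bound; CI = (bound, +inf)
    else:
        k = int(np.ceil(mu + z * sigma))
        k = min(max(k, 0), m * n - 1)
        bound = float(diffs[k])  # upper bound; CI = (-inf, bound)
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        shift_estimate=hl,
        conf_bound=bound,
        alternative=alternative,
    )


def fit_pool_age_regression(
    proportions: Sequence[float], pool_ages: Sequence[float]
) -> dict[str, float]:
    """Simple linear regression of one CpG's pool methylation on pool age.

    Returns both orientations — ``slope_meth_per_year`` (methylation ~ age,
    interpretable as proportion/yr) and ``slope_age_per_meth`` (age ~
    methylation) — with their shared simple-regression F-test p-value.
    Requires at least 3 pools.
    """
    y = np.asarray(proportions, dtype=float)
    x = np.asarray(pool_ages, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x)
    y, x = y[mask], x[mask]
    if len(y) < 3:
        raise ValueError("need >=3 pools with QC-passing data")
    if np.allclose(y.std(), 0.0):
        return {"slope_meth_per_year": 0.0, "slope_age_per_meth": 0.0, "p": 1.0}
    fwd = stats.linregress(x, y)
    rev = stats.linregress(y, x)
    return {
        "slope_meth_per_year": float(fwd.slope),
        "slope_age_per_meth": float(rev.slope),
        "p": float(fwd.pvalue),
    }
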