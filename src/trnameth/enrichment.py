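"""Enrichment of age-significant windows in a feature set.

Two complementary tests:

* a one-sided Fisher's exact test on the 2x2 table of significant /
  non-significant windows inside vs outside the feature set;
* a CpG-density-matched permutation test: each permutation draws a random
  window set whose CpG-count histogram matches the feature set's, counts
  its significant windows, and the empirical p-value is (r + 1) / (N + 1)
  where r is the number of permutations with a count at least the observed.

Density matching is by exact CpG count below the CpG-island regime; all
windows at >=45 CpGs per 500 bp (18% density) — where CpG islands are
consistently hypomethylated and counts become sparse — are pooled into a
single stratum and sampled interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .window_methylome import Window

__all__ = [
    "EnrichmentTable",
    "PermutationResult",
    "POOLED_STRATUM",
    "fisher_enrichment",
    "build_density_pools",
    "sample_matched_set",
    "permutation_enrichment",
    "cpg_count_threshold",
]

#: Key of the pooled high-density stratum in density-pool mappings.
POOLED_STRATUM = "pooled"


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 significance-by-membership contingency table.

    a: significant windows in the feature set; b: non-significant in the
    feature set; c: significant outside; d: non-significant outside.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


@dataclass
class PermutationResult:
    """Outcome of the density-matched permutation test."""

    observed: int
    perm_counts: list[int]
    r: int
    n_permutations: int

    @property
    def empirical_p(self) -> float:
        return (self.r + 1) / (self.n_permutations + 1)


def fisher_enrichment(
    table: EnrichmentTable, alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided Fisher's exact test for feature-set enrichment.

    Returns (odds_ratio, p). The odds ratio is the sample estimate
    a*d / (b*c); a zero in b or c gives ``inf`` (or ``nan`` when the
    numerator is also zero).
    """
    res = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alternative
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.float64(table.a * table.d) / np.float64(table.b * table.c)
    return float(odds), float(res.pvalue)


def cpg_count_threshold(pool_threshold_pct: float = 18.0, window_size: int = 500) -> int:
    """CpG count corresponding to a density threshold (18% of 500 bp -> 45)."""
    return int(np.ceil(pool_threshold_pct / 100.0 * window_size / 2.0))


def build_density_pools(
    windows: Sequence[Window],
    pool_threshold_pct: float = 18.0,
) -> dict[object, np.ndarray]:
    """Stratify window indices by exact CpG count, pooling the CGI regime.

    Windows below the threshold form one stratum per exact CpG count;
    windows at or above it (>=45 CpGs for 500 bp windows) share a single
    ``POOLED_STRATUM``. Every window lands in exactly one stratum.
    """
    if not windows:
        return {}
    thresh = cpg_count_threshold(pool_threshold_pct, len(windows[0].interval))
    strata: dict[object, list[int]] = {}
    for i, w in enumerate(windows):
        key = POOLED_STRATUM if w.cpg_count >= thresh else w.cpg_count
        strata.setdefault(key, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in strata.items()}


def _feature_stratum_counts(
    feature_idx: Sequence[int],
    windows: Sequence[Window],
    thresh: int,
) -> dict[object, int]:
    counts: dict[object, int] = {}
    for i in feature_idx:
        key = POOLED_STRATUM if windows[i].cpg_count >= thresh else windows[i].cpg_count
        counts[key] = counts.get(key, 0) + 1
    return counts


def sample_matched_set(
    stratum_counts: Mapping[object, int],
    pools: Mapping[object, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one random window set matching a CpG-count histogram.

    For each stratum, samples (without replacement within this one
    permutation) as many pool windows as the feature set has there. Raises
    if any stratum has fewer candidates than needed, naming the stratum.
    """
    picks = []
    for key, need in stratum_counts.items():
        pool = pools.get(key)
        if pool is None or len(pool) < need:
            have = 0 if pool is None else len(pool)
            raise ValueError(
                f"density stratum {key!r} exhausted: need {need}, have {have}"
            )
        picks.append(rng.choice(pool, size=need, replace=False))
    if not picks:
        return np.empty(0, dtype=int)
    return np.concatenate(picks)


def permutation_enrichment(
    feature_window_idx: Sequence[int],
    all_windows: Sequence[Window],
    significant_flags: Sequence[bool],
    n_permutations: int = 1000,
    seed: int = 0,
    pool_threshold_pct: float = 18.0,
) -> PermutationResult:
    """CpG-density-matched permutation test of feature-set enrichment.

    ``significant_flags`` is aligned to ``all_windows`` (e.g. window p-value
    below a chosen threshold, optionally restricted to one direction of
    change). The feature windows themselves are excluded from the sampling
    pool so the empirical null does not contain the signal. Ties count
    against the feature set (r counts permutations with count >= observed).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    flags = np.asarray(significant_flags, dtype=bool)
    if len(flags) != len(all_windows):
        raise ValueError("flags must align to all_windows")
    feature_idx = np.asarray(sorted(set(feature_window_idx)), dtype=int)
    observed = int(flags[feature_idx].sum())

    thresh = cpg_count_threshold(pool_threshold_pct, len(all_windows[0].interval))
    pools = build_density_pools(all_windows, pool_threshold_pct)
    background = {
        k: v[~np.isin(v, feature_idx)] for k, v in pools.items()
    }
    stratum_counts = _feature_stratum_counts(feature_idx, all_windows, thresh)

    rng = np.random.default_rng(seed)
    perm_counts = []
    for _ in range(n_permutations):
        picked = sample_matched_set(stratum_counts, background, rng)
        perm_counts.append(int(flags[picked].sum()))
    r = int(sum(c >= observed for c in perm_counts))
    return PermutationResult(
        observed=observed,
        perm_counts=perm_counts,
        r=r,
        n_permutations=n_permutations,
    )
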