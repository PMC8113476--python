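"""Synthetic study generator for the tRNA methylation-ageing pipeline.

Emulates the statistical structure the downstream analysis assumes, without
simulating raw sequencing reads:

* a small synthetic genome tiled into 500 bp / 250 bp sliding windows, with
  per-window CpG counts drawn so that tRNA-overlapping windows skew CpG-denser
  than background (as tRNA loci do);
* a blood-cohort sample table (ages 16-82 years, sex, batch, four blood
  cell counts, monozygotic/dizygotic twin pairs, optional longitudinal
  revisits 5-16.1 years apart);
* a window x sample score matrix built as
  ``baseline(CpG density) + slope*age (at affected tRNA windows) +
  batch effect + cell-type effects + participant/family effects + noise``,
  floored at zero — an RPM-like scale;
* pooled targeted-bisulfite binomial read counts over an 8-pool, 4-age-point
  design (2 pools each at ~4, ~28, ~63 and ~78 years; 190 contributors).

Baseline methylation signal rises with CpG count up to the CpG-island
regime and drops for windows at >=18% CpG density (>=45 CpGs/500 bp), where
CpG islands are consistently hypomethylated; this makes CpG-density matching
in the enrichment permutation consequential.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_annotation import GenomicInterval, TRNAGene
from .window_methylome import (
    MethylationMatrix,
    Window,
    make_sliding_windows,
    map_windows_to_features,
)

__all__ = [
    "SimulationConfig",
    "PoolSpec",
    "TABLE1_POOLS",
    "SimulatedStudy",
    "simulate_study",
    "simulate_sample_table",
    "simulate_pooled_bis",
]

_ISOTYPES = [
    ("iMet", "CAT"), ("Met", "CAT"), ("Ser", "AGA"), ("Ser", "TGA"),
    ("Ile", "AAT"), ("Ile", "TAT"), ("Leu", "AAG"), ("Leu", "TAG"),
    ("Gly", "GCC"), ("Glu", "TTC"), ("Asp", "GTC"), ("Val", "AAC"),
    ("Ala", "AGC"), ("Arg", "ACG"), ("Thr", "AGT"), ("Lys", "CTT"),
]

# CpG-island pooling threshold of the enrichment permutation: 18% density
# = 45 CpGs per 500 bp window.
CGI_CPG_COUNT = 45


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_study`.

    Defaults mirror the discovery-cohort structure at desk scale: blood
    methylomes from adults aged 16-82 years with batch structure, measured
    lymphocyte/monocyte/neutrophil/eosinophil counts, a twin fraction, and
    an optional longitudinal subset revisited 5-16.1 years later.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_len: int = 2_000_000
    window_size: int = 500
    window_step: int = 250
    # tRNA annotation
    n_trna: int = 100
    # planted age effect
    frac_age_affected: float = 0.1
    slope_per_year: float = 0.02
    # nuisance structure
    noise_sd: float = 1.0
    n_batches: int = 2
    batch_effect_sd: float = 0.5
    celltype_effect: tuple[float, float, float, float] = (0.3, 0.6, 0.15, 1.0)
    celltype_age_assoc: float = 0.0
    participant_effect_sd: float = 0.3
    family_effect_sd: float = 0.3
    # cohort
    n_samples: int = 300
    age_range: tuple[float, float] = (16.0, 82.0)
    twin_fraction: float = 0.3
    longitudinal_fraction: float = 0.0
    revisit_gap_years: tuple[float, float] = (5.0, 16.1)
    # CpG count distributions (negative binomial mean/shape). Background is
    # a mixture: mostly CpG-poor windows plus a CpG-rich island/shore
    # component spanning intermediate-to-CGI densities, so density-matched
    # sampling has candidates at every stratum the tRNA windows occupy.
    background_cpg_mean: float = 4.0
    background_cpg_shape: float = 1.5
    cpgrich_fraction: float = 0.10
    cpgrich_mean: float = 30.0
    cpgrich_shape: float = 2.5
    trna_cpg_mean: float = 25.0
    trna_cpg_shape: float = 6.0
    # baseline(density): score = bmax*c/(c+khalf) below the CGI regime
    baseline_max: float = 8.0
    baseline_halfsat: float = 8.0
    cgi_baseline: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.batch_effect_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 <= self.frac_age_affected <= 1):
            raise ValueError("frac_age_affected must be in [0, 1]")
        if not (0 <= self.twin_fraction <= 1 and 0 <= self.longitudinal_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 120):
            raise ValueError("age_range must lie within [0, 120]")


@dataclass
class SimulatedStudy:
    """Everything one synthetic discovery study comprises, plus the truth."""

    genes: list[TRNAGene]
    windows: list[Window]
    matrix: MethylationMatrix
    samples: pd.DataFrame
    truth: dict


def _negbin_counts(rng, mean: float, shape: float, size: int) -> np.ndarray:
    """Gamma-Poisson (negative binomial) integer draws with given mean/shape."""
    lam = rng.gamma(shape, mean / shape, size=size)
    return rng.poisson(lam)


def simulate_sample_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Build the cohort metadata table (one row per methylome sample).

    Twin pairs (half MZ, half DZ) share a family_id; longitudinal
    participants contribute two samples separated by a gap drawn from
    ``revisit_gap_years``, with baseline ages positioned so revisits stay
    inside ``age_range``.
    """
    lo, hi = config.age_range
    n_long = int(round(config.longitudinal_fraction * config.n_samples / 2))
    n_single = config.n_samples - 2 * n_long
    n_participants = n_single + n_long

    n_twin_pairs = int(round(config.twin_fraction * n_participants / 2))
    family_ids = []
    zygosity = []
    fam = 0
    for i in range(n_twin_pairs):
        fam += 1
        zyg = "MZ" if i % 2 == 0 else "DZ"
        family_ids += [f"F{fam:04d}"] * 2
        zygosity += [zyg] * 2
    while len(family_ids) < n_participants:
        fam += 1
        family_ids.append(f"F{fam:04d}")
        zygosity.append("NA")
    family_ids = family_ids[:n_participants]
    zygosity = zygosity[:n_participants]

    gap_lo, gap_hi = config.revisit_gap_years
    rows = []
    sample_no = 0
    for p in range(n_participants):
        pid = f"P{p:04d}"
        longitudinal = p < n_long
        if longitudinal:
            gap = rng.uniform(gap_lo, gap_hi)
            base_age = rng.uniform(lo, max(lo + 1e-6, hi - gap))
            ages = [base_age, base_age + gap]
        else:
            ages = [rng.uniform(lo, hi)]
        sex = rng.choice(["F", "M"], p=[0.93, 0.07])  # female-skewed twin cohort
        for age in ages:
            sample_no += 1
            rows.append(
                {
                    "sample_id": f"S{sample_no:05d}",
                    "participant_id": pid,
                    "family_id": family_ids[p],
                    "zygosity": zygosity[p],
                    "age": float(age),
                    "sex": sex,
                    "batch": f"batch{rng.integers(config.n_batches) + 1}",
                }
            )
    samples = pd.DataFrame(rows)

    # Blood cell counts (1e9 cells/L scale); celltype_age_assoc > 0 plants a
    # myeloid skew: neutrophils rise and lymphocytes fall with age.
    n = len(samples)
    age_c = (samples["age"].to_numpy() - (lo + hi) / 2) / ((hi - lo) / 2)
    base = {
        "lymphocytes": (2.0, 0.5),
        "monocytes": (0.5, 0.15),
        "neutrophils": (4.0, 1.0),
        "eosinophils": (0.2, 0.08),
    }
    skew = {"lymphocytes": -0.5, "monocytes": 0.2, "neutrophils": 1.0, "eosinophils": 0.0}
    for cell, (mu, sd) in base.items():
        vals = mu + config.celltype_age_assoc * skew[cell] * age_c + rng.normal(0, sd, n)
        samples[cell] = np.clip(vals, 0.01, None)
    return samples


def _place_trna_genes(config: SimulationConfig, rng: np.random.Generator) -> list[TRNAGene]:
    """Scatter non-overlapping tRNA genes (60-86 bp) over the synthetic genome."""
    genes = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    fam_counter: dict[tuple[str, str], int] = {}
    attempts = 0
    while len(genes) < config.n_trna:
        attempts += 1
        if attempts > 100 * config.n_trna:
            raise ValueError("infeasible config: cannot place tRNA genes on genome")
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(60, 87))
        start = int(rng.integers(1000, config.chrom_len - 1000 - length))
        end = start + length
        # keep genes >= 1kb apart so each maps to its own windows
        if any(start < e + 1000 and s - 1000 < end for s, e in occupied.get(chrom, ())):
            continue
        occupied.setdefault(chrom, []).append((start, end))
        iso, anti = _ISOTYPES[rng.integers(len(_ISOTYPES))]
        fam_counter[(iso, anti)] = fam_counter.get((iso, anti), 0) + 1
        copy = fam_counter[(iso, anti)]
        name = f"tRNA-{iso}-{anti}-{1 + copy // 10}-{1 + copy % 10}"
        iv = GenomicInterval(chrom, start, end, name=name, strand="+")
        genes.append(TRNAGene.from_interval(iv))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one complete synthetic discovery study.

    Returns the tRNA annotation, windows with CpG counts, the score matrix,
    the sample table, and a truth record listing the affected tRNA names,
    affected window indices and the planted slope. Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_windows_per_chrom = (config.chrom_len - config.window_size) // config.window_step + 1
    if config.n_trna * 3 > n_windows_per_chrom * config.n_chroms:
        raise ValueError("infeasible config: tRNA windows exceed the genome")

    genes = _place_trna_genes(config, rng)
    chrom_sizes = {f"chr{i + 1}": config.chrom_len for i in range(config.n_chroms)}
    intervals = make_sliding_windows(chrom_sizes, config.window_size, config.window_step)

    feature_map = map_windows_to_features(
        [Window(iv) for iv in intervals], genes
    )
    trna_window_idx = np.array(feature_map.window_indices, dtype=int)

    # CpG counts: CpG-poor background with a CpG-rich island/shore
    # component; tRNA-overlapping windows skew denser still
    n_win = len(intervals)
    counts = _negbin_counts(rng, config.background_cpg_mean, config.background_cpg_shape, n_win)
    rich = rng.random(n_win) < config.cpgrich_fraction
    counts[rich] = _negbin_counts(rng, config.cpgrich_mean, config.cpgrich_shape, int(rich.sum()))
    counts[trna_window_idx] = _negbin_counts(
        rng, config.trna_cpg_mean, config.trna_cpg_shape, len(trna_window_idx)
    )
    max_count = config.window_size // 2
    counts = np.clip(counts, 0, max_count)
    windows = [Window(iv, cpg_count=int(c)) for iv, c in zip(intervals, counts)]

    samples = simulate_sample_table(config, rng)
    n_samp = len(samples)

    # affected tRNAs and their windows
    n_affected = int(round(config.frac_age_affected * len(genes)))
    affected_idx = rng.choice(len(genes), size=n_affected, replace=False)
    affected_genes = sorted(genes[i].name for i in affected_idx)
    affected_windows = sorted(
        {w for name in affected_genes for w in feature_map.windows_for(name)}
    )

    # score = baseline(density) + age effect + batch + celltype + person + noise
    c = counts.astype(float)
    baseline = np.where(
        counts >= CGI_CPG_COUNT,
        config.cgi_baseline,
        config.baseline_max * c / (c + config.baseline_halfsat),
    )
    scores = np.tile(baseline[:, None], (1, n_samp))

    ages = samples["age"].to_numpy()
    if affected_windows:
        scores[np.array(affected_windows, dtype=int), :] += config.slope_per_year * ages[None, :]

    batch_levels = sorted(samples["batch"].unique())
    batch_offsets = {
        b: (0.0 if i == 0 else rng.normal(0, config.batch_effect_sd))
        for i, b in enumerate(batch_levels)
    }
    scores += samples["batch"].map(batch_offsets).to_numpy()[None, :]

    cell_cols = ["lymphocytes", "monocytes", "neutrophils", "eosinophils"]
    cell_contrib = samples[cell_cols].to_numpy() @ np.asarray(config.celltype_effect)
    scores += cell_contrib[None, :]

    # participant / family effects induce twin correlation
    part_eff = {}
    fam_eff = {}
    for _, row in samples.drop_duplicates("participant_id").iterrows():
        fid = row["family_id"]
        if fid not in fam_eff:
            fam_eff[fid] = rng.normal(0, config.family_effect_sd)
        weight = {"MZ": 1.0, "DZ": 0.5}.get(row["zygosity"], 0.0)
        part_eff[row["participant_id"]] = (
            weight * fam_eff[fid] + rng.normal(0, config.participant_effect_sd)
        )
    scores += samples["participant_id"].map(part_eff).to_numpy()[None, :]

    if config.noise_sd > 0:
        scores += rng.normal(0, config.noise_sd, size=scores.shape)
    scores = np.clip(scores, 0.0, None)

    score_df = pd.DataFrame(
        scores,
        index=[w.name for w in windows],
        columns=samples["sample_id"].to_list(),
    )
    matrix = MethylationMatrix(windows, score_df)
    truth = {
        "seed": config.seed,
        "affected_trnas": affected_genes,
        "affected_window_indices": affected_windows,
        "slope_per_year": config.slope_per_year,
        "config": asdict(config),
    }
    return SimulatedStudy(genes, windows, matrix, samples, truth)


# ---------------------------------------------------------------------------
# pooled targeted bisulfite design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolSpec:
    """One pooled-DNA library: age-matched contributors sequenced together."""

    pool_id: str
    mean_age: float
    n_contributors: int
    sex: str


#: The 8-pool, 4-age-point pooled design (190 contributors in total):
#: two pools each at ~4, ~28, ~63 and ~78 years.
TABLE1_POOLS: tuple[PoolSpec, ...] = (
    PoolSpec("Pool1", 4.07, 20, "M"),
    PoolSpec("Pool2", 4.09, 20, "F"),
    PoolSpec("Pool3", 28.07, 25, "F"),
    PoolSpec("Pool4", 28.23, 25, "F"),
    PoolSpec("Pool5", 63.40, 25, "F"),
    PoolSpec("Pool6", 63.26, 25, "F"),
    PoolSpec("Pool7", 77.96, 25, "F"),
    PoolSpec("Pool8", 77.22, 25, "F"),
)


def simulate_pooled_bis(
    pools: Sequence[PoolSpec] = TABLE1_POOLS,
    regions: Sequence[tuple[str, str, Sequence[int]]] = (),
    affected: Sequence[str] = (),
    baseline_meth: float = 0.02,
    slope_per_year: float = 5e-4,
    coverage_median: float = 679.0,
    coverage_log_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-CpG pooled bisulfite read counts.

    ``regions`` is a sequence of (tRNA name, chrom, CpG positions). For each
    CpG and pool, total reads follow a lognormal depth law with median
    ``coverage_median`` and log-scale sd ``coverage_log_sd`` — amplicon
    sequencing depth is strongly right-skewed (mean several-fold above the
    median at the defaults) — and methylated reads are Binomial(total, p)
    with ``p = baseline_meth + slope_per_year * pool_age`` for tRNAs in
    ``affected`` and ``p = baseline_meth`` otherwise. At the default scale
    (baseline 2%, 5e-4/yr) an affected locus gains ~3.7% methylation from
    age 4 to age 78, matching the magnitude of age effects at individual
    hypermethylating tRNAs.

    Returns a tidy DataFrame: trna, chrom, pos, pool_id, pool_age,
    meth_reads, total_reads.
    """
    if not (0 <= baseline_meth <= 1):
        raise ValueError("baseline_meth must be in [0, 1]")
    max_age = max((p.mean_age for p in pools), default=0.0)
    if baseline_meth + slope_per_year * max_age > 1:
        raise ValueError("methylation probability exceeds 1 at the oldest pool")
    rng = np.random.default_rng(seed)
    affected_set = set(affected)
    rows = []
    for trna, chrom, positions in regions:
        slope = slope_per_year if trna in affected_set else 0.0
        for pos in positions:
            for pool in pools:
                p = baseline_meth + slope * pool.mean_age
                total = int(round(rng.lognormal(np.log(coverage_median), coverage_log_sd)))
                meth = int(rng.binomial(total, p)) if total > 0 else 0
                rows.append(
                    {
                        "trna": trna,
                        "chrom": chrom,
                        "pos": int(pos),
                        "pool_id": pool.pool_id,
                        "pool_age": pool.mean_age,
                        "meth_reads": meth,
                        "total_reads": total,
                    }
                )
    return pd.DataFrame(rows)
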