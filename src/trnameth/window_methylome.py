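"""Sliding-window methylome representation.

MeDIP-seq gives a regional, fragment-scale methylation readout summarised as
reads-per-million (RPM) scores in 500 bp windows with a 250 bp slide. This
module builds those windows, computes CpG density per window, maps windows
onto tRNA genes by any-overlap, and quantile-normalises window x sample
score matrices.

CpG density convention: a window's density in percent counts both bases of
each CpG dinucleotide, ``100 * 2 * cpg_count / window_length``, so that
45 CpGs in a 500 bp window is 18% density.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_annotation import GenomicInterval, TRNAGene

__all__ = [
    "Window",
    "MethylationMatrix",
    "WindowFeatureMap",
    "make_sliding_windows",
    "count_cpgs",
    "cpg_density_pct",
    "map_windows_to_features",
    "quantile_normalize",
    "read_chrom_sizes",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass(frozen=True)
class Window:
    """A fixed-width genomic bin with its CpG content."""

    interval: GenomicInterval
    cpg_count: int = 0

    @property
    def name(self) -> str:
        return self.interval.name

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def cpg_density_pct(self) -> float:
        return 100.0 * 2.0 * self.cpg_count / len(self.interval)


def window_name(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


@dataclass
class MethylationMatrix:
    """Windows x samples score matrix with aligned window metadata.

    ``scores`` is a DataFrame indexed by window name ("chrom:start-end"),
    columns are sample IDs, values are RPM-like non-negative scores.
    ``windows`` is the ordered list of :class:`Window` objects matching the
    row order.
    """

    windows: list[Window]
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.windows) != self.scores.shape[0]:
            raise ValueError(
                f"{len(self.windows)} windows but {self.scores.shape[0]} score rows"
            )
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("scores must be finite")

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_windows(self) -> int:
        return len(self.windows)


class WindowFeatureMap:
    """All (window index, feature name) pairs with >=1 bp overlap."""

    def __init__(self, pairs: Sequence[tuple[int, str]]):
        self.pairs = list(pairs)
        self._by_feature: dict[str, list[int]] = {}
        for idx, name in self.pairs:
            self._by_feature.setdefault(name, []).append(idx)

    def windows_for(self, feature_name: str) -> list[int]:
        return self._by_feature.get(feature_name, [])

    @property
    def feature_names(self) -> list[str]:
        return list(self._by_feature)

    @property
    def window_indices(self) -> list[int]:
        """Sorted unique indices of windows overlapping any feature."""
        return sorted({idx for idx, _ in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["window_index", "feature"])


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


def make_sliding_windows(
    chrom_sizes: Mapping[str, int], size: int = 500, step: int = 250
) -> list[GenomicInterval]:
    """Tile each chromosome with fixed-size windows.

    Windows start at 0 and advance by ``step``; only windows lying fully
    inside the chromosome are emitted (partial terminal windows are dropped
    so every window has the same length, keeping CpG densities comparable).
    Output order is (chrom, start) with chromosomes sorted by name.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if not (0 < step <= size):
        raise ValueError("require 0 < step <= size")
    out: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        if length is None or length <= 0:
            raise ValueError(f"unknown or invalid length for chromosome {chrom!r}")
        for start in range(0, length - size + 1, step):
            end = start + size
            out.append(
                GenomicInterval(chrom, start, end, name=window_name(chrom, start, end))
            )
    return out


def count_cpgs(sequence: str) -> int:
    """Count CpG dinucleotides ("CG" occurrences) in a window sequence.

    Counting is on the forward strand only; CpG is strand-symmetric so this
    is complete. Occurrences cannot overlap, so ``str.count`` is exact.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return sequence.upper().count("CG")


def cpg_density_pct(cpg_count: int, window_length: int) -> float:
    """Density in percent, counting both bases of each CpG (45/500bp = 18%)."""
    return 100.0 * 2.0 * cpg_count / window_length


def map_windows_to_features(
    windows: Sequence[Window | GenomicInterval],
    features: Sequence[TRNAGene],
) -> WindowFeatureMap:
    """All (window, feature) pairs sharing at least one base pair.

    A 73 bp tRNA gene under 500/250 windowing overlaps 2 or 3 windows
    depending on phase. Implemented as a per-chromosome sorted sweep over
    window start positions.
    """
    ivs = [w.interval if isinstance(w, Window) else w for w in windows]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(ivs):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
    for lst in by_chrom.values():
        lst.sort()
    pairs: list[tuple[int, str]] = []
    for gene in features:
        lst = by_chrom.get(gene.chrom)
        if not lst:
            continue
        for w_start, w_end, idx in lst:
            if w_start >= gene.end:
                break
            if w_end > gene.start:
                pairs.append((idx, gene.name))
    pairs.sort()
    return WindowFeatureMap(pairs)


def quantile_normalize(matrix: MethylationMatrix) -> MethylationMatrix:
    """Quantile-normalise sample columns to a shared reference distribution.

    The reference is the across-sample mean of order statistics; every
    column is mapped onto it rank-for-rank, preserving within-sample rank
    order. Tied values within a column receive the mean of the reference
    values they span. The operation is idempotent (exactly so on tie-free
    data; tie-averaging perturbs the reference slightly on re-application).
    A single-row matrix is returned unchanged (degenerate).
    """
    X = matrix.scores.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2:
        return MethylationMatrix(list(matrix.windows), matrix.scores.copy())
    if m < 2:
        raise ValueError("quantile normalisation requires >=2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = reference
        # ties: average the reference values assigned to equal inputs
        s = pd.Series(mapped).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    normed = pd.DataFrame(out, index=matrix.scores.index, columns=matrix.scores.columns)
    return MethylationMatrix(list(matrix.windows), normed)


def write_matrix_tsv(matrix: MethylationMatrix, path: str | Path) -> None:
    df = matrix.scores.copy()
    df.insert(0, "cpg_count", [w.cpg_count for w in matrix.windows])
    df.to_csv(path, sep="\t", index_label="window")


def read_matrix_tsv(path: str | Path) -> MethylationMatrix:
    """Read a window score matrix written by :func:`write_matrix_tsv`.

    Row keys are "chrom:start-end"; a ``cpg_count`` column, if present,
    populates window CpG counts (else 0).
    """
    df = pd.read_csv(path, sep="\t", index_col="window")
    df.index.name = None
    if "cpg_count" in df.columns:
        counts = df.pop("cpg_count").astype(int).to_list()
    else:
        counts = [0] * df.shape[0]
    windows = []
    for key, cnt in zip(df.index, counts):
        chrom, span = key.rsplit(":", 1)
        start, end = span.split("-")
        iv = GenomicInterval(chrom, int(start), int(end), name=key)
        windows.append(Window(iv, cpg_count=cnt))
    return MethylationMatrix(windows, df)
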