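"""tRNA gene annotation: BED I/O, blacklist/autosome filtering, and clustering.

tRNA genes are short (60-86 bp) features annotated in gtRNAdb-style BED files
with names such as ``tRNA-iMet-CAT-1-4`` (isotype, anticodon, family, copy).
All coordinates follow the BED convention: 0-based, half-open intervals.
Overlap means at least one shared base pair under half-open arithmetic, and
strand is ignored throughout (the analysis treats tRNA loci positionally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "TRNAGene",
    "TRNACluster",
    "AUTOSOMES",
    "read_feature_bed",
    "read_interval_bed",
    "write_feature_bed",
    "write_cluster_bed",
    "filter_features",
    "cluster_trnas",
    "intervals_overlap",
]

#: hg19-style autosome names, the default universe for "autosomal" filtering.
AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True if ``a`` and ``b`` share at least one base pair (half-open)."""
    return a.overlaps(b)


@dataclass(frozen=True)
class TRNAGene:
    """A tRNA gene locus with its name parsed into isotype/anticodon/copy.

    Names of the form ``tRNA-<Isotype>-<Anticodon>-<family>-<copy>`` (e.g.
    ``tRNA-iMet-CAT-1-4``) are decomposed; other names leave the parsed
    fields empty, since gtRNAdb also annotates pseudogenes and
    nuclear-encoded mitochondrial tRNAs with different naming schemes.
    """

    interval: GenomicInterval
    isotype: str = ""
    anticodon: str = ""
    copy_id: str = ""

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

    @classmethod
    def from_interval(cls, interval: GenomicInterval) -> "TRNAGene":
        isotype = anticodon = copy_id = ""
        parts = interval.name.split("-")
        # tRNA-iMet-CAT-1-4 -> ["tRNA", "iMet", "CAT", "1", "4"]
        if len(parts) >= 5 and parts[0].lower().endswith("trna"):
            isotype, anticodon = parts[1], parts[2]
            copy_id = f"{isotype}-{anticodon}-{parts[3]}-{parts[4]}"
        return cls(interval, isotype=isotype, anticodon=anticodon, copy_id=copy_id)


@dataclass
class TRNACluster:
    """A group of tRNA genes merged by proximity on one chromosome."""

    members: list[TRNAGene] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def span_start(self) -> int:
        return min(g.start for g in self.members)

    @property
    def span_end(self) -> int:
        return max(g.end for g in self.members)

    @property
    def span_mb(self) -> float:
        return (self.span_end - self.span_start) / 1e6

    @property
    def n_genes(self) -> int:
        return len(self.members)

    @property
    def density_per_mb(self) -> float:
        return self.n_genes / self.span_mb


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    name = fields[3] if len(fields) > 3 else "."
    strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
    try:
        return GenomicInterval(chrom, start, end, name=name, strand=strand)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def _iter_bed_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_interval_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file (e.g. a genome blacklist) into plain intervals."""
    return [_parse_bed_line(line, lineno) for lineno, line in _iter_bed_lines(path)]


def read_feature_bed(path: str | Path) -> list[TRNAGene]:
    """Read a gtRNAdb-style BED4+ file into :class:`TRNAGene` records.

    Coordinates are preserved exactly; strand defaults to ``"."`` when the
    column is absent. Malformed lines raise :class:`BedParseError` naming
    the line number.
    """
    return [
        TRNAGene.from_interval(_parse_bed_line(line, lineno))
        for lineno, line in _iter_bed_lines(path)
    ]


def write_feature_bed(genes: Sequence[TRNAGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.interval.strand}\n"
            )


def write_cluster_bed(clusters: Sequence[TRNACluster], path: str | Path) -> None:
    """Write clusters as merged intervals, member names comma-joined."""
    with open(path, "w") as fh:
        for c in clusters:
            names = ",".join(g.name for g in c.members)
            fh.write(f"{c.chrom}\t{c.span_start}\t{c.span_end}\t{names}\n")


def filter_features(
    genes: Sequence[TRNAGene],
    blacklist: Sequence[GenomicInterval],
    autosomes: Iterable[str] = AUTOSOMES,
) -> list[TRNAGene]:
    """Keep autosomal genes that overlap no blacklist interval.

    Any overlap (>=1 shared bp, half-open arithmetic) with a blacklist
    interval excludes a gene. Input order is preserved.
    """
    autosome_set = set(autosomes)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in blacklist:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for g in genes:
        if g.chrom not in autosome_set:
            continue
        if any(g.interval.overlaps(iv) for iv in by_chrom.get(g.chrom, ())):
            continue
        kept.append(g)
    return kept


def cluster_trnas(
    genes: Sequence[TRNAGene],
    max_gap: int = 5_000_000,
    min_genes: int = 5,
    min_density: float = 5.0,
) -> list[TRNACluster]:
    """Group tRNA genes into major clusters by single-linkage merging.

    Genes are sorted by (chrom, start) and consecutive genes join one group
    whenever the gap to the growing group's right edge is at most ``max_gap``
    (bedtools ``merge -d`` semantics). Groups must contain at least
    ``min_genes`` members at a density of at least ``min_density`` genes per
    Mb of merged span (min start to max end) to be reported as clusters.
    """
    if max_gap <= 0 or min_genes <= 0 or min_density <= 0:
        raise ValueError("max_gap, min_genes and min_density must be positive")
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.name))
    clusters: list[TRNACluster] = []
    group: list[TRNAGene] = []
    group_end = None
    for g in ordered:
        if group and g.chrom == group[0].chrom and g.start - group_end <= max_gap:
            group.append(g)
            group_end = max(group_end, g.end)
        else:
            if group:
                clusters.append(TRNACluster(group))
            group = [g]
            group_end = g.end
    if group:
        clusters.append(TRNACluster(group))
    return [
        c
        for c in clusters
        if c.n_genes >= min_genes and c.density_per_mb >= min_density
    ]
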