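#!/usr/bin/env python
"""Cluster tRNA genes and place the age-affected loci among the clusters.

Merges tRNAs within 5 Mb of one another and keeps groups with at least 5
genes at a density of at least 5 genes/Mb, then reports how the planted
age-affected tRNAs distribute over the clusters.
"""

import argparse
import json
from pathlib import Path

from trnameth.genome_annotation import cluster_trnas, read_feature_bed, write_cluster_bed

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "clusters")
    parser.add_argument("--max-gap", type=int, default=5_000_000)
    parser.add_argument("--min-genes", type=int, default=5)
    parser.add_argument("--min-density", type=float, default=5.0)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genes = read_feature_bed(args.sim / "trna_genes.bed")
    truth = json.loads((args.sim / "truth.json").read_text())
    affected = set(truth["affected_trnas"])

    clusters = cluster_trnas(
        genes, max_gap=args.max_gap, min_genes=args.min_genes, min_density=args.min_density
    )
    write_cluster_bed(clusters, args.out / "trna_clusters.bed")

    total = sum(c.n_genes for c in clusters)
    print(f"{len(clusters)} clusters containing {total}/{len(genes)} tRNA genes "
          f"(gap <= {args.max_gap/1e6:g} Mb, >= {args.min_genes} genes, "
          f">= {args.min_density:g}/Mb)")
    for c in clusters:
        hit = sum(1 for g in c.members if g.name in affected)
        print(f"  {c.chrom}:{c.span_start}-{c.span_end}  {c.n_genes} genes, "
              f"{c.density_per_mb:.1f}/Mb, {hit} age-affected")


if __name__ == "__main__":
    main()
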