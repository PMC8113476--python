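#!/usr/bin/env python
"""Test tRNA windows for enrichment of age-related hypermethylation.

Builds the 2x2 significant-by-membership table for the one-sided Fisher's
exact test, then runs the CpG-density-matched permutation test (1000
permutations) and reports the empirical p-value (r + 1) / (N + 1).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from trnameth.enrichment import EnrichmentTable, fisher_enrichment, permutation_enrichment
from trnameth.genome_annotation import read_feature_bed
from trnameth.window_methylome import map_windows_to_features, read_matrix_tsv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--age-models", type=Path, default=ROOT / "results" / "age_models")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "enrichment")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-perm", type=int, default=1000)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = read_matrix_tsv(args.sim / "window_matrix.tsv")
    genes = read_feature_bed(args.sim / "trna_genes.bed")
    res = pd.read_csv(args.age_models / "window_results_model4.tsv", sep="\t")
    thresholds = json.loads((args.age_models / "thresholds.json").read_text())

    flags = (res["p"] < thresholds["study_wide"]).to_numpy() & (res["slope"] > 0).to_numpy()
    fmap = map_windows_to_features(matrix.windows, genes)
    feat_idx = fmap.window_indices
    in_feat = np.zeros(len(flags), dtype=bool)
    in_feat[feat_idx] = True

    table = EnrichmentTable(
        a=int(flags[in_feat].sum()),
        b=int((~flags[in_feat]).sum()),
        c=int(flags[~in_feat].sum()),
        d=int((~flags[~in_feat]).sum()),
    )
    odds, fisher_p = fisher_enrichment(table)
    print(f"Fisher 2x2 (a,b,c,d)=({table.a},{table.b},{table.c},{table.d}): "
          f"odds ratio {odds:.1f}, one-sided p = {fisher_p:.3g}")

    perm = permutation_enrichment(
        feat_idx, matrix.windows, flags, n_permutations=args.n_perm, seed=args.seed
    )
    print(f"permutation: observed {perm.observed} significant tRNA windows; "
          f"max over {perm.n_permutations} density-matched sets "
          f"{max(perm.perm_counts)}; r = {perm.r}; "
          f"empirical p = {perm.empirical_p:.6g}")

    report = {
        "fisher_table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "fisher_odds_ratio": odds,
        "fisher_p": fisher_p,
        "observed": perm.observed,
        "r": perm.r,
        "n_permutations": perm.n_permutations,
        "empirical_p": perm.empirical_p,
        "perm_count_max": max(perm.perm_counts),
    }
    (args.out / "enrichment.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
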