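#!/usr/bin/env python
"""Collapse SNP-pair results to gene-pair genetic interactions: each gene
pair inherits the most significant contributing SNP pair's p-value and odds
ratio. The full body+promoter assignment drives the global GI table; a
body-only assignment defines the intragenic subset used later for hubs.

Reads results/scan/pairs.tsv, writes results/collapse/gis.tsv and
gis_intragenic.tsv.
"""

from pathlib import Path

from epinet.collapse import GenePairGI, collapse_to_gene_pairs, map_snps_to_genes
from epinet.epistasis import SnpPairResult
from epinet.io import read_annotation_bed, read_plink, read_results_tsv, write_results_tsv
from epinet.network import classify_directions

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = read_plink(ROOT / "qc" / "cohort_qc")
    models = read_annotation_bed(ROOT / "cohort" / "cohort.annotation.bed")
    pair_results = read_results_tsv(ROOT / "scan" / "pairs.tsv", SnpPairResult)

    full = map_snps_to_genes(dataset, models)
    gis = classify_directions(collapse_to_gene_pairs(pair_results, full))
    write_results_tsv(gis, ROOT / "collapse" / "gis.tsv", record_type=GenePairGI)

    body = map_snps_to_genes(dataset, models, sources=("body",))
    intragenic = classify_directions(collapse_to_gene_pairs(pair_results, body))
    write_results_tsv(intragenic, ROOT / "collapse" / "gis_intragenic.tsv",
                      record_type=GenePairGI)

    print(f"{len(gis)} gene-pair GIs ({len(intragenic)} intragenic)")
    for gi in sorted(gis, key=lambda g: g.p)[:5]:
        print(f"  {gi.gene_a}-{gi.gene_b}: p={gi.p:.2e} OR={gi.or_value:.3f} "
              f"({gi.direction}) via {gi.best_snp_a} x {gi.best_snp_b}")


if __name__ == "__main__":
    main()
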