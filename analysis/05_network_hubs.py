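#!/usr/bin/env python
"""Significance calls and hub-gene degrees over the gene-pair GI table.

Thresholds use the genome-wide universe the method targets at full scale
(m = 200,000,000 assumed gene-pair tests): Bonferroni 0.05/m = 2.5e-10 and
the Benjamini-Hochberg step-up cutoff. Hub degrees count two-fold GIs
(OR > 2 or OR < 0.5) among intragenic interactions at the nominal cutoff,
split by risk direction.

Reads results/collapse/, writes results/network/.
"""

from pathlib import Path

from epinet.collapse import GenePairGI
from epinet.io import read_results_tsv, write_results_tsv
from epinet.network import (
    HubSummary,
    ThresholdSet,
    call_significant,
    hub_degrees,
    twofold_filter,
)
from epinet.pipeline import _AnnotatedRow

ROOT = Path(__file__).resolve().parent.parent / "results"
NOMINAL_P = 1e-5  # the workflow's nominal GI cutoff


def main() -> None:
    gis = read_results_tsv(ROOT / "collapse" / "gis.tsv", GenePairGI)
    intragenic = read_results_tsv(ROOT / "collapse" / "gis_intragenic.tsv", GenePairGI)

    thresholds = ThresholdSet.build([g.p for g in gis], alpha=0.05,
                                    m=200_000_000, nominal_p=NOMINAL_P)
    annotated = call_significant(gis, thresholds)
    rows = [
        _AnnotatedRow(a.gi.gene_a, a.gi.gene_b, a.gi.best_snp_a, a.gi.best_snp_b,
                      a.gi.p, a.gi.or_value, a.gi.direction,
                      int(a.nominal), int(a.bonferroni), int(a.fdr))
        for a in annotated
    ]
    write_results_tsv(rows, ROOT / "network" / "gis_annotated.tsv",
                      record_type=_AnnotatedRow)

    hub_input = twofold_filter([g for g in intragenic if g.p <= NOMINAL_P])
    hubs = hub_degrees(hub_input)
    write_results_tsv(hubs, ROOT / "network" / "hub_genes.tsv", record_type=HubSummary)

    n_inc = sum(g.direction == "increased" for g in gis)
    print(f"{len(gis)} GIs: {n_inc} increased risk, {len(gis) - n_inc} decreased/none")
    print(f"thresholds: bonferroni={thresholds.bonferroni_p:.3e} "
          f"bh={thresholds.bh_cutoff:.3e} nominal={NOMINAL_P:g}")
    print(f"{sum(a.bonferroni for a in annotated)} GIs pass Bonferroni, "
          f"{sum(a.fdr for a in annotated)} pass FDR, "
          f"{sum(a.nominal for a in annotated)} pass nominal")
    print(f"hub input: {len(hub_input)} two-fold intragenic GIs")
    for h in hubs[:5]:
        print(f"  {h.gene_id}: +{h.degree_increased} / -{h.degree_decreased} "
              f"(total {h.total})")


if __name__ == "__main__":
    main()
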