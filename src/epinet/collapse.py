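"""SNP-to-gene assignment and gene-level collapsing of SNP-pair results.

A SNP represents a gene when it falls inside the gene body or the gene's
promoter; a SNP may represent several genes (overlapping bodies/promoters).
Only *intergenic* SNP pairs — pairs whose gene sets are disjoint — are tested,
so every interaction links two different genes. Per gene pair, the most
significant contributing SNP pair (minimum Wald p) supplies the gene-level
p-value and odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .epistasis import STATUS_OK, SnpPairResult
from .io import GeneModel, GenotypeDataset

DIRECTION_INCREASED = "increased"
DIRECTION_DECREASED = "decreased_or_none"


@dataclass
class GenePairGI:
    """One gene-pair genetic interaction (gene_a < gene_b lexicographically)."""

    gene_a: str
    gene_b: str
    best_snp_a: str
    best_snp_b: str
    p: float
    or_value: float
    direction: str = ""

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort strictly before gene_b")


class AnnotationMismatchError(ValueError):
    """Annotation and genotype data appear to use different chromosome names."""


def map_snps_to_genes(
    dataset: GenotypeDataset,
    gene_models: Sequence[GeneModel],
    sources: tuple[str, ...] = ("body", "promoter"),
) -> dict[str, frozenset[str]]:
    """Assign every variant to the genes whose intervals contain it.

    A variant at 1-based position p maps to gene g iff p - 1 lies in one of
    g's half-open intervals with a tag in ``sources``. Multi-assignment is
    allowed; unassigned variants keep an empty set. Raises
    :class:`AnnotationMismatchError` when annotation exists but shares no
    chromosome name with the variants (a naming-scheme error would otherwise
    silently discard everything).
    """
    variant_chroms = {v.chrom for v in dataset.variants}
    model_chroms = {g.chrom for g in gene_models}
    if dataset.n_variants and gene_models and not (variant_chroms & model_chroms):
        raise AnnotationMismatchError(
            f"no chromosome overlap between variants {sorted(variant_chroms)} "
            f"and annotation {sorted(model_chroms)}"
        )
    assignment: dict[str, frozenset[str]] = {}
    for v in dataset.variants:
        genes = {
            g.gene_id
            for g in gene_models
            if g.chrom == v.chrom and g.contains(v.pos, sources=sources)
        }
        assignment[v.variant_id] = frozenset(genes)
    return assignment


def eligible_intergenic_pairs(
    assignment: dict[str, frozenset[str]]
) -> list[tuple[str, str]]:
    """Unordered SNP pairs where both SNPs are gene-assigned with disjoint
    gene sets; each pair listed once, in sorted id order."""
    assigned = sorted(vid for vid, genes in assignment.items() if genes)
    pairs = []
    for i, u in enumerate(assigned):
        gu = assignment[u]
        for v in assigned[i + 1:]:
            if gu.isdisjoint(assignment[v]):
                pairs.append((u, v))
    return pairs


def collapse_to_gene_pairs(
    pair_results: Iterable[SnpPairResult],
    assignment: dict[str, frozenset[str]],
) -> list[GenePairGI]:
    """Collapse SNP-pair results to gene-pair GIs by minimum Wald p.

    Each ``ok`` SNP pair contributes to every gene pair in the cross product
    of its two gene sets (same-gene pairs dropped); per gene pair the SNP
    pair with minimum Wald p wins, ties broken by lexicographically smallest
    (snp_a, snp_b). The result is invariant to the input ordering of
    ``pair_results`` and sorted by (gene_a, gene_b).
    """
    best: dict[tuple[str, str], tuple[float, str, str, float]] = {}
    for r in pair_results:
        if r.status != STATUS_OK or r.p_wald is None:
            continue
        genes_a = assignment.get(r.snp_a, frozenset())
        genes_b = assignment.get(r.snp_b, frozenset())
        for ga in genes_a:
            for gb in genes_b:
                if ga == gb:
                    continue
                key = (ga, gb) if ga < gb else (gb, ga)
                cand = (r.p_wald, r.snp_a, r.snp_b, r.or_value)
                prev = best.get(key)
                if prev is None or cand[:3] < prev[:3]:
                    best[key] = cand
    out = [
        GenePairGI(
            gene_a=ga, gene_b=gb, best_snp_a=snp_a, best_snp_b=snp_b,
            p=p, or_value=or_value,
        )
        for (ga, gb), (p, snp_a, snp_b, or_value) in best.items()
    ]
    out.sort(key=lambda gi: (gi.gene_a, gi.gene_b))
    return out
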