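"""Multiple-testing control and hub-gene analysis over the gene-pair universe.

The gene-pair test universe is taken as a flat assumed count m (by default
200,000,000, i.e. roughly C(20000, 2) for the protein-coding genome), not the
number of pairs actually measured: untested pairs count as non-discoveries.
Bonferroni control gives alpha / m; Benjamini-Hochberg step-up control finds
the largest rank k with p(k) <= k * alpha / m.

Direction: a genetic interaction with OR > 1 increases risk; OR <= 1 is
"decreased or no risk" (the no-effect point OR = 1 belongs to the latter
bucket by that bucket's definition). Hub analysis keeps only two-fold effects
(OR > 2 or OR < 0.5, strict) and tallies per-gene degrees by direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .collapse import DIRECTION_DECREASED, DIRECTION_INCREASED, GenePairGI

DEFAULT_M = 200_000_000
DEFAULT_NOMINAL_P = 1e-5


@dataclass(frozen=True)
class ThresholdSet:
    alpha: float = 0.05
    m: int = DEFAULT_M
    nominal_p: float = DEFAULT_NOMINAL_P
    bonferroni_p: float = 0.0
    bh_cutoff: float = 0.0

    @classmethod
    def build(
        cls,
        pvalues: Sequence[float],
        alpha: float = 0.05,
        m: int = DEFAULT_M,
        nominal_p: float = DEFAULT_NOMINAL_P,
    ) -> "ThresholdSet":
        """Derive Bonferroni and BH cutoffs for the observed p-values."""
        cutoff, _k = bh_cutoff(sorted(pvalues), m=m, alpha=alpha)
        return cls(
            alpha=alpha, m=m, nominal_p=nominal_p,
            bonferroni_p=bonferroni_threshold(alpha, m), bh_cutoff=cutoff,
        )


@dataclass
class HubSummary:
    gene_id: str
    degree_increased: int
    degree_decreased: int
    total: int = -1

    def __post_init__(self) -> None:
        expected = self.degree_increased + self.degree_decreased
        if self.total == -1:
            self.total = expected
        elif self.total != expected:
            raise ValueError("total must equal degree_increased + degree_decreased")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise cutoff alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bh_cutoff(
    sorted_pvalues: Sequence[float], m: int, alpha: float = 0.05
) -> tuple[float, int]:
    """Benjamini-Hochberg step-up cutoff against an assumed test count m.

    ``sorted_pvalues`` must be ascending; p-values beyond the supplied list
    (up to m) are treated as non-discoveries. Returns ``(cutoff,
    n_discoveries)`` where cutoff = k * alpha / m for the largest k with
    p(k) <= k * alpha / m, or (0.0, 0) when no rank qualifies.
    """
    p = np.asarray(sorted_pvalues, dtype=float)
    if p.size and np.any(np.diff(p) < 0):
        raise ValueError("p-values must be sorted ascending")
    if m < p.size:
        raise ValueError(f"m = {m} is smaller than the number of p-values ({p.size})")
    if p.size == 0:
        return 0.0, 0
    ranks = np.arange(1, p.size + 1)
    ok = p <= ranks * alpha / m
    if not ok.any():
        return 0.0, 0
    k = int(ranks[ok][-1])
    return k * alpha / m, k


def estimate_test_count(n_genes: int) -> int:
    """Number of unordered gene pairs, C(n_genes, 2)."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    return n_genes * (n_genes - 1) // 2


def classify_direction(or_value: float) -> str:
    """OR > 1 -> increased risk; OR <= 1 -> decreased or no risk."""
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    return DIRECTION_INCREASED if or_value > 1.0 else DIRECTION_DECREASED


def classify_directions(gis: Iterable[GenePairGI]) -> list[GenePairGI]:
    for gi in gis:
        gi.direction = classify_direction(gi.or_value)
    return list(gis)


def twofold_filter(gis: Iterable[GenePairGI]) -> list[GenePairGI]:
    """Keep GIs with OR > 2 or OR < 0.5 (strict inequalities)."""
    return [gi for gi in gis if gi.or_value > 2.0 or gi.or_value < 0.5]


def hub_degrees(gis_twofold: Iterable[GenePairGI]) -> list[HubSummary]:
    """Per-gene GI degree split by direction, over both endpoint positions.

    Sorted by total degree descending, ties by gene id ascending.
    """
    inc: dict[str, int] = {}
    dec: dict[str, int] = {}
    for gi in gis_twofold:
        direction = gi.direction or classify_direction(gi.or_value)
        bucket = inc if direction == DIRECTION_INCREASED else dec
        for gene in (gi.gene_a, gi.gene_b):
            bucket[gene] = bucket.get(gene, 0) + 1
    genes = sorted(set(inc) | set(dec))
    out = [HubSummary(g, inc.get(g, 0), dec.get(g, 0)) for g in genes]
    out.sort(key=lambda h: (-h.total, h.gene_id))
    return out


@dataclass
class AnnotatedGI:
    """A gene-pair GI with significance flags under a :class:`ThresholdSet`."""

    gi: GenePairGI
    nominal: bool
    bonferroni: bool
    fdr: bool


def call_significant(
    gis: Iterable[GenePairGI], thresholds: ThresholdSet
) -> list[AnnotatedGI]:
    """Flag each GI as nominal / Bonferroni / FDR significant."""
    out = []
    for gi in gis:
        out.append(
            AnnotatedGI(
                gi=gi,
                nominal=gi.p <= thresholds.nominal_p,
                bonferroni=gi.p <= thresholds.bonferroni_p,
                fdr=gi.p <= thresholds.bh_cutoff,
            )
        )
    return out
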