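"""Variant- and sample-level quality control for case-control genotype data.

Implements the standard GWAS cleaning steps: per-variant call-rate and minor
allele frequency filters, an exact Hardy-Weinberg equilibrium test with
case/control-specific significance tiers, per-sample call-rate filtering, and
relatedness exclusion based on a PLINK-style method-of-moments PI-HAT
estimate computed on an LD-pruned variant panel.

Two named threshold presets are provided: ``"array"`` mirrors typical
pre-imputation filtering of directly genotyped arrays (variant missingness
0.02, MAF 0.01, a single HWE tier at 1e-3, sample missingness 0.1, PI-HAT
0.1875) and ``"imputed"`` mirrors post-imputation hard-call filtering
(variant missingness 0.05 and tiered HWE: 1e-5 in both strata, 1e-6 in
controls alone, 1e-10 in cases alone).

Filters run in a fixed, documented order — variant call rate, MAF, HWE,
sample call rate, relatedness — and every step's removals are reconciled in a
:class:`QCReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, PHENO_CASE, PHENO_CONTROL, GenotypeDataset


@dataclass(frozen=True)
class QCThresholds:
    variant_missingness_max: float = 0.05  # "geno"
    sample_missingness_max: float = 0.1  # "mind"
    maf_min: float = 0.01
    hwe_p_min_all: float = 1e-5  # fails only if below this in BOTH strata
    hwe_p_min_controls: float = 1e-6
    hwe_p_min_cases: float = 1e-10
    pihat_max: float = 0.1875

    def __post_init__(self) -> None:
        for name in (
            "variant_missingness_max", "sample_missingness_max", "maf_min",
            "hwe_p_min_all", "hwe_p_min_controls", "hwe_p_min_cases",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


PRESETS: dict[str, QCThresholds] = {
    "array": QCThresholds(
        variant_missingness_max=0.02,
        sample_missingness_max=0.1,
        maf_min=0.01,
        hwe_p_min_all=1e-3,
        hwe_p_min_controls=1e-3,
        hwe_p_min_cases=1e-3,
        pihat_max=0.1875,
    ),
    "imputed": QCThresholds(
        variant_missingness_max=0.05,
        sample_missingness_max=0.1,
        maf_min=0.01,
        hwe_p_min_all=1e-5,
        hwe_p_min_controls=1e-6,
        hwe_p_min_cases=1e-10,
        pihat_max=0.1875,
    ),
}


@dataclass
class QCReport:
    """Per-step removals; input - removed = output at every step."""

    input_samples: int = 0
    input_variants: int = 0
    steps: list[dict] = field(default_factory=list)
    output_samples: int = 0
    output_variants: int = 0

    def add_step(self, name: str, removed_variants: list[str], removed_samples: list[str]) -> None:
        self.steps.append(
            {
                "step": name,
                "removed_variant_ids": list(removed_variants),
                "removed_sample_ids": list(removed_samples),
            }
        )

    @property
    def removed_variant_ids(self) -> set[str]:
        return {v for s in self.steps for v in s["removed_variant_ids"]}

    @property
    def removed_sample_ids(self) -> set[str]:
        return {v for s in self.steps for v in s["removed_sample_ids"]}


# ---------------------------------------------------------------------------
# Per-variant summaries


@dataclass
class VariantSummary:
    variant_id: str
    call_rate: float
    maf: float | None  # None when every call is missing
    counts_all: tuple[int, int, int]  # genotype counts (hom-major, het, hom-minor)
    counts_cases: tuple[int, int, int]
    counts_controls: tuple[int, int, int]


def _genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """Counts of dosage 0/1/2 per variant, shape (n_variants, 3)."""
    return np.stack([(dosages == d).sum(axis=0) for d in (0, 1, 2)], axis=1)


def variant_summaries(dataset: GenotypeDataset) -> list[VariantSummary]:
    pheno = dataset.phenotypes
    d = dataset.dosages
    counts_all = _genotype_counts(d)
    counts_cases = _genotype_counts(d[pheno == PHENO_CASE])
    counts_controls = _genotype_counts(d[pheno == PHENO_CONTROL])
    n_samples = dataset.n_samples
    out = []
    for j, v in enumerate(dataset.variants):
        n_called = int(counts_all[j].sum())
        call_rate = n_called / n_samples if n_samples else 0.0
        if n_called == 0:
            maf = None
        else:
            freq = (counts_all[j, 1] + 2 * counts_all[j, 2]) / (2 * n_called)
            maf = float(min(freq, 1 - freq))
        out.append(
            VariantSummary(
                variant_id=v.variant_id,
                call_rate=call_rate,
                maf=maf,
                counts_all=tuple(int(x) for x in counts_all[j]),
                counts_cases=tuple(int(x) for x in counts_cases[j]),
                counts_controls=tuple(int(x) for x in counts_controls[j]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test


def hwe_het_distribution(n_minor: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    Under random mating, conditional on ``n_total`` diploid individuals and
    ``n_minor`` copies of the minor allele, the heterozygote count ``h`` takes
    values of fixed parity between 0/1 and ``min(n_minor, 2*n_total-n_minor)``.
    Probabilities are computed in log space via the ratio recurrence

        P(h+2) / P(h) = 4 * n_hom_minor(h) * n_hom_major(h) / ((h+1) * (h+2)).

    Returns ``(het_values, probabilities)``.
    """
    n_major = 2 * n_total - n_minor
    if not (0 <= n_minor <= n_major):
        raise ValueError("n_minor must be the rarer allele count")
    h0 = n_minor % 2
    h_max = min(n_minor, n_major)
    hets = np.arange(h0, h_max + 1, 2)
    if len(hets) == 1:
        return hets, np.ones(1)
    h = hets[:-1].astype(float)
    hom_minor = (n_minor - h) / 2.0
    hom_major = (n_major - h) / 2.0
    log_ratio = np.log(4.0) + np.log(hom_minor) + np.log(hom_major) - np.log(h + 1) - np.log(h + 2)
    log_p = np.concatenate([[0.0], np.cumsum(log_ratio)])
    log_p -= log_p.max()
    p = np.exp(log_p)
    return hets, p / p.sum()


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts (at fixed allele
    counts) no more probable than the observed one, under the exact sampling
    distribution conditional on the allele counts. Symmetric in the
    homozygote labels; returns 1.0 for monomorphic variants.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n_total = n_hom1 + n_het + n_hom2
    if n_total < 1:
        raise ValueError("need at least one genotyped individual")
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    hets, probs = hwe_het_distribution(n_minor, n_total)
    p_obs = probs[hets == n_het]
    if p_obs.size != 1:  # impossible het count for these allele counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = float(probs[probs <= p_obs[0] * (1 + 1e-12)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Relatedness (PI-HAT)


def _ibs_expectations(freqs: np.ndarray) -> np.ndarray:
    """Per-variant P(IBS=s | IBD=k) terms needed by the MoM estimator.

    Returns array of shape (n_variants, 4): [P(IBS0|IBD0), P(IBS1|IBD0),
    P(IBS2|IBD0), P(IBS1|IBD1)]; P(IBS2|IBD1) = 1 - P(IBS1|IBD1),
    P(IBS2|IBD2) = 1.
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    return np.stack(
        [
            2 * p**2 * q**2,
            4 * p**3 * q + 4 * p * q**3,
            p**4 + q**4 + 4 * p**2 * q**2,
            2 * p * q,  # 2 p^2 q + 2 p q^2
        ],
        axis=1,
    )


def pihat_matrix(
    dosages: np.ndarray, allele_freqs: np.ndarray, min_overlap: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments PI-HAT for every sample pair.

    ``dosages``: (n_samples, n_variants) minor-allele counts with -1 missing;
    ``allele_freqs``: per-variant minor allele frequency from the full sample.
    Returns ``(pihat, reliable)`` where ``pihat[i, j]`` is P(IBD=1)/2 +
    P(IBD=2) clamped to [0, 1] and ``reliable[i, j]`` is False when fewer
    than ``min_overlap`` variants had both calls present.

    Monomorphic variants (freq 0 or 1) carry no IBS information and are
    dropped before estimation.
    """
    freqs = np.asarray(allele_freqs, dtype=float)
    poly = (freqs > 0) & (freqs < 1)
    d = dosages[:, poly]
    freqs = freqs[poly]

    valid = (d != MISSING).astype(np.float64)
    onehot = [((d == g) & (d != MISSING)).astype(np.float64) for g in (0, 1, 2)]

    n_valid = valid @ valid.T
    ibs2 = sum(h @ h.T for h in onehot)
    ibs0 = onehot[0] @ onehot[2].T + onehot[2] @ onehot[0].T
    ibs1 = n_valid - ibs2 - ibs0

    exp_terms = _ibs_expectations(freqs)  # (m, 4)
    # per-pair expected sums restricted to jointly-called variants
    e = [valid @ (exp_terms[:, k][:, None] * valid.T) for k in range(4)]
    e_ibs0_ibd0, e_ibs1_ibd0, e_ibs2_ibd0, e_ibs1_ibd1 = e
    e_ibs2_ibd1 = n_valid - e_ibs1_ibd1

    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(e_ibs0_ibd0 > 0, ibs0 / e_ibs0_ibd0, 0.0)
        p1 = np.where(e_ibs1_ibd1 > 0, (ibs1 - p0 * e_ibs1_ibd0) / e_ibs1_ibd1, 0.0)
        p0c = np.clip(p0, 0.0, None)
        p1c = np.clip(p1, 0.0, None)
        p2 = np.where(
            n_valid > 0, (ibs2 - p0c * e_ibs2_ibd0 - p1c * e_ibs2_ibd1) / n_valid, 0.0
        )
        p2c = np.clip(p2, 0.0, None)
    pihat_raw = p1c / 2.0 + p2c
    pihat = np.clip(pihat_raw, 0.0, 1.0)
    np.fill_diagonal(pihat, 1.0)
    reliable = n_valid >= min_overlap
    return pihat, reliable


def pihat(
    dosages_a: np.ndarray,
    dosages_b: np.ndarray,
    allele_freqs: np.ndarray,
    min_overlap: int = 200,
    clamp: bool = True,
) -> tuple[float, bool]:
    """PI-HAT for one sample pair; see :func:`pihat_matrix`.

    With ``clamp=False`` the raw (possibly negative) estimate is returned,
    useful for calibration checks on unrelated pairs.
    """
    d = np.stack([np.asarray(dosages_a, dtype=np.int8), np.asarray(dosages_b, dtype=np.int8)])
    if clamp:
        mat, rel = pihat_matrix(d, allele_freqs, min_overlap=min_overlap)
        return float(mat[0, 1]), bool(rel[0, 1])
    # unclamped scalar path (same arithmetic without the final clip)
    freqs = np.asarray(allele_freqs, dtype=float)
    poly = (freqs > 0) & (freqs < 1)
    a, b, freqs = d[0][poly], d[1][poly], freqs[poly]
    both = (a != MISSING) & (b != MISSING)
    a, b, freqs = a[both], b[both], freqs[both]
    n = len(a)
    ibs0 = int(((a == 0) & (b == 2)).sum() + ((a == 2) & (b == 0)).sum())
    ibs2 = int((a == b).sum())
    ibs1 = n - ibs0 - ibs2
    e = _ibs_expectations(freqs).sum(axis=0)
    p0 = ibs0 / e[0] if e[0] > 0 else 0.0
    p1 = (ibs1 - p0 * e[1]) / e[3] if e[3] > 0 else 0.0
    p2 = (ibs2 - max(p0, 0) * e[2] - max(p1, 0) * (n - e[3])) / n if n else 0.0
    return max(p1, 0.0) / 2.0 + p2, n >= min_overlap


def select_unrelated(
    dataset: GenotypeDataset,
    pihat_max: float,
    variant_subset: np.ndarray | None = None,
    min_overlap: int = 200,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy relatedness exclusion.

    Computes PI-HAT on the given variant subset (ideally an LD-pruned panel),
    flags reliable pairs (>= ``min_overlap`` jointly-called variants) with
    PI-HAT >= ``pihat_max``, then repeatedly removes the
    sample involved in the most flagged pairs (ties broken by sample id,
    removing the lexicographically later id so original samples win over
    appended duplicates) until no flagged pair survives.

    Returns (retained sample ids, flagged pairs as (id_a, id_b, pihat)).
    """
    d = dataset.dosages if variant_subset is None else dataset.dosages[:, variant_subset]
    obs = np.ma.masked_equal(d, MISSING)
    freqs = obs.mean(axis=0).filled(0.0) / 2.0
    mat, rel = pihat_matrix(d, freqs, min_overlap=min_overlap)

    ids = dataset.sample_ids
    n = len(ids)
    hit = (mat >= pihat_max) & rel
    hit[np.tril_indices(n)] = False
    flagged_idx = list(zip(*np.nonzero(hit)))
    flagged = [(ids[i], ids[j], float(mat[i, j])) for i, j in flagged_idx]

    edges = {(i, j) for i, j in flagged_idx}
    removed: set[int] = set()
    while edges:
        degree: dict[int, int] = {}
        for i, j in edges:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        worst = max(degree, key=lambda k: (degree[k], ids[k]))
        removed.add(worst)
        edges = {(i, j) for i, j in edges if worst not in (i, j)}
    retained = [ids[i] for i in range(n) if i not in removed]
    return retained, flagged


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(
    dataset: GenotypeDataset, r2_max: float = 0.2, window: int = 50, step: int = 5
) -> np.ndarray:
    """Greedy left-to-right windowed LD pruning on dosage correlation.

    Within any window of ``window`` variants (advanced by ``step``), a variant
    is dropped if its squared Pearson correlation with an already-kept earlier
    variant in the window exceeds ``r2_max``. Returns kept variant indices.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    d = np.ma.masked_equal(dataset.dosages, MISSING).astype(float)
    m = dataset.n_variants
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        end = min(start + window, m)
        idx = [j for j in range(start, end) if keep[j]]
        if len(idx) > 1:
            with np.errstate(invalid="ignore"):
                corr = np.ma.corrcoef(d[:, idx], rowvar=False)
            r2 = np.ma.filled(corr, 0.0) ** 2
            for a_pos, j in enumerate(idx):
                if not keep[j]:
                    continue
                for b_pos in range(a_pos + 1, len(idx)):
                    k = idx[b_pos]
                    if keep[k] and r2[a_pos, b_pos] > r2_max:
                        keep[k] = False
        if end == m:
            break
        start += step
    return np.nonzero(keep)[0]


# ---------------------------------------------------------------------------
# Full QC


def apply_qc(
    dataset: GenotypeDataset,
    thresholds: QCThresholds,
    ld_r2_max: float = 0.2,
    min_overlap: int = 200,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply all QC filters in the documented order and reconcile counts.

    Order: (1) variant call rate, (2) MAF, (3) HWE tiers — a variant fails if
    its exact HWE p is below ``hwe_p_min_all`` in cases AND in controls, or
    below ``hwe_p_min_controls`` in controls alone, or below
    ``hwe_p_min_cases`` in cases alone — (4) sample call rate, (5) relatedness
    on an LD-pruned panel. Raises if the output would be empty.
    """
    report = QCReport(input_samples=dataset.n_samples, input_variants=dataset.n_variants)
    ds = dataset

    def _check_nonempty(d: GenotypeDataset) -> None:
        if d.n_samples == 0 or d.n_variants == 0:
            raise ValueError("QC removed every sample or every variant")

    # (1) variant call rate: remove iff call_rate < 1 - geno
    summaries = variant_summaries(ds)
    bad = [s.variant_id for s in summaries if s.call_rate < 1 - thresholds.variant_missingness_max]
    report.add_step("variant_call_rate", bad, [])
    ds = _drop_variants(ds, bad)

    # (2) MAF
    summaries = variant_summaries(ds)
    bad = [s.variant_id for s in summaries if s.maf is None or s.maf < thresholds.maf_min]
    report.add_step("maf", bad, [])
    ds = _drop_variants(ds, bad)
    _check_nonempty(ds)

    # (3) HWE tiers
    summaries = variant_summaries(ds)
    bad = []
    for s in summaries:
        p_cases = hwe_exact_test(*s.counts_cases) if sum(s.counts_cases) else 1.0
        p_controls = hwe_exact_test(*s.counts_controls) if sum(s.counts_controls) else 1.0
        fails = (
            (p_cases < thresholds.hwe_p_min_all and p_controls < thresholds.hwe_p_min_all)
            or p_controls < thresholds.hwe_p_min_controls
            or p_cases < thresholds.hwe_p_min_cases
        )
        if fails:
            bad.append(s.variant_id)
    report.add_step("hwe", bad, [])
    ds = _drop_variants(ds, bad)
    _check_nonempty(ds)

    # (4) sample call rate
    if ds.n_variants:
        miss = (ds.dosages == MISSING).mean(axis=1)
    else:
        miss = np.zeros(ds.n_samples)
    bad_samples = [
        s.sample_id for s, m in zip(ds.samples, miss) if m > thresholds.sample_missingness_max
    ]
    report.add_step("sample_call_rate", [], bad_samples)
    ds = _drop_samples(ds, bad_samples)
    _check_nonempty(ds)

    # (5) relatedness
    pruned = ld_prune(ds, r2_max=ld_r2_max)
    retained, _flagged = select_unrelated(
        ds, thresholds.pihat_max, variant_subset=pruned, min_overlap=min_overlap
    )
    retained_set = set(retained)
    bad_samples = [s.sample_id for s in ds.samples if s.sample_id not in retained_set]
    report.add_step("relatedness", [], bad_samples)
    ds = _drop_samples(ds, bad_samples)

    report.output_samples = ds.n_samples
    report.output_variants = ds.n_variants
    _check_nonempty(ds)
    return ds, report


def _drop_variants(ds: GenotypeDataset, variant_ids: list[str]) -> GenotypeDataset:
    if not variant_ids:
        return ds
    drop = set(variant_ids)
    keep = [j for j, v in enumerate(ds.variants) if v.variant_id not in drop]
    return ds.subset(variant_idx=keep)


def _drop_samples(ds: GenotypeDataset, sample_ids: list[str]) -> GenotypeDataset:
    if not sample_ids:
        return ds
    drop = set(sample_ids)
    keep = [i for i, s in enumerate(ds.samples) if s.sample_id not in drop]
    return ds.subset(sample_idx=keep)
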