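"""Synthetic case-control cohorts with planted epistatic architecture.

The generator emulates a post-QC imputed case-control dataset at desk scale:
biallelic SNPs under Hardy-Weinberg equilibrium, genes laid out on one
synthetic chromosome with upstream promoter intervals, and a logistic disease
model with planted gene-pair interactions,

    logit P(case) = b0 + sum over planted pairs (b1*gA + b2*gB + b3*gA*gB),

with minor-allele dosage coding 0/1/2 and b0 = logit(baseline prevalence).
Sampling is retrospective: population individuals are drawn until the case and
control quotas fill, mirroring a case-control design. Under this sampling the
interaction odds ratio exp(b3) remains the recoverable quantity (case-control
ascertainment shifts only the intercept of a logistic model).

`inject_artifacts` adds the defects the QC stage must catch: missing calls,
heterozygote-deficient (HWE-violating) variants and near-duplicate samples,
and returns a manifest so QC recall can be measured against ground truth.

All randomness flows from one `numpy.random.Generator` seeded from the config;
identical config (including seed) gives a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
from scipy.special import expit, logit

from .io import (
    MISSING,
    PHENO_CASE,
    PHENO_CONTROL,
    GeneModel,
    GenotypeDataset,
    Sample,
    Variant,
)

# synthetic chromosome layout: gene g's body starts at g*GENE_SPACING + BODY_OFFSET
# (0-based), body SNPs every SNP_SPACING bp, promoter PROMOTER_GAP bp upstream.
GENE_SPACING = 100_000
BODY_OFFSET = 10_000
SNP_SPACING = 100
PROMOTER_GAP = 2_000
PROMOTER_LENGTH = 1_000
CHROM = "1"

DRAW_CAP = 10_000_000


class QuotaError(RuntimeError):
    """A case/control quota could not be filled within the draw cap."""


@dataclass(frozen=True)
class PlantedInteraction:
    """One planted gene-pair interaction in the disease model.

    ``log_or_interaction`` is the log odds per unit of the dosage product
    gA*gB; its exponential is the interaction odds ratio the downstream
    logistic test estimates.
    """

    gene_a: str
    gene_b: str
    causal_snp_a: int  # body-SNP index within gene_a
    causal_snp_b: int
    log_or_main_a: float = 0.0
    log_or_main_b: float = 0.0
    log_or_interaction: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("planted interaction must link two distinct genes")


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 500
    n_controls: int = 500
    n_genes: int = 20
    snps_per_gene: int = 3
    promoter_snps_per_gene: int = 1
    maf_range: tuple[float, float] = (0.1, 0.4)
    baseline_prevalence: float = 0.01
    planted_interactions: tuple[PlantedInteraction, ...] = ()
    missing_rate: float = 0.0
    n_hwe_violating_snps: int = 0
    n_duplicate_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 < self.baseline_prevalence < 1):
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_genes < 1 or self.snps_per_gene < 1:
            raise ValueError("need at least one gene with one SNP")
        object.__setattr__(self, "planted_interactions", tuple(self.planted_interactions))
        gene_ids = set(gene_id_list(self.n_genes))
        for pi in self.planted_interactions:
            for g in (pi.gene_a, pi.gene_b):
                if g not in gene_ids:
                    raise ValueError(f"planted gene {g!r} not among the {self.n_genes} simulated genes")
            for idx in (pi.causal_snp_a, pi.causal_snp_b):
                if not 0 <= idx < self.snps_per_gene:
                    raise ValueError("causal SNP index outside the gene body")


@dataclass
class SimulationTruth:
    """What was planted: everything needed for recovery and QC-recall tests."""

    config: SimulationConfig
    allele_freqs: np.ndarray  # per-variant population MAF
    causal_variant_ids: list[tuple[str, str]]  # one (snp_a, snp_b) per planted pair

    def to_json(self) -> str:
        payload = {
            "config": _config_to_dict(self.config),
            "allele_freqs": [round(float(f), 10) for f in self.allele_freqs],
            "causal_variant_ids": self.causal_variant_ids,
        }
        return json.dumps(payload, indent=1)


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["planted_interactions"] = [asdict(pi) for pi in config.planted_interactions]
    d["maf_range"] = list(config.maf_range)
    return d


def gene_id_list(n_genes: int) -> list[str]:
    width = max(3, len(str(n_genes - 1)))
    return [f"G{g:0{width}d}" for g in range(n_genes)]


def variant_layout(config: SimulationConfig) -> list[Variant]:
    """Deterministic variant grid shared by cohort and annotation generators.

    Gene g's body SNPs sit at 1-based positions ``g*GENE_SPACING + BODY_OFFSET
    + i*SNP_SPACING + 1``; promoter SNPs sit inside the promoter interval
    upstream. Variants are returned in position order.
    """
    variants: list[Variant] = []
    for g, gid in enumerate(gene_id_list(config.n_genes)):
        body_start0 = g * GENE_SPACING + BODY_OFFSET
        prom_start0 = body_start0 - PROMOTER_GAP
        for i in range(config.promoter_snps_per_gene):
            pos = prom_start0 + i * SNP_SPACING + 1
            variants.append(Variant(f"{gid}_p{i}", CHROM, pos, "A", "B"))
        for i in range(config.snps_per_gene):
            pos = body_start0 + i * SNP_SPACING + 1
            variants.append(Variant(f"{gid}_s{i}", CHROM, pos, "A", "B"))
    return variants


def body_snp_id(gene: str, index: int) -> str:
    return f"{gene}_s{index}"


def simulate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Gene models matching :func:`variant_layout`.

    Each gene gets one body interval covering its body SNPs and one disjoint
    upstream promoter interval covering its promoter SNPs. When there are at
    least two genes, the last gene's promoter is extended to reach back over
    the previous gene's body so at least one variant maps to two genes
    (exercising multi-assignment downstream).
    """
    models: list[GeneModel] = []
    gids = gene_id_list(config.n_genes)
    for g, gid in enumerate(gids):
        body_start0 = g * GENE_SPACING + BODY_OFFSET
        body_end0 = body_start0 + (config.snps_per_gene - 1) * SNP_SPACING + 1
        prom_start0 = body_start0 - PROMOTER_GAP
        prom_end0 = prom_start0 + max(
            PROMOTER_LENGTH, (config.promoter_snps_per_gene - 1) * SNP_SPACING + 1
        )
        intervals = [(prom_start0, prom_end0, "promoter"), (body_start0, body_end0, "body")]
        if g == config.n_genes - 1 and config.n_genes >= 2:
            # reach back over the previous gene's last body SNP
            prev_body_start0 = (g - 1) * GENE_SPACING + BODY_OFFSET
            prev_last_snp0 = prev_body_start0 + (config.snps_per_gene - 1) * SNP_SPACING
            intervals.append((prev_last_snp0, prev_last_snp0 + 1, "promoter"))
        models.append(GeneModel(gene_id=gid, chrom=CHROM, intervals=intervals))
    return models


def _causal_columns(config: SimulationConfig, variant_ids: list[str]) -> list[tuple[int, int]]:
    index = {vid: i for i, vid in enumerate(variant_ids)}
    cols = []
    for pi in config.planted_interactions:
        cols.append(
            (index[body_snp_id(pi.gene_a, pi.causal_snp_a)],
             index[body_snp_id(pi.gene_b, pi.causal_snp_b)])
        )
    return cols


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeDataset, SimulationTruth]:
    """Draw a case-control cohort under the planted logistic disease model.

    Raises :class:`QuotaError` if either quota cannot be filled within
    ``DRAW_CAP`` population draws (pathological prevalence/effect choices).
    """
    rng = np.random.default_rng(config.seed)
    variants = variant_layout(config)
    vids = [v.variant_id for v in variants]
    n_var = len(variants)

    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=n_var)
    causal_cols = _causal_columns(config, vids)
    betas = [
        (pi.log_or_main_a, pi.log_or_main_b, pi.log_or_interaction)
        for pi in config.planted_interactions
    ]
    b0 = float(logit(config.baseline_prevalence))

    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    n_cases_needed, n_controls_needed = config.n_cases, config.n_controls
    drawn = 0
    batch = max(1024, min(65536, 4 * (n_cases_needed + n_controls_needed)))
    while n_cases_needed > 0 or n_controls_needed > 0:
        if drawn >= DRAW_CAP:
            missing_quota = "case" if n_cases_needed > 0 else "control"
            raise QuotaError(
                f"could not fill the {missing_quota} quota within {DRAW_CAP} population draws"
            )
        b = min(batch, DRAW_CAP - drawn)
        geno = rng.binomial(2, mafs, size=(b, n_var)).astype(np.int8)
        eta = np.full(b, b0)
        for (ca, cb), (b1, b2, b3) in zip(causal_cols, betas):
            ga = geno[:, ca].astype(float)
            gb = geno[:, cb].astype(float)
            eta += b1 * ga + b2 * gb + b3 * ga * gb
        is_case = rng.random(b) < expit(eta)
        drawn += b
        for i in np.nonzero(is_case)[0]:
            if n_cases_needed > 0:
                case_rows.append(geno[i])
                n_cases_needed -= 1
        for i in np.nonzero(~is_case)[0]:
            if n_controls_needed > 0:
                control_rows.append(geno[i])
                n_controls_needed -= 1

    dosages = np.vstack(case_rows + control_rows)
    samples = [Sample(f"case_{i:05d}", PHENO_CASE) for i in range(config.n_cases)] + [
        Sample(f"ctrl_{i:05d}", PHENO_CONTROL) for i in range(config.n_controls)
    ]
    dataset = GenotypeDataset(samples=samples, variants=variants, dosages=dosages)
    truth = SimulationTruth(
        config=config,
        allele_freqs=mafs,
        causal_variant_ids=[(vids[a], vids[b]) for a, b in causal_cols],
    )
    return dataset, truth


@dataclass
class ArtifactManifest:
    """Record of injected QC defects, for recall/precision tests."""

    hwe_violating_variant_ids: list[str] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)  # (original, copy)
    n_missing_injected: int = 0


def inject_artifacts(
    dataset: GenotypeDataset, config: SimulationConfig
) -> tuple[GenotypeDataset, ArtifactManifest]:
    """Corrupt a clean cohort with the defects QC is meant to remove.

    Missing calls at ``missing_rate``; ``n_hwe_violating_snps`` non-causal
    variants overwritten with an extreme heterozygote-deficient genotype
    distribution (only homozygotes at allele frequency 1/2); and
    ``n_duplicate_samples`` appended near-copies of existing samples.
    Artifact randomness derives from ``config.seed`` (offset stream) so the
    corrupted cohort is as reproducible as the clean one.
    """
    rng = np.random.default_rng((config.seed, 0xA27))
    manifest = ArtifactManifest()
    dosages = dataset.dosages.copy()
    samples = list(dataset.samples)
    vids = dataset.variant_ids

    if config.n_hwe_violating_snps:
        causal = {vid for pair in _causal_columns(config, vids) for vid in pair}
        eligible = [j for j in range(dataset.n_variants) if j not in causal]
        if config.n_hwe_violating_snps > len(eligible):
            raise ValueError("more HWE-violating variants requested than non-causal variants")
        chosen = rng.choice(eligible, size=config.n_hwe_violating_snps, replace=False)
        for j in sorted(chosen):
            # only homozygotes, allele freq 1/2: maximal het deficit, MAF-filter safe
            dosages[:, j] = 2 * rng.integers(0, 2, size=dataset.n_samples, dtype=np.int8)
            manifest.hwe_violating_variant_ids.append(vids[j])

    if config.n_duplicate_samples:
        if config.n_duplicate_samples > dataset.n_samples:
            raise ValueError("more duplicate samples requested than samples present")
        originals = rng.choice(dataset.n_samples, size=config.n_duplicate_samples, replace=False)
        dup_rows = []
        for i in sorted(originals):
            orig = samples[i]
            dup_id = f"dup_{orig.sample_id}"
            samples.append(Sample(dup_id, orig.phenotype))
            dup_rows.append(dosages[i].copy())
            manifest.duplicate_pairs.append((orig.sample_id, dup_id))
        dosages = np.vstack([dosages, np.array(dup_rows, dtype=np.int8)])

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        manifest.n_missing_injected = int(mask.sum())
        dosages[mask] = MISSING

    out = GenotypeDataset(samples=samples, variants=list(dataset.variants), dosages=dosages)
    return out, manifest


# ---------------------------------------------------------------------------
# On-disk outputs


def write_simulation(
    dataset: GenotypeDataset,
    truth: SimulationTruth,
    gene_models: list[GeneModel],
    prefix: str | Path,
) -> dict[str, Path]:
    """Write PLINK triplet, annotation BED, truth JSON and a config echo."""
    from .io import write_annotation_bed, write_plink

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_plink(dataset, prefix)
    bed_path = prefix.parent / (prefix.name + ".annotation.bed")
    write_annotation_bed(gene_models, bed_path)
    truth_path = prefix.parent / (prefix.name + ".truth.json")
    truth_path.write_text(truth.to_json())
    config_path = prefix.parent / (prefix.name + ".config.json")
    config_path.write_text(json.dumps(_config_to_dict(truth.config), indent=1))
    return {
        "bed": prefix.with_suffix(".bed"),
        "bim": prefix.with_suffix(".bim"),
        "fam": prefix.with_suffix(".fam"),
        "annotation": bed_path,
        "truth": truth_path,
        "config": config_path,
    }
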