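"""Reproducible calibration and recovery studies over synthetic cohorts.

These are the package's standing experiments: null calibration of the
two-stage scan, recovery of a planted interaction odds ratio, end-to-end
recovery of the planted gene pair, and QC recall against an artifact
manifest. The analysis drivers, the test suite and the acceptance script all
run the same code so every reported number has a single definition.

Study conditions (chosen once, documented in the methods note):

* null calibration — a cohort of 500 cases + 500 controls over 150
  single-SNP genes, giving C(150, 2) = 11,175 intergenic null pairs;
* effect recovery — 200 replicate cohorts of 1,000 cases + 1,000 controls
  with one planted pair at interaction OR = 2 (log-OR ln 2) and modest main
  effects (log-OR 0.15);
* planted-pair ranking — 100 replicates of the same effect inside a
  48-gene scan (1,128 gene pairs) with the default screen threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import kstest

from .collapse import eligible_intergenic_pairs, map_snps_to_genes
from .epistasis import STATUS_OK, logistic_interaction_test, scan_pairs
from .qc import PRESETS, apply_qc
from .simulate import (
    PlantedInteraction,
    SimulationConfig,
    inject_artifacts,
    simulate_annotation,
    simulate_cohort,
)

LN2 = math.log(2.0)
_Z975 = 1.959963984540054


def _derive_seed(seed: int, stream: int) -> int:
    """Independent child seed below 2**31."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------


def null_calibration_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_cases=500, n_controls=500, n_genes=150, snps_per_gene=1,
        promoter_snps_per_gene=0, maf_range=(0.1, 0.4),
        baseline_prevalence=0.01, seed=seed,
    )


@dataclass
class NullCalibration:
    n_pairs: int
    type_i_error: float  # fraction of Wald p <= 0.05
    ks_statistic: float
    ks_pvalue: float
    pvalues: np.ndarray


def null_calibration(seed: int, alpha: float = 0.05) -> NullCalibration:
    """Two-stage scan on a null cohort: every intergenic pair gets the
    follow-up (screen threshold 1) and the Wald p-values are summarised."""
    cfg = null_calibration_config(_derive_seed(seed, 1))
    dataset, _ = simulate_cohort(cfg)
    models = simulate_annotation(cfg)
    assignment = map_snps_to_genes(dataset, models)
    pairs = eligible_intergenic_pairs(assignment)
    results = scan_pairs(dataset, pairs, screen_alpha=1.0)
    pvals = np.array([r.p_wald for r in results if r.status == STATUS_OK])
    ks = kstest(pvals, "uniform")
    return NullCalibration(
        n_pairs=len(pvals),
        type_i_error=float((pvals <= alpha).mean()),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        pvalues=pvals,
    )


# ---------------------------------------------------------------------------


def planted_effect_config(seed: int, n_cases: int = 1000, n_controls: int = 1000,
                          n_genes: int = 4) -> SimulationConfig:
    return SimulationConfig(
        n_cases=n_cases, n_controls=n_controls, n_genes=n_genes, snps_per_gene=1,
        promoter_snps_per_gene=0, maf_range=(0.2, 0.4), baseline_prevalence=0.01,
        planted_interactions=(
            PlantedInteraction("G000", "G001", 0, 0, 0.15, 0.15, LN2),
        ),
        seed=seed,
    )


@dataclass
class EffectRecovery:
    n_replicates: int
    coverage: float  # fraction of 95% Wald intervals containing ln 2
    mean_log_or: float
    mean_or: float


def interaction_recovery(seed: int, n_replicates: int = 200) -> EffectRecovery:
    """Refit the causal SNP pair across replicate cohorts; summarise the
    Wald-interval coverage of the true interaction log-OR and its mean."""
    covered = 0
    betas = []
    for rep in range(n_replicates):
        cfg = planted_effect_config(_derive_seed(seed, 100_000 + rep))
        dataset, truth = simulate_cohort(cfg)
        vindex = dataset.variant_index()
        snp_a, snp_b = truth.causal_variant_ids[0]
        fit = logistic_interaction_test(
            dataset.dosages[:, vindex[snp_a]],
            dataset.dosages[:, vindex[snp_b]],
            dataset.phenotypes,
        )
        if fit["status"] != STATUS_OK:
            continue
        b3, se = fit["beta3"], fit["se"]
        betas.append(b3)
        if b3 - _Z975 * se <= LN2 <= b3 + _Z975 * se:
            covered += 1
    n = len(betas)
    return EffectRecovery(
        n_replicates=n,
        coverage=covered / n,
        mean_log_or=float(np.mean(betas)),
        mean_or=float(np.exp(np.mean(betas))),
    )


@dataclass
class PlantedTopRate:
    n_replicates: int
    top_rate: float  # fraction of replicates where the causal pair is the best follow-up
    followup_rate: float  # fraction where it reached the follow-up at all


def planted_top_gi_rate(
    seed: int, n_replicates: int = 100, screen_alpha: float = 1e-4
) -> PlantedTopRate:
    """Full two-stage scan on replicate cohorts with one planted pair among
    ~1,100 gene pairs; how often is the causal SNP pair the top Wald hit?"""
    hits = 0
    followed_up = 0
    for rep in range(n_replicates):
        cfg = planted_effect_config(_derive_seed(seed, 200_000 + rep), n_genes=48)
        dataset, truth = simulate_cohort(cfg)
        models = simulate_annotation(cfg)
        assignment = map_snps_to_genes(dataset, models, sources=("body",))
        pairs = eligible_intergenic_pairs(assignment)
        results = scan_pairs(dataset, pairs, screen_alpha=screen_alpha)
        causal = tuple(sorted(truth.causal_variant_ids[0]))
        followups = [r for r in results if r.p_wald is not None]
        in_followup = any((r.snp_a, r.snp_b) == causal for r in followups)
        followed_up += in_followup
        if followups and in_followup:
            top = min(followups, key=lambda r: (r.p_wald, r.snp_a, r.snp_b))
            hits += (top.snp_a, top.snp_b) == causal
    return PlantedTopRate(
        n_replicates=n_replicates,
        top_rate=hits / n_replicates,
        followup_rate=followed_up / n_replicates,
    )


# ---------------------------------------------------------------------------


def qc_stress_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_cases=150, n_controls=150, n_genes=150, snps_per_gene=8,
        promoter_snps_per_gene=1, maf_range=(0.15, 0.45), baseline_prevalence=0.01,
        planted_interactions=(
            PlantedInteraction("G000", "G001", 0, 0, 0.15, 0.15, LN2),
        ),
        missing_rate=0.01, n_hwe_violating_snps=10, n_duplicate_samples=4,
        seed=seed,
    )


@dataclass
class QcRecall:
    hwe_recall: float        # injected HWE-violating variants removed
    duplicate_recall: float  # injected duplicate pairs resolved
    causal_retention: float  # planted causal SNPs surviving QC


def qc_recall(seed: int) -> QcRecall:
    """Corrupt a cohort with known artifacts, run full QC, score recall."""
    cfg = qc_stress_config(_derive_seed(seed, 3))
    dataset, truth = simulate_cohort(cfg)
    corrupted, manifest = inject_artifacts(dataset, cfg)
    filtered, report = apply_qc(corrupted, PRESETS["imputed"], min_overlap=200)

    removed_v = report.removed_variant_ids
    removed_s = report.removed_sample_ids
    hwe_hits = sum(v in removed_v for v in manifest.hwe_violating_variant_ids)
    dup_hits = sum(
        (orig in removed_s) or (dup in removed_s)
        for orig, dup in manifest.duplicate_pairs
    )
    kept = set(filtered.variant_ids)
    causal = [v for pair in truth.causal_variant_ids for v in pair]
    return QcRecall(
        hwe_recall=hwe_hits / len(manifest.hwe_violating_variant_ids),
        duplicate_recall=dup_hits / len(manifest.duplicate_pairs),
        causal_retention=sum(v in kept for v in causal) / len(causal),
    )
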