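import math

import numpy as np
import pytest
from hypothesis import settings

from epinet.simulate import (
    PlantedInteraction,
    SimulationConfig,
    simulate_annotation,
    simulate_cohort,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

LN2 = math.log(2.0)


@pytest.fixture(scope="session")
def planted_cfg() -> SimulationConfig:
    """Small cohort with one planted interaction (OR = 2) between G000/G001."""
    return SimulationConfig(
        n_cases=400,
        n_controls=400,
        n_genes=6,
        snps_per_gene=3,
        promoter_snps_per_gene=1,
        maf_range=(0.2, 0.4),
        baseline_prevalence=0.01,
        planted_interactions=(
            PlantedInteraction("G000", "G001", 0, 0, 0.15, 0.15, LN2),
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_cfg):
    dataset, truth = simulate_cohort(planted_cfg)
    return dataset, truth, simulate_annotation(planted_cfg)


@pytest.fixture(scope="session")
def null_cfg() -> SimulationConfig:
    return SimulationConfig(
        n_cases=500,
        n_controls=500,
        n_genes=10,
        snps_per_gene=2,
        promoter_snps_per_gene=0,
        maf_range=(0.2, 0.4),
        seed=7,
    )


@pytest.fixture(scope="session")
def null_cohort(null_cfg):
    dataset, truth = simulate_cohort(null_cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def qc_stress_cfg() -> SimulationConfig:
    """Cohort with injected QC defects and enough SNPs for a reliable
    relatedness panel (the real workflows use tens of thousands)."""
    return SimulationConfig(
        n_cases=150,
        n_controls=150,
        n_genes=150,
        snps_per_gene=8,
        promoter_snps_per_gene=1,
        maf_range=(0.15, 0.45),
        baseline_prevalence=0.01,
        planted_interactions=(
            PlantedInteraction("G000", "G001", 0, 0, 0.15, 0.15, LN2),
        ),
        missing_rate=0.01,
        n_hwe_violating_snps=10,
        n_duplicate_samples=4,
        seed=3,
    )


def random_pair_table(rng: np.random.Generator, n: int = 400) -> np.ndarray:
    """A random 3x3x2 count table from a random joint distribution."""
    probs = rng.dirichlet(np.ones(18))
    return rng.multinomial(n, probs).reshape(3, 3, 2)
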