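"""QC: exact HWE test, PI-HAT relatedness, LD pruning, filter pipeline."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2

from epinet.io import MISSING, PHENO_CASE, PHENO_CONTROL, GenotypeDataset, Sample, Variant
from epinet.qc import (
    PRESETS,
    QCThresholds,
    apply_qc,
    hwe_exact_test,
    ld_prune,
    pihat,
    select_unrelated,
    variant_summaries,
)
from epinet.simulate import inject_artifacts, simulate_cohort

from .oracles import hwe_enum_pvalue


def _dataset_from_dosages(dosages, phenos=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    phenos = phenos or [PHENO_CASE if i < n // 2 else PHENO_CONTROL for i in range(n)]
    return GenotypeDataset(
        samples=[Sample(f"s{i:03d}", p) for i, p in enumerate(phenos)],
        variants=[Variant(f"v{j}", "1", 100 * (j + 1), "A", "B") for j in range(m)],
        dosages=dosages,
    )


class TestVariantSummaries:
    def test_direct_counts(self):
        ds = _dataset_from_dosages([[0], [0], [1], [2]])
        s = variant_summaries(ds)[0]
        assert s.maf == pytest.approx(3 / 8)
        assert s.call_rate == 1.0

    def test_monomorphic_maf_zero(self):
        ds = _dataset_from_dosages([[0], [0], [0], [0]])
        assert variant_summaries(ds)[0].maf == 0.0

    def test_call_rate_with_missing(self):
        ds = _dataset_from_dosages([[0], [MISSING], [2], [MISSING]])
        s = variant_summaries(ds)[0]
        assert s.call_rate == 0.5

    def test_all_missing_flagged_undefined(self):
        ds = _dataset_from_dosages([[MISSING], [MISSING]])
        s = variant_summaries(ds)[0]
        assert s.call_rate == 0.0 and s.maf is None

    def test_stratified_counts_sum_to_totals(self):
        ds = _dataset_from_dosages([[0], [1], [1], [2]])
        s = variant_summaries(ds)[0]
        assert tuple(
            c + k for c, k in zip(s.counts_cases, s.counts_controls)
        ) == s.counts_all


class TestHweExactTest:
    def test_monomorphic_p_is_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_allele_label_symmetry(self):
        assert hwe_exact_test(10, 20, 5) == pytest.approx(hwe_exact_test(5, 20, 10), rel=1e-12)

    def test_matches_enumeration_oracle_on_spec_counts(self):
        assert hwe_exact_test(68, 57, 75) == pytest.approx(hwe_enum_pvalue(68, 57, 75), rel=1e-9)

    @given(
        n_hom1=st.integers(0, 80),
        n_het=st.integers(0, 80),
        n_hom2=st.integers(0, 80),
    )
    def test_matches_enumeration_oracle_everywhere(self, n_hom1, n_het, n_hom2):
        if n_hom1 + n_het + n_hom2 == 0:
            return
        assert hwe_exact_test(n_hom1, n_het, n_hom2) == pytest.approx(
            hwe_enum_pvalue(n_hom1, n_het, n_hom2), rel=1e-9
        )

    def test_pvalue_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = rng.integers(0, 50, size=3)
            if c.sum() == 0:
                continue
            p = hwe_exact_test(*c)
            assert 0 < p <= 1

    def test_agrees_with_chisquare_for_large_balanced_counts(self):
        # asymptotic consistency: 1-df chi-square p within 20% relative
        for counts in [(2500, 5000, 2500), (2400, 5100, 2500), (3600, 4700, 1700)]:
            n_hom1, n_het, n_hom2 = counts
            n = sum(counts)
            p_a = (2 * n_hom1 + n_het) / (2 * n)
            expected = np.array([p_a**2, 2 * p_a * (1 - p_a), (1 - p_a) ** 2]) * n
            stat = float(((np.array(counts) - expected) ** 2 / expected).sum())
            p_chi = float(chi2.sf(stat, df=1))
            p_exact = hwe_exact_test(*counts)
            assert p_exact == pytest.approx(p_chi, rel=0.2)


class TestPihat:
    @staticmethod
    def _freqs_and_pair(rng, m=1000, maf=0.3, kind="unrelated"):
        f = np.full(m, maf)
        a = rng.binomial(2, f).astype(np.int8)
        if kind == "identical":
            b = a.copy()
        elif kind == "parent_offspring":
            transmitted = np.where(a == 2, 1, np.where(a == 0, 0, rng.integers(0, 2, m)))
            b = (transmitted + rng.binomial(1, f)).astype(np.int8)
        else:
            b = rng.binomial(2, f).astype(np.int8)
        return a, b, f

    def test_identical_vectors_pihat_near_one(self):
        rng = np.random.default_rng(1)
        a, b, f = self._freqs_and_pair(rng, kind="identical")
        est, reliable = pihat(a, b, f)
        assert 0.9 <= est <= 1.0 and reliable

    def test_unrelated_pair_unclamped_near_zero(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(30):
            a, b, f = self._freqs_and_pair(rng, kind="unrelated")
            vals.append(pihat(a, b, f, clamp=False)[0])
        assert -0.1 < np.mean(vals) < 0.1

    def test_parent_offspring_pihat_near_half(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(20):
            a, b, f = self._freqs_and_pair(rng, kind="parent_offspring")
            vals.append(pihat(a, b, f)[0])
        assert 0.4 <= np.mean(vals) <= 0.6

    def test_too_few_overlapping_calls_flagged_unreliable(self):
        rng = np.random.default_rng(4)
        a, b, f = self._freqs_and_pair(rng, m=50)
        _, reliable = pihat(a, b, f, min_overlap=200)
        assert not reliable


class TestSelectUnrelated:
    def _related_dataset(self, structure, m=600, seed=0):
        """structure: list of groups of sample indices sharing one genotype row."""
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.2, 0.5, m)
        n = max(i for group in structure for i in group) + 1
        dosages = rng.binomial(2, f, size=(n, m)).astype(np.int8)
        for group in structure:
            for i in group[1:]:
                dosages[i] = dosages[group[0]]
        return _dataset_from_dosages(dosages)

    def test_no_related_pairs_is_identity(self):
        ds = self._related_dataset([[0], [1], [2], [3], [4], [5]])
        retained, flagged = select_unrelated(ds, 0.1875, min_overlap=100)
        assert retained == ds.sample_ids and flagged == []

    def test_duplicate_pair_removes_exactly_one(self):
        ds = self._related_dataset([[0, 1], [2], [3], [4], [5]])
        retained, flagged = select_unrelated(ds, 0.1875, min_overlap=100)
        assert len(retained) == 5
        assert len({"s000", "s001"} & set(retained)) == 1

    def test_triangle_of_duplicates_removes_two(self):
        # minimum vertex cover of a 3-clique has size 2
        ds = self._related_dataset([[0, 1, 2], [3], [4], [5], [6]])
        retained, _ = select_unrelated(ds, 0.1875, min_overlap=100)
        assert len(retained) == 5
        assert len({"s000", "s001", "s002"} & set(retained)) == 1


class TestLdPrune:
    def test_independent_variants_untouched(self):
        rng = np.random.default_rng(5)
        ds = _dataset_from_dosages(rng.binomial(2, 0.3, size=(300, 20)).astype(np.int8))
        kept = ld_prune(ds, r2_max=0.5)
        assert list(kept) == list(range(20))

    def test_duplicated_column_pruned(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.3, size=(100, 5)).astype(np.int8)
        d[:, 3] = d[:, 1]
        ds = _dataset_from_dosages(d)
        kept = ld_prune(ds, r2_max=0.8)
        assert 1 in kept and 3 not in kept

    def test_perfectly_correlated_small_vectors_pruned(self):
        ds = _dataset_from_dosages(np.array([[0, 0], [1, 1], [2, 2], [1, 1]]))
        kept = ld_prune(ds, r2_max=0.99)
        assert list(kept) == [0]


class TestApplyQc:
    def test_permissive_thresholds_are_identity(self, null_cohort):
        dataset, _ = null_cohort
        permissive = QCThresholds(
            variant_missingness_max=1.0, sample_missingness_max=1.0, maf_min=0.0,
            hwe_p_min_all=0.0, hwe_p_min_controls=0.0, hwe_p_min_cases=0.0,
            pihat_max=1.1,
        )
        out, report = apply_qc(dataset, permissive, min_overlap=10)
        assert out.n_samples == dataset.n_samples
        assert out.n_variants == dataset.n_variants
        assert report.removed_variant_ids == set() == report.removed_sample_ids

    def test_call_rate_boundary_remove_iff_below_threshold(self):
        # 100 samples; variant 0 has 94 calls (< 0.95 -> removed),
        # variant 1 has 95 calls (= 0.95 -> retained)
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.4, size=(100, 2)).astype(np.int8)
        d[:6, 0] = MISSING
        d[:5, 1] = MISSING
        ds = _dataset_from_dosages(d)
        thresholds = QCThresholds(
            variant_missingness_max=0.05, sample_missingness_max=1.0, maf_min=0.0,
            hwe_p_min_all=0.0, hwe_p_min_controls=0.0, hwe_p_min_cases=0.0, pihat_max=1.1,
        )
        out, report = apply_qc(ds, thresholds, min_overlap=1)
        assert report.steps[0]["removed_variant_ids"] == ["v0"]
        assert out.variant_ids == ["v1"]

    def test_report_counts_conserved_each_step(self, artifact_cohort):
        _, _, _, report = artifact_cohort
        n_var = report.input_variants
        n_samp = report.input_samples
        for step in report.steps:
            n_var -= len(step["removed_variant_ids"])
            n_samp -= len(step["removed_sample_ids"])
        assert (n_var, n_samp) == (report.output_variants, report.output_samples)

    def test_idempotent(self, artifact_cohort):
        _, _, filtered, _ = artifact_cohort
        again, report2 = apply_qc(filtered, PRESETS["imputed"], min_overlap=200)
        assert again.n_samples == filtered.n_samples
        assert again.n_variants == filtered.n_variants

    def test_empty_output_raises(self):
        ds = _dataset_from_dosages(np.zeros((20, 3), dtype=np.int8))  # all monomorphic
        with pytest.raises(ValueError, match="every"):
            apply_qc(ds, PRESETS["imputed"], min_overlap=1)


@pytest.fixture(scope="session")
def artifact_cohort(qc_stress_cfg):
    dataset, truth = simulate_cohort(qc_stress_cfg)
    corrupted, manifest = inject_artifacts(dataset, qc_stress_cfg)
    filtered, report = apply_qc(corrupted, PRESETS["imputed"], min_overlap=200)
    return truth, manifest, filtered, report


class TestQcRecall:
    def test_all_injected_hwe_violations_removed(self, artifact_cohort):
        _, manifest, _, report = artifact_cohort
        assert set(manifest.hwe_violating_variant_ids) <= report.removed_variant_ids

    def test_all_duplicate_samples_resolved(self, artifact_cohort):
        _, manifest, _, report = artifact_cohort
        removed = report.removed_sample_ids
        for orig, dup in manifest.duplicate_pairs:
            assert orig in removed or dup in removed

    def test_planted_causal_snps_retained(self, artifact_cohort):
        truth, _, filtered, _ = artifact_cohort
        kept = set(filtered.variant_ids)
        for snp_a, snp_b in truth.causal_variant_ids:
            assert snp_a in kept and snp_b in kept
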