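"""Two-stage scan: pair tables, KSA screen, logistic follow-up."""

import numpy as np
import pytest
import statsmodels.api as sm

from epinet.epistasis import (
    STATUS_DEGENERATE,
    STATUS_OK,
    STATUS_SCREEN_ONLY,
    PairTable,
    boost_screen,
    kirkwood_fit,
    logistic_interaction_test,
    pair_table,
    scan_pairs,
)
from epinet.io import MISSING, PHENO_CASE, PHENO_CONTROL
from epinet.collapse import eligible_intergenic_pairs, map_snps_to_genes

from .conftest import random_pair_table
from .oracles import exact_lr_statistic, grid_search_logistic, ksa_cell_by_cell, ksa_tau


class TestPairTable:
    def test_all_same_cell(self):
        t = pair_table(np.zeros(4), np.zeros(4), np.full(4, PHENO_CONTROL))
        assert t.counts[0, 0, 0] == 4 and t.counts.sum() == 4

    def test_missing_genotype_drops_sample(self):
        t = pair_table(
            np.array([0, MISSING, 1, 2]), np.array([0, 0, 1, 2]),
            np.array([PHENO_CONTROL, PHENO_CONTROL, PHENO_CASE, PHENO_CASE]),
        )
        assert t.n_used == 3

    def test_missing_phenotype_drops_sample(self):
        t = pair_table(np.array([0, 1]), np.array([0, 1]), np.array([PHENO_CONTROL, -1]))
        assert t.n_used == 1

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        ga = rng.integers(0, 3, 50)
        gb = rng.integers(0, 3, 50)
        ph = rng.integers(0, 2, 50)
        perm = rng.permutation(50)
        t1 = pair_table(ga, gb, ph)
        t2 = pair_table(ga[perm], gb[perm], ph[perm])
        assert np.array_equal(t1.counts, t2.counts)


class TestKirkwoodFit:
    def test_uniform_table_is_independence_fixed_point(self):
        t = PairTable(counts=np.full((3, 3, 2), 10), n_used=180)
        fitted = kirkwood_fit(t)
        assert np.allclose(fitted, t.counts / 180)

    def test_product_of_marginals_is_fixed_point(self):
        pi = np.array([0.5, 0.3, 0.2])
        pj = np.array([0.25, 0.5, 0.25])
        pk = np.array([0.4, 0.6])
        joint = pi[:, None, None] * pj[None, :, None] * pk[None, None, :]
        counts = np.round(joint * 4000).astype(int)
        t = PairTable(counts=counts, n_used=int(counts.sum()))
        fitted = kirkwood_fit(t)
        assert np.allclose(fitted, counts / counts.sum(), atol=1e-9)

    def test_zero_row_marginal_gives_zero_cells_rest_renormalised(self):
        counts = np.full((3, 3, 2), 5)
        counts[2, :, :] = 0  # genotype 2 at SNP A never observed
        t = PairTable(counts=counts, n_used=int(counts.sum()))
        fitted = kirkwood_fit(t)
        assert np.all(fitted[2] == 0)
        assert fitted.sum() == pytest.approx(1.0)

    def test_matches_cell_by_cell_formula_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            counts = random_pair_table(rng)
            if counts.sum() == 0:
                continue
            t = PairTable(counts=counts, n_used=int(counts.sum()))
            assert np.allclose(kirkwood_fit(t), ksa_cell_by_cell(counts), atol=1e-12)


class TestBoostScreen:
    def test_uniform_table_tau_zero_p_one(self):
        t = PairTable(counts=np.full((3, 3, 2), 10), n_used=180)
        tau, p = boost_screen(t)
        assert tau == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_tau_non_negative_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            counts = random_pair_table(rng)
            t = PairTable(counts=counts, n_used=int(counts.sum()))
            try:
                tau, _ = boost_screen(t)
            except ValueError:
                continue
            assert tau >= -1e-8

    def test_tau_upper_bounds_exact_lr_statistic(self):
        # the KSA log-likelihood never exceeds the IPF-fitted maximum, so
        # tau >= the exact homogeneous-association LR on every table
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 100:
            counts = random_pair_table(rng, n=300)
            t = PairTable(counts=counts, n_used=int(counts.sum()))
            try:
                tau, _ = boost_screen(t)
            except ValueError:
                continue
            assert tau >= exact_lr_statistic(counts) - 1e-6
            checked += 1

    def test_tau_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            counts = random_pair_table(rng)
            t = PairTable(counts=counts, n_used=int(counts.sum()))
            try:
                tau, _ = boost_screen(t)
            except ValueError:
                continue
            assert tau == pytest.approx(ksa_tau(counts), rel=1e-9, abs=1e-9)


class TestLogisticInteraction:
    @staticmethod
    def _simulate(rng, n=200, b=(0.2, 0.1, -0.1, 0.8), maf=(0.3, 0.4)):
        ga = rng.binomial(2, maf[0], n).astype(float)
        gb = rng.binomial(2, maf[1], n).astype(float)
        eta = b[0] + b[1] * ga + b[2] * gb + b[3] * ga * gb
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        ph = np.where(y == 1, PHENO_CASE, PHENO_CONTROL)
        return ga, gb, ph

    def test_null_data_beta3_within_three_se(self):
        rng = np.random.default_rng(5)
        ga, gb, ph = self._simulate(rng, n=2000, b=(0.0, 0.0, 0.0, 0.0))
        fit = logistic_interaction_test(ga, gb, ph)
        assert fit["status"] == STATUS_OK
        assert abs(fit["beta3"]) < 3 * fit["se"]

    def test_matches_grid_search_mle_within_1e2(self):
        rng = np.random.default_rng(6)
        ga, gb, ph = self._simulate(rng, n=200)
        fit = logistic_interaction_test(ga, gb, ph)
        X = np.column_stack([np.ones(len(ga)), ga, gb, ga * gb])
        y = (ph == PHENO_CASE).astype(float)
        beta_grid = grid_search_logistic(X, y)
        assert fit["beta3"] == pytest.approx(beta_grid[3], abs=1e-2)

    def test_matches_statsmodels_fit(self):
        rng = np.random.default_rng(7)
        ga, gb, ph = self._simulate(rng, n=500)
        fit = logistic_interaction_test(ga, gb, ph)
        X = np.column_stack([np.ones(len(ga)), ga, gb, ga * gb])
        y = (ph == PHENO_CASE).astype(float)
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit["beta3"] == pytest.approx(ref.params[3], abs=1e-6)
        assert fit["se"] == pytest.approx(ref.bse[3], rel=1e-4)
        assert fit["p_wald"] == pytest.approx(ref.pvalues[3], rel=1e-4)

    def test_constant_snp_is_degenerate(self):
        rng = np.random.default_rng(8)
        _, gb, ph = self._simulate(rng, n=100)
        fit = logistic_interaction_test(np.zeros(100), gb, ph)
        assert fit["status"] == STATUS_DEGENERATE
        assert fit["or_value"] is None

    def test_single_class_phenotype_is_degenerate(self):
        rng = np.random.default_rng(9)
        ga = rng.integers(0, 3, 50)
        gb = rng.integers(0, 3, 50)
        fit = logistic_interaction_test(ga, gb, np.full(50, PHENO_CASE))
        assert fit["status"] == STATUS_DEGENERATE

    def test_separation_flagged_not_reported(self):
        # interaction perfectly predicts status -> quasi-separation
        ga = np.array([0, 0, 1, 1, 2, 2] * 10)
        gb = np.array([0, 1, 0, 1, 2, 2] * 10)
        ph = np.where(ga * gb >= 2, PHENO_CASE, PHENO_CONTROL)
        fit = logistic_interaction_test(ga, gb, ph)
        assert fit["status"] in ("non_converged", "degenerate")
        assert fit["or_value"] is None

    def test_swapping_snps_leaves_beta3_unchanged(self):
        rng = np.random.default_rng(10)
        ga, gb, ph = self._simulate(rng, n=400)
        f1 = logistic_interaction_test(ga, gb, ph)
        f2 = logistic_interaction_test(gb, ga, ph)
        assert f1["beta3"] == pytest.approx(f2["beta3"], rel=1e-8)
        assert f1["or_value"] == pytest.approx(f2["or_value"], rel=1e-8)


@pytest.fixture(scope="module")
def scan_inputs(planted_cohort):
    dataset, truth, models = planted_cohort
    assignment = map_snps_to_genes(dataset, models)
    pairs = eligible_intergenic_pairs(assignment)
    return dataset, truth, pairs


class TestScanPairs:
    def test_screen_alpha_one_follows_up_everything(self, scan_inputs):
        dataset, _, pairs = scan_inputs
        res = scan_pairs(dataset, pairs[:40], screen_alpha=1.0)
        assert all(r.status != STATUS_SCREEN_ONLY for r in res)

    def test_screen_alpha_zero_no_followups(self, scan_inputs):
        dataset, _, pairs = scan_inputs
        res = scan_pairs(dataset, pairs[:40], screen_alpha=0.0)
        assert all(r.p_wald is None for r in res)
        assert all(r.status in (STATUS_SCREEN_ONLY, STATUS_DEGENERATE) for r in res)

    def test_symmetry_in_pair_order(self, scan_inputs):
        dataset, _, pairs = scan_inputs
        a, b = pairs[0]
        r1 = scan_pairs(dataset, [(a, b)], screen_alpha=1.0)[0]
        r2 = scan_pairs(dataset, [(b, a)], screen_alpha=1.0)[0]
        assert (r1.snp_a, r1.snp_b) == (r2.snp_a, r2.snp_b)
        assert r1.tau == pytest.approx(r2.tau, rel=1e-12)
        assert r1.beta3 == pytest.approx(r2.beta3, rel=1e-9)

    def test_output_sorted_and_deterministic(self, scan_inputs):
        dataset, _, pairs = scan_inputs
        res1 = scan_pairs(dataset, pairs, screen_alpha=1.0)
        res2 = scan_pairs(dataset, list(reversed(pairs)), screen_alpha=1.0)
        assert [(r.snp_a, r.snp_b) for r in res1] == [(r.snp_a, r.snp_b) for r in res2]
        pw = [r.p_wald for r in res1 if r.p_wald is not None]
        assert pw == sorted(pw)

    def test_vectorised_screen_equals_per_pair_reference(self, planted_cohort):
        # scan_pairs counts cells with block-vectorised indicator products;
        # pair_table/boost_screen recompute each pair independently
        import dataclasses

        from epinet.simulate import inject_artifacts

        dataset, truth, models = planted_cohort
        cfg = dataclasses.replace(truth.config, missing_rate=0.03)
        noisy, _ = inject_artifacts(dataset, cfg)
        assignment = map_snps_to_genes(noisy, models)
        pairs = eligible_intergenic_pairs(assignment)[:150]
        res = scan_pairs(noisy, pairs, screen_alpha=0.0)
        vi = noisy.variant_index()
        ph = noisy.phenotypes
        for r in res:
            table = pair_table(noisy.dosages[:, vi[r.snp_a]],
                               noisy.dosages[:, vi[r.snp_b]], ph)
            assert table.n_used == r.n_used
            try:
                tau, p_screen = boost_screen(table)
            except ValueError:
                assert r.status == STATUS_DEGENERATE
                continue
            assert r.tau == pytest.approx(tau, rel=1e-9, abs=1e-9)
            assert r.p_screen == pytest.approx(p_screen, rel=1e-9)

    def test_planted_pair_has_minimum_wald_p(self, scan_inputs):
        dataset, truth, pairs = scan_inputs
        res = scan_pairs(dataset, pairs, screen_alpha=1.0)
        ok = [r for r in res if r.status == STATUS_OK]
        top = min(ok, key=lambda r: r.p_wald)
        assert {top.snp_a, top.snp_b} == set(truth.causal_variant_ids[0])
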