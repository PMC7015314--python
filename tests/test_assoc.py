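"""Association stages: PCA, linear GWAS, Li-Ji Me, allelic tests, IBS."""

import numpy as np
import pytest

from cssig import (
    QTLConfig,
    SimulationConfig,
    allelic_association,
    bonferroni_thresholds,
    effective_tests_li_ji,
    gwas_linear,
    ibs_permutation_test,
    li_ji_me_from_correlation,
    pca,
    simulate_quantitative_phenotype,
    simulate_speed_indices,
    simulate_two_pop_panel,
)

from conftest import make_panel


class TestPCA:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        res = pca(np.column_stack([x, 2 * x + 1]))
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_two_uncorrelated_variables_split_evenly(self):
        # exactly orthogonal centred columns
        a = np.array([1.0, 1.0, -1.0, -1.0])
        b = np.array([1.0, -1.0, 1.0, -1.0])
        res = pca(np.column_stack([a, b]))
        np.testing.assert_allclose(res.variance_fractions, [0.5, 0.5], atol=1e-12)

    def test_fractions_sum_to_one_and_decrease(self, rng):
        res = pca(rng.normal(size=(40, 6)))
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)
        # loadings orthonormal
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(6), atol=1e-10)

    def test_latent_factor_share_recovered(self):
        """Generating model implies PC1 share (1 + 5a^2)/6 ~ 0.647."""
        tab = simulate_speed_indices(500, seed=9)
        cols = ["v_peak", "acc", "ave_spr", "dist6a", "dist6b", "dist6"]
        res = pca(tab[cols].to_numpy())
        assert res.variance_fractions[0] == pytest.approx(0.647, abs=0.03)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            pca(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestGWASLinear:
    def test_perfect_fit(self):
        hap = np.array(
            [[0, 1], [0, 0], [1, 0], [0, 1], [1, 1], [1, 0], [0, 0], [0, 1],
             [1, 1], [1, 1], [0, 0], [1, 0]], dtype=np.int8)
        panel = make_panel(hap)
        y = 2.0 * panel.genotypes()[:, 0]
        res = gwas_linear(panel, y)
        assert res.beta[0] == pytest.approx(2.0, abs=1e-10)
        assert res.p_unadj[0] < 1e-10

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        panel = simulate_two_pop_panel(SimulationConfig(n_snps=8, n_per_cohort=30, seed=4))
        y = rng.normal(size=panel.n_individuals)
        cov = rng.normal(size=panel.n_individuals)
        res = gwas_linear(panel, y, covariates=cov)
        G = panel.genotypes()
        for j in range(8):
            if np.isnan(res.beta[j]):
                continue
            X = sm.add_constant(np.column_stack([cov, G[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert res.beta[j] == pytest.approx(fit.params[-1], rel=1e-10)
            assert res.se[j] == pytest.approx(fit.bse[-1], rel=1e-10)
            assert res.p_unadj[j] == pytest.approx(fit.pvalues[-1], rel=1e-8)

    def test_monomorphic_invalid_and_collinear_raises(self):
        hap = np.zeros((8, 1), dtype=np.int8)
        panel = make_panel(hap)
        res = gwas_linear(panel, np.arange(4.0))
        assert np.isnan(res.beta[0])
        with pytest.raises(ValueError, match="collinear"):
            gwas_linear(panel, np.arange(4.0), covariates=np.ones(4))

    def test_beta_recovery_within_three_se(self):
        ok = 0
        for s in range(40):
            panel = simulate_two_pop_panel(
                SimulationConfig(n_snps=40, n_per_cohort=100, seed=500 + s))
            pheno = simulate_quantitative_phenotype(
                panel, QTLConfig(snp_index=20, beta=0.5, residual_sd=1.0), seed=600 + s)
            sex = (pheno["sex"] == "M").to_numpy().astype(float)
            res = gwas_linear(panel, pheno["phenotype"].to_numpy(), covariates=sex)
            if abs(res.beta[20] - 0.5) <= 3 * res.se[20]:
                ok += 1
        assert ok >= 38  # >= 95% of replicates


class TestEffectiveTests:
    def test_independent_correlation_counts_every_test(self):
        assert li_ji_me_from_correlation(np.eye(7)) == pytest.approx(7.0)

    def test_duplicated_snp_counts_once(self):
        # dosages per individual are (0, 2, 1) at both SNPs -> identical columns
        hap = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [0, 0], [1, 1]], dtype=np.int8)
        panel = make_panel(hap)
        assert effective_tests_li_ji(panel) == pytest.approx(1.0)

    def test_three_snp_eigenvalue_oracle(self):
        r12, r13, r23 = 0.9, 0.1, 0.3
        corr = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
        lam = np.linalg.eigvalsh(corr)
        expected = sum((l >= 1) + (l - np.floor(l)) for l in np.clip(lam, 0, None))
        assert li_ji_me_from_correlation(corr) == pytest.approx(expected, rel=1e-12)

    def test_me_bounded_and_decreasing_in_ld(self):
        mes = []
        for rate in (0.002, 0.05, 1.0):
            panel = simulate_two_pop_panel(
                SimulationConfig(n_snps=200, mosaic_switch_rate=rate, seed=5))
            me = effective_tests_li_ji(panel)
            assert 1 <= me <= panel.n_snps
            mes.append(me)
        assert mes[0] < mes[1] < mes[2]


class TestThresholds:
    def test_published_effective_count_reproduces_printed_thresholds(self):
        thr = bonferroni_thresholds(20_661)
        assert thr.genomewide_p == pytest.approx(2.4e-6, rel=0.05)
        assert thr.suggestive_p == pytest.approx(4.8e-5, rel=0.05)

    def test_single_test_limit(self):
        thr = bonferroni_thresholds(1)
        assert (thr.genomewide_p, thr.suggestive_p) == (0.05, 1.0)
        assert thr.genomewide_p < thr.suggestive_p


class TestAllelic:
    def _case_control_panel(self, rng, n=120, m=30):
        panel = simulate_two_pop_panel(
            SimulationConfig(n_snps=m, n_per_cohort=n // 2, f_drift=0.02, seed=8))
        labels = ["case"] * (n // 2) + ["control"] * (n // 2)
        panel.individuals["cohort"] = labels
        return panel

    def test_identical_counts_null(self):
        # both cohorts carry alt-allele frequency 0.5 at the single SNP
        hap = np.array([[0], [1], [1], [0]] * 2, dtype=np.int8)
        panel = make_panel(hap, cohorts=["case", "case", "control", "control"])
        res = allelic_association(panel, "case", "control", maf_min=0.0, call_min=0.0)
        assert res.statistic[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_unadj[0] == pytest.approx(1.0)

    def test_two_by_two_oracle(self):
        """[[30,10],[10,30]] -> chi-square 20 by sum (O-E)^2/E; OR = 9."""
        table = np.array([[30, 10], [10, 30.0]])
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_oracle = ((table - exp) ** 2 / exp).sum()
        # panel realizing those allele counts: 20 cases, 20 controls
        rows = []
        for (a, b), n in [((1, 1), 15), ((1, 0), 0), ((0, 0), 5)]:
            rows += [[a], [b]] * n
        case = np.array(rows, dtype=np.int8)
        rows = []
        for (a, b), n in [((1, 1), 5), ((1, 0), 0), ((0, 0), 15)]:
            rows += [[a], [b]] * n
        ctrl = np.array(rows, dtype=np.int8)
        hap = np.vstack([case, ctrl])
        panel = make_panel(hap, cohorts=["case"] * 20 + ["control"] * 20)
        res = allelic_association(panel, "case", "control", maf_min=0.0, call_min=0.0)
        assert res.statistic[0] == pytest.approx(chi2_oracle, rel=1e-10)
        assert res.statistic[0] == pytest.approx(20.0, rel=1e-10)
        assert res.odds_ratio[0] == pytest.approx(9.0, rel=1e-10)

    def test_bonferroni_multiplication_and_cap(self, rng):
        panel = self._case_control_panel(rng)
        res = allelic_association(panel, "case", "control", maf_min=0.05, call_min=0.95)
        n = len(res)
        np.testing.assert_allclose(
            res.p_adjusted, np.minimum(res.p_unadj * n, 1.0), atol=1e-12)
        assert (res.p_adjusted <= 1).all()
        assert (res.p_adjusted >= res.p_unadj - 1e-15).all()

    def test_adjustment_arithmetic(self):
        assert min(1.0, 0.0005 * 109) == pytest.approx(0.0545)


class TestIBSPermutation:
    def test_clone_groups_reach_minimal_p(self, rng):
        a = (rng.random(40) < 0.5).astype(np.int8)
        b = 1 - a
        hap = np.array([a] * 12 + [b] * 12)
        panel = make_panel(hap, cohorts=["g1"] * 6 + ["g2"] * 6)
        obs, p = ibs_permutation_test(panel, panel.individuals["cohort"].to_numpy(),
                                      n_perm=200, seed=3)
        assert obs < 0
        assert p == pytest.approx(1 / 201)

    def test_deterministic_given_seed(self, null_panel):
        labels = null_panel.individuals["cohort"].to_numpy()
        sub = null_panel.take_snps(np.arange(100))
        r1 = ibs_permutation_test(sub, labels, n_perm=150, seed=9)
        r2 = ibs_permutation_test(sub, labels, n_perm=150, seed=9)
        assert r1 == r2

    def test_random_labels_not_extreme(self, rng):
        panel = simulate_two_pop_panel(
            SimulationConfig(n_snps=120, n_per_cohort=15, f_drift=0.02, seed=21))
        sub = panel.take_individuals(np.arange(15))  # one cohort: unstructured
        ps = []
        for s in range(5):
            labels = rng.permutation(["a"] * 8 + ["b"] * 7)
            _, p = ibs_permutation_test(sub, labels, n_perm=150, seed=s)
            ps.append(p)
        # roughly uniform: not all tiny, not all 1
        assert min(ps) > 1 / 151 or max(ps) > 0.2
        assert np.mean(ps) > 0.1
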