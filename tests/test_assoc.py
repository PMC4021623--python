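"""Single-mtSNP regression tests and significance accounting."""

import numpy as np
import pandas as pd
import pytest

from mtphewas import (linear_assoc, logistic_assoc, run_mt_scan,
                      expected_false_positives, summarize_counts)

from conftest import random_genotypes


def ols_oracle(y, x):
    """Normal-equations OLS with Wald t, independent of statsmodels."""
    from scipy.stats import t as t_dist
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = y.size - x.shape[1]
    s2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(s2 * xtx_inv))
    t = beta / se
    p = 2 * t_dist.sf(np.abs(t), df)
    return beta, se, t, p


def irls_logistic_oracle(y, x, n_iter=60):
    """Hand-rolled Newton/IRLS logistic fit with Wald z."""
    from scipy.stats import norm
    beta = np.zeros(x.shape[1])
    for _ in range(n_iter):
        eta = x @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        h = x.T @ (w[:, None] * x)
        step = np.linalg.solve(h, x.T @ (y - mu))
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    cov = np.linalg.inv(x.T @ ((mu * (1 - mu))[:, None] * x))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * norm.sf(np.abs(z))
    return beta, se, z, p


class TestLinearAssoc:
    def test_noiseless_construction_beta_exact(self):
        rng = np.random.default_rng(1)
        n = 100
        snp = rng.integers(0, 2, size=n).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 2.0 * snp + 0.0 * cov[:, 0]
        res = linear_assoc(y, cov, snp)
        assert res.effect == pytest.approx(2.0, abs=1e-10)
        assert res.p_value < 1e-100

    def test_matches_normal_equations_oracle_on_printed_fixture(self):
        # fixed 12-row fixture, values chosen once and frozen
        y = np.array([4.7, 5.0, 3.2, 6.9, 5.1, 4.8, 7.6, 6.3, 4.6, 4.9, 6.1, 6.4])
        age = np.array([41., 52., 39., 60., 55., 48., 71., 63., 50., 44., 68., 59.])
        sex = np.array([0., 1., 0., 1., 1., 0., 1., 0., 0., 1., 1., 0.])
        snp = np.array([0., 1., 0., 1., 0., 0., 1., 1., 0., 0., 1., 1.])
        res = linear_assoc(y, np.column_stack([age, sex]), snp)
        x = np.column_stack([np.ones(12), age, sex, snp])
        beta, se, t, p = ols_oracle(y, x)
        assert res.effect == pytest.approx(beta[3], abs=1e-10)
        assert res.se == pytest.approx(se[3], abs=1e-10)
        assert res.statistic == pytest.approx(t[3], abs=1e-8)
        assert res.p_value == pytest.approx(p[3], abs=1e-10)

    def test_permutation_null_small_beta_uniform_p(self):
        rng = np.random.default_rng(7)
        n = 500
        ps = []
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        for _ in range(100):
            snp = rng.permutation(np.repeat([0.0, 1.0], n // 2))
            ps.append(linear_assoc(y, cov, snp).p_value)
        ps = np.array(ps)
        # roughly uniform: mean near 0.5, about 5% below 0.05
        assert abs(ps.mean() - 0.5) < 0.1
        assert (ps < 0.05).sum() <= 15

    def test_monomorphic_flagged_untestable(self):
        y = np.random.default_rng(0).normal(size=20)
        res = linear_assoc(y, np.ones((20, 1)) * 0.5, np.zeros(20))
        assert not res.testable and np.isnan(res.p_value)


class TestLogisticAssoc:
    def test_no_association_or_one(self):
        # identical case fraction in both genotype groups
        y = np.array([1.0, 0.0] * 20)
        snp = np.array([0.0] * 20 + [1.0] * 20)
        res = logistic_assoc(y, np.zeros((40, 0)), snp)
        assert res.effect == pytest.approx(1.0, abs=1e-8)

    def test_2x2_closed_form_cross_product(self):
        # (a,b,c,d) = (30,20,15,35): OR = ad/bc = 3.5
        y = np.concatenate([np.ones(30), np.zeros(20), np.ones(15), np.zeros(35)])
        snp = np.concatenate([np.ones(50), np.zeros(50)])
        res = logistic_assoc(y, np.zeros((100, 0)), snp)
        assert res.effect == pytest.approx(3.5, abs=1e-6)
        se_expected = np.sqrt(1 / 30 + 1 / 20 + 1 / 15 + 1 / 35)
        assert res.se == pytest.approx(se_expected, abs=1e-6)

    def test_matches_irls_oracle_with_covariates(self):
        rng = np.random.default_rng(3)
        n = 200
        cov = rng.normal(size=(n, 2))
        snp = rng.integers(0, 2, size=n).astype(float)
        eta = -0.5 + 0.8 * snp + 0.3 * cov[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = logistic_assoc(y, cov, snp)
        x = np.column_stack([np.ones(n), cov, snp])
        beta, se, z, p = irls_logistic_oracle(y, x)
        assert np.log(res.effect) == pytest.approx(beta[3], abs=1e-6)
        assert res.se == pytest.approx(se[3], abs=1e-6)
        assert res.p_value == pytest.approx(p[3], abs=1e-6)

    def test_separation_flagged(self):
        y = np.concatenate([np.ones(20), np.zeros(20)])
        snp = y.copy()  # perfect separation
        res = logistic_assoc(y, np.zeros((40, 0)), snp)
        assert not res.testable

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            logistic_assoc(np.ones(30), np.zeros((30, 0)),
                           np.random.default_rng(0).integers(0, 2, 30).astype(float))


@pytest.fixture(scope="module")
def scan_inputs():
    g = random_genotypes(150, 0, 20, seed=33)
    g_mt = g.take_snps(np.where(g.ploidy == 1)[0])
    rng = np.random.default_rng(4)
    ph = pd.DataFrame({
        "age": rng.normal(50, 10, 150),
        "sex": rng.integers(0, 2, 150).astype(float),
        "PC1": rng.normal(size=150),
        "PC2": rng.normal(size=150),
        "chol": rng.normal(180, 40, 150),
        "t2d": rng.integers(0, 2, 150).astype(float),
    }, index=pd.Index(g_mt.sample_ids, name="sample_id"))
    return g_mt, ph


class TestScan:

    def test_one_row_per_trait_snp_pair(self, scan_inputs):
        g_mt, ph = scan_inputs
        res = run_mt_scan(g_mt, ph, {"chol": "continuous", "t2d": "binary"})
        assert len(res) == 2 * g_mt.n_snps
        assert set(res["kind"]) == {"linear", "logistic"}

    def test_empty_trait_list(self, scan_inputs):
        g_mt, ph = scan_inputs
        res = run_mt_scan(g_mt, ph, {})
        assert len(res) == 0

    def test_results_invariant_to_snp_order(self, scan_inputs):
        g_mt, ph = scan_inputs
        res1 = run_mt_scan(g_mt, ph, {"chol": "continuous"})
        perm = np.random.default_rng(9).permutation(g_mt.n_snps)
        res2 = run_mt_scan(g_mt.take_snps(perm), ph, {"chol": "continuous"})
        merged = res1.merge(res2, on="snp_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["p_value_a"], merged["p_value_b"], equal_nan=True)


class TestAccounting:
    @pytest.mark.parametrize("m,alpha,expected", [
        (86, 0.05, 4.3), (100, 0.05, 5.0), (0, 0.05, 0.0),
    ])
    def test_expected_by_chance(self, m, alpha, expected):
        assert expected_false_positives(m, alpha) == pytest.approx(expected)

    def test_counts_flags_and_brute_force(self):
        rng = np.random.default_rng(2)
        rows = []
        for j in range(86):
            rows.append({"snp_id": f"mt{j}", "trait": "t2d",
                         "p_value": 0.01 if j < 13 else rng.uniform(0.2, 1.0)})
            rows.append({"snp_id": f"mt{j}", "trait": "quiet",
                         "p_value": rng.uniform(0.06, 1.0)})
        res = pd.DataFrame(rows)
        summ = summarize_counts(res, alpha=0.05,
                                pve_per_trait={"t2d": 0.004, "quiet": 0.0001})
        counts = summ.counts.set_index("trait")
        # brute-force threshold pass
        for trait in ("t2d", "quiet"):
            brute = int((res[res["trait"] == trait]["p_value"] < 0.05).sum())
            assert counts.loc[trait, "n_significant"] == brute
        assert counts.loc["t2d", "n_significant"] == 13
        assert counts.loc["t2d", "exceeds_chance"]          # 13 > 4.3
        assert not counts.loc["quiet", "exceeds_chance"]

    def test_bonferroni_option_tightens_threshold(self):
        res = pd.DataFrame({"snp_id": [f"mt{j}" for j in range(100)],
                            "trait": "x",
                            "p_value": np.linspace(1e-5, 0.99, 100)})
        plain = summarize_counts(res, alpha=0.05)
        corrected = summarize_counts(res, alpha=0.05, bonferroni=True)
        # corrected threshold is 0.05/100 = 5e-4: only the smallest p passes
        assert corrected.counts["n_significant"].iloc[0] == 1
        assert plain.counts["n_significant"].iloc[0] > 1
        assert corrected.counts["expected_by_chance"].iloc[0] == \
            pytest.approx(0.05)

    def test_all_null_pvalues_no_flags(self):
        res = pd.DataFrame({"snp_id": [f"mt{j}" for j in range(10)] * 2,
                            "trait": ["a"] * 10 + ["b"] * 10,
                            "p_value": 1.0})
        summ = summarize_counts(res, alpha=0.05)
        assert (summ.counts["n_significant"] == 0).all()
        assert not summ.counts["exceeds_chance"].any()

    def test_null_scan_counts_near_binomial_expectation(self):
        """Phenotype independent of mito genotypes: counts average m*alpha."""
        rng = np.random.default_rng(77)
        g = random_genotypes(300, 0, 40, seed=55)
        g_mt = g.take_snps(np.where(g.ploidy == 1)[0])
        m = g_mt.n_snps
        counts = []
        covs = pd.DataFrame({
            "age": rng.normal(50, 10, 300), "sex": rng.integers(0, 2, 300),
            "PC1": rng.normal(size=300), "PC2": rng.normal(size=300),
        }, index=pd.Index(g_mt.sample_ids, name="sample_id"))
        reps = 40
        for _ in range(reps):
            ph = covs.copy()
            ph["y"] = rng.normal(size=300)
            res = run_mt_scan(g_mt, ph, {"y": "continuous"})
            counts.append(int((res["p_value"] < 0.05).sum()))
        mean = np.mean(counts)
        # binomial mean m*alpha = 2.0, sd of the mean ~ sqrt(m*a*(1-a)/reps)
        tol = 4 * np.sqrt(m * 0.05 * 0.95 / reps)
        assert abs(mean - m * 0.05) < tol
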