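"""EM-REML fitting, restricted likelihood, LRT conventions, prioritization."""

import numpy as np
import pytest
from scipy.stats import chi2

from mtphewas import (MixedModelSpec, VarianceComponentFit, LRTResult,
                      restricted_loglik, fit_em_reml, lrt_mito,
                      prioritize_phenotypes, simulate_phenotype)


def dense_reml_oracle(y, x, grms, sigma2):
    """Direct textbook evaluation with explicit inverses (no Cholesky path)."""
    n = y.size
    v = sigma2[-1] * np.eye(n)
    for s, a in zip(sigma2[:-1], grms):
        v = v + s * a
    vi = np.linalg.inv(v)
    xtvix = x.T @ vi @ x
    p = vi - vi @ x @ np.linalg.inv(xtvix) @ x.T @ vi
    _, ld_v = np.linalg.slogdet(v)
    _, ld_x = np.linalg.slogdet(xtvix)
    return -0.5 * (ld_v + ld_x + float(y @ p @ y))


@pytest.fixture(scope="module")
def small_model():
    rng = np.random.default_rng(5)
    n = 40
    z = rng.normal(size=(n, 15))
    a = z @ z.T / 15
    y = rng.normal(size=n)
    x = np.column_stack([np.ones(n), rng.normal(size=n)])
    return y, x, a


class TestRestrictedLoglik:
    def test_matches_dense_oracle(self, small_model):
        y, x, a = small_model
        spec = MixedModelSpec(y, x, [a])
        for sigma2 in ([0.5, 0.8], [1.2, 0.3], [0.05, 2.0]):
            got = restricted_loglik(spec, sigma2)
            want = dense_reml_oracle(y, x, [a], np.array(sigma2))
            assert got == pytest.approx(want, abs=1e-8)

    def test_grm_free_closed_form_maximum(self):
        rng = np.random.default_rng(8)
        n, p = 120, 3
        x = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = x @ np.array([1.0, 0.5, -0.3]) + rng.normal(size=n)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        rss = float(np.sum((y - x @ beta) ** 2))
        s2 = rss / (n - p)
        spec = MixedModelSpec(y, x, [])
        # closed-form residual REML likelihood at the maximizer (the
        # implementation keeps the data-dependent log|X'X| term)
        want = -0.5 * ((n - p) * np.log(s2) + rss / s2
                       + np.linalg.slogdet(x.T @ x)[1])
        assert restricted_loglik(spec, [s2]) == pytest.approx(want)
        # and the maximizer beats nearby values
        assert restricted_loglik(spec, [s2 * 1.1]) < want
        assert restricted_loglik(spec, [s2 * 0.9]) < want

    def test_scaling_identity_grm_free(self, small_model):
        # doubling sigma2_e changes logL by -0.5*((n-p) log 2 + (1/2 - 1) yPy)
        y, x, _ = small_model
        n, p = y.size, x.shape[1]
        spec = MixedModelSpec(y, x, [])
        ll1 = restricted_loglik(spec, [1.0])
        ll2 = restricted_loglik(spec, [2.0])
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        rss = float(np.sum((y - x @ beta) ** 2))
        assert ll2 - ll1 == pytest.approx(-0.5 * ((n - p) * np.log(2.0) - rss / 2.0))

    def test_wrong_component_count_rejected(self, small_model):
        y, x, a = small_model
        with pytest.raises(ValueError):
            restricted_loglik(MixedModelSpec(y, x, [a]), [1.0])


class TestFitEmReml:
    def test_grm_free_recovers_ols_residual_variance(self):
        rng = np.random.default_rng(12)
        n, p = 200, 2
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = x @ np.array([2.0, 1.0]) + rng.normal(scale=1.5, size=n)
        fit = fit_em_reml(MixedModelSpec(y, x, []), tol=1e-12, max_iter=500)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        expected = float(np.sum((y - x @ beta) ** 2)) / (n - p)
        assert fit.converged
        assert fit.sigma2[-1] == pytest.approx(expected, rel=1e-8)

    def test_loglik_trace_monotone_on_fixtures(self, reml_bench):
        cfg = reml_bench["cfg"]
        ph = simulate_phenotype(reml_bench["genotypes"], cfg,
                                grm_roots=reml_bench["roots"])
        y = ph["q"].to_numpy()
        x = np.column_stack([np.ones(len(y)), ph["age"], ph["sex"]])
        for grms in ([reml_bench["A"], reml_bench["S"]], [reml_bench["A"]], []):
            fit = fit_em_reml(MixedModelSpec(y, x, grms))
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_null_mito_component_pinned_at_floor(self, reml_bench):
        """sigma2_mt = 0 in truth: the estimate sits at the floor in most runs."""
        from mtphewas import TraitSpec
        cfg = reml_bench["cfg"]
        at_floor = 0
        reps = 6
        for rep in range(reps):
            cfg2 = type(cfg)(**{**cfg.__dict__,
                                "traits": [TraitSpec("q", pve_nuc=0.30, pve_mt=0.0)],
                                "seed": 900 + rep})
            ph = simulate_phenotype(reml_bench["genotypes"], cfg2,
                                    grm_roots=reml_bench["roots"])
            y = ph["q"].to_numpy()
            x = np.column_stack([np.ones(len(y)), ph["age"], ph["sex"]])
            fit = fit_em_reml(MixedModelSpec(y, x,
                                             [reml_bench["A"], reml_bench["S"]]))
            if fit.pve[1] < 0.01:
                at_floor += 1
        assert at_floor >= reps // 2 + 1

    def test_parameter_recovery_two_components(self, reml_bench):
        """Estimates center on the generating (pve_nuc, pve_mt) = (0.30, 0.05)."""
        cfg = reml_bench["cfg"]
        est = []
        reps = 5
        for rep in range(reps):
            cfg2 = type(cfg)(**{**cfg.__dict__, "seed": 300 + 17 * rep})
            ph = simulate_phenotype(reml_bench["genotypes"], cfg2,
                                    grm_roots=reml_bench["roots"])
            y = ph["q"].to_numpy()
            x = np.column_stack([np.ones(len(y)), ph["age"], ph["sex"]])
            fit = fit_em_reml(MixedModelSpec(y, x,
                                             [reml_bench["A"], reml_bench["S"]]))
            est.append(fit.pve)
        est = np.array(est)
        mean = est.mean(axis=0)
        sem = est.std(axis=0, ddof=1) / np.sqrt(reps)
        assert abs(mean[0] - 0.30) < 3 * max(sem[0], 0.02)
        assert abs(mean[1] - 0.05) < 3 * max(sem[1], 0.01)

    def test_nested_dominance(self, reml_bench):
        cfg = reml_bench["cfg"]
        ph = simulate_phenotype(reml_bench["genotypes"], cfg,
                                grm_roots=reml_bench["roots"])
        y = ph["q"].to_numpy()
        x = np.column_stack([np.ones(len(y)), ph["age"], ph["sex"]])
        full = fit_em_reml(MixedModelSpec(y, x, [reml_bench["A"], reml_bench["S"]]))
        red = fit_em_reml(MixedModelSpec(y, x, [reml_bench["A"]]))
        assert full.logL >= red.logL - 1e-6

    def test_rank_deficient_design_rejected(self):
        y = np.arange(10.0)
        x = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            MixedModelSpec(y, x, [])


class TestLrt:
    def _fit(self, ll, n=100):
        return VarianceComponentFit(
            sigma2=np.array([1.0]), se_sigma2=np.array([0.1]),
            pve=np.array([]), se_pve=np.array([]), logL=ll,
            n_iter=1, converged=True, n=n, names=[])

    def test_zero_statistic_boundary_convention(self):
        res = lrt_mito(self._fit(-10.0), self._fit(-10.0))
        assert res.statistic == 0.0
        assert res.p_mixture == pytest.approx(0.5)
        assert res.p_chi2_1 == pytest.approx(1.0)

    def test_known_quantile(self):
        # statistic 2.706 is the chi2_1 0.10 tail
        res = lrt_mito(self._fit(-10.0 + 2.706 / 2), self._fit(-10.0))
        assert res.p_chi2_1 == pytest.approx(chi2.sf(2.706, 1), abs=1e-12)
        assert res.p_chi2_1 == pytest.approx(0.100, abs=5e-4)
        assert res.p_mixture == pytest.approx(0.050, abs=3e-4)

    def test_negative_noise_clipped(self):
        res = lrt_mito(self._fit(-10.0 - 1e-9), self._fit(-10.0))
        assert res.statistic == 0.0

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValueError, match="sample sets"):
            lrt_mito(self._fit(-1.0, n=100), self._fit(-2.0, n=99))


class TestPrioritize:
    def test_alpha_and_suggestive_flags(self):
        res = {t: LRTResult(statistic=1.0, p_mixture=p, p_chi2_1=2 * p)
               for t, p in {"A": 0.046, "B": 0.055, "C": 0.30}.items()}
        df = prioritize_phenotypes(res, alpha=0.05, suggestive=0.055)
        assert list(df["trait"]) == ["A", "B", "C"]
        assert list(df.loc[df["prioritized"], "trait"]) == ["A"]
        assert list(df.loc[df["suggestive"], "trait"]) == ["B"]

    def test_all_null_empty_prioritized_set(self):
        res = {t: LRTResult(0.0, 1.0, 1.0) for t in "abc"}
        df = prioritize_phenotypes(res)
        assert not df["prioritized"].any()

    def test_order_invariant_under_relabeling(self):
        ps = {"x": 0.2, "y": 0.01, "z": 0.6}
        df1 = prioritize_phenotypes(ps)
        relabeled = {f"t_{k}": v for k, v in ps.items()}
        df2 = prioritize_phenotypes(relabeled)
        assert [t.removeprefix("t_") for t in df2["trait"]] == list(df1["trait"])
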