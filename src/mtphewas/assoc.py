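"""Single-mtSNP association scans with covariate adjustment.

Each mitochondrial SNP is tested one at a time against each trait:
linear regression (OLS, Wald t) for continuous traits and logistic
regression (ML, Wald z) for binary traits, both adjusted for age, sex and
the first two nuclear principal components. Haploid genotypes are coded
0/1 (single allele dose), so betas are per-allele on that coding.

Significance accounting follows the uncorrected-alpha convention: with m
SNPs tested at level alpha, ``m * alpha`` associations are expected by
chance alone; per-trait counts above that line, and the rank correlation
between per-trait mitochondrial PVE and counts, are the scan summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

from .genotype import GenotypeMatrix

__all__ = [
    "AssocResult",
    "PhewasSummary",
    "linear_assoc",
    "logistic_assoc",
    "run_mt_scan",
    "expected_false_positives",
    "summarize_counts",
]


@dataclass
class AssocResult:
    """One SNP x trait test.

    ``effect`` is the regression beta for continuous traits and the odds
    ratio for binary traits; ``se`` is of the beta / log-OR. Untestable
    SNPs (monomorphic in the complete cases, or separated in the logistic
    fit) carry ``testable=False`` with NaN statistics and a reason note.
    """

    snp_id: str
    trait: str
    n: int
    effect: float
    se: float
    statistic: float
    p_value: float
    kind: str  # "linear" | "logistic"
    testable: bool = True
    note: str = ""


@dataclass
class PhewasSummary:
    """Per-trait significant-SNP accounting for the scan."""

    counts: pd.DataFrame          # trait, n_significant, expected, exceeds_chance
    alpha: float
    m_snps: int
    spearman_rho: float           # PVE vs count rank correlation
    spearman_p: float


def _design(x_cov: np.ndarray, snp: np.ndarray) -> np.ndarray:
    x_cov = np.atleast_2d(np.asarray(x_cov, dtype=float))
    if x_cov.shape[0] != snp.size:
        x_cov = x_cov.T
    return np.column_stack([np.ones(snp.size), x_cov, snp])


def linear_assoc(y, x_cov, snp_calls, snp_id: str = "", trait: str = "") -> AssocResult:
    """OLS fit of ``y ~ intercept + covariates + snp``; Wald t on the SNP term."""
    y = np.asarray(y, dtype=float).ravel()
    snp = np.asarray(snp_calls, dtype=float).ravel()
    n = y.size
    if snp.min() == snp.max():
        return AssocResult(snp_id, trait, n, np.nan, np.nan, np.nan, np.nan,
                           "linear", testable=False, note="monomorphic in complete cases")
    x = _design(x_cov, snp)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, x).fit()
    j = x.shape[1] - 1
    return AssocResult(snp_id, trait, n,
                       effect=float(fit.params[j]), se=float(fit.bse[j]),
                       statistic=float(fit.tvalues[j]), p_value=float(fit.pvalues[j]),
                       kind="linear")


def logistic_assoc(y01, x_cov, snp_calls, snp_id: str = "", trait: str = "") -> AssocResult:
    """Logistic ML fit; effect reported as the odds ratio ``exp(beta_snp)``."""
    y = np.asarray(y01, dtype=float).ravel()
    snp = np.asarray(snp_calls, dtype=float).ravel()
    n = y.size
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class; logistic model undefined")
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("binary outcome must be coded 0/1")
    if snp.min() == snp.max():
        return AssocResult(snp_id, trait, n, np.nan, np.nan, np.nan, np.nan,
                           "logistic", testable=False, note="monomorphic in complete cases")
    x = _design(x_cov, snp)
    j = x.shape[1] - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and kin
            return AssocResult(snp_id, trait, n, np.nan, np.nan, np.nan, np.nan,
                               "logistic", testable=False, note=f"fit failed: {exc}")
    beta = float(fit.params[j])
    se = float(fit.bse[j])
    if not np.isfinite(se) or se > 1e3 or abs(beta) > 20:
        return AssocResult(snp_id, trait, n, np.nan, np.nan, np.nan, np.nan,
                           "logistic", testable=False, note="quasi-separation")
    return AssocResult(snp_id, trait, n,
                       effect=float(np.exp(beta)), se=se,
                       statistic=beta / se,
                       p_value=float(fit.pvalues[j]), kind="logistic")


def run_mt_scan(g_mt: GenotypeMatrix, phenotypes: pd.DataFrame,
                traits: dict[str, str],
                covariates: tuple[str, ...] = ("age", "sex", "PC1", "PC2"),
                ) -> pd.DataFrame:
    """Scan every (trait, mtSNP) pair; returns one row per test.

    ``traits`` maps trait column -> ``"continuous"`` or ``"binary"``.
    ``phenotypes`` is indexed by sample_id and must hold the covariate
    columns. Complete cases are taken per trait; a failing SNP never aborts
    the scan — its row is flagged untestable instead. The input mito
    genotypes are expected to be MAF-filtered already.
    """
    ph = phenotypes.loc[[s for s in g_mt.sample_ids if s in phenotypes.index]]
    order = {s: i for i, s in enumerate(g_mt.sample_ids)}
    rows = []
    for trait, kind in traits.items():
        cols = [trait, *covariates]
        sub = ph[cols].dropna()
        idx = np.array([order[s] for s in sub.index])
        y = sub[trait].to_numpy(dtype=float)
        xc = sub[list(covariates)].to_numpy(dtype=float)
        for j, snp_id in enumerate(g_mt.snp_ids):
            calls = g_mt.calls[idx, j]
            ok = ~np.isnan(calls)
            test = linear_assoc if kind == "continuous" else logistic_assoc
            try:
                res = test(y[ok], xc[ok], calls[ok], snp_id=snp_id, trait=trait)
            except ValueError as exc:
                res = AssocResult(snp_id, trait, int(ok.sum()), np.nan, np.nan,
                                  np.nan, np.nan,
                                  "linear" if kind == "continuous" else "logistic",
                                  testable=False, note=str(exc))
            rows.append(res.__dict__ | {"chrom": g_mt.chrom[j], "pos": int(g_mt.pos[j]),
                                        "a1": g_mt.a1[j]})
    return pd.DataFrame(rows)


def expected_false_positives(m: int, alpha: float) -> float:
    """Associations expected by chance alone among m tests at level alpha."""
    if m < 0 or not 0.0 <= alpha <= 1.0:
        raise ValueError("require m >= 0 and alpha in [0, 1]")
    return m * alpha


def summarize_counts(results: pd.DataFrame, alpha: float = 0.05,
                     pve_per_trait: dict[str, float] | None = None,
                     bonferroni: bool = False) -> PhewasSummary:
    """Per-trait significant counts, chance expectation, and the PVE-count
    Spearman correlation across traits.

    ``bonferroni=True`` divides alpha by the number of SNPs tested; the
    default is the uncorrected threshold, in keeping with the
    hypothesis-generating design.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    m = results["snp_id"].nunique()
    if bonferroni and m:
        alpha = alpha / m
    expected = expected_false_positives(m, alpha)
    counts = (results.assign(sig=results["p_value"] < alpha)
              .groupby("trait", sort=True)["sig"].sum().astype(int)
              .rename("n_significant").reset_index())
    counts["expected_by_chance"] = expected
    counts["exceeds_chance"] = counts["n_significant"] > expected
    rho = p = np.nan
    if pve_per_trait:
        counts["mito_pve"] = counts["trait"].map(pve_per_trait)
        both = counts.dropna(subset=["mito_pve"])
        if len(both) >= 3:
            rho, p = spearmanr(both["mito_pve"], both["n_significant"])
    return PhewasSummary(counts=counts, alpha=alpha, m_snps=m,
                         spearman_rho=float(rho), spearman_p=float(p))
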