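"""Variance-component mixed model: EM-REML fits and the mitochondrial LRT.

Model
-----
``y = X b + sum_i g_i + e`` with ``g_i ~ N(0, sigma2_i A_i)`` for each
relationship matrix ``A_i`` (nuclear additive, mitochondrial sharing) and
``e ~ N(0, sigma2_e I)``. Binary traits are analyzed on the observed 0/1
scale with the same linear mixed model.

The restricted log-likelihood is

``logL = -0.5 * (log|V| + log|X' V^-1 X| + y' P y)``

with ``V = sum_i sigma2_i A_i + sigma2_e I`` and
``P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1``. The additive constant
(-0.5 * (n - p) * log(2 pi) and the REML |X'X| term) is dropped throughout,
so likelihood *differences* — all that the LRT uses — are convention-free.

Maximization uses the EM-REML update

``sigma2_i <- sigma2_i + sigma2_i^2 / n * (y' P A_i P y - tr(A_i P))``

(``A_e = I`` for the residual), which keeps components non-negative and
never decreases the restricted likelihood. Plain EM crawls near the
optimum, so pairs of EM steps are extrapolated (SQUAREM scheme); an
extrapolated candidate is accepted only if it does not lower the
likelihood, so the recorded iterate trajectory stays monotone and every
accepted point is still reachable by the EM map. Models with at most one
GRM are evaluated in the GRM eigenbasis, where each iteration is O(n p^2)
instead of O(n^3).

Standard errors come from the inverse average-information matrix at the EM
solution (EM itself provides none); PVE standard errors by the delta
method.

The mitochondrial variance component is tested by a full (nuclear + mito
GRM) versus reduced (nuclear GRM only) likelihood-ratio test. Because the
null value sits on the boundary of the parameter space, the default null is
the mixture ``0.5 * chi2_0 + 0.5 * chi2_1``; the plain chi2_1 p-value is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from .grm import RelationshipMatrix

__all__ = [
    "MixedModelSpec",
    "VarianceComponentFit",
    "LRTResult",
    "restricted_loglik",
    "fit_em_reml",
    "lrt_mito",
    "prioritize_phenotypes",
]

#: variance floor, as a fraction of var(y)
FLOOR_FRACTION = 1e-6


@dataclass
class MixedModelSpec:
    """Aligned phenotype, fixed-effect design, and GRM list for one trait.

    ``grms`` entries may be :class:`RelationshipMatrix` or plain arrays;
    ``names`` labels the genetic components (residual is always last and
    implicit). All rows must refer to the same complete-case sample set.
    """

    y: np.ndarray
    X: np.ndarray
    grms: list
    names: list[str] = field(default_factory=list)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effects design X is rank-deficient")
        mats = []
        for a in self.grms:
            m = a.values if isinstance(a, RelationshipMatrix) else np.asarray(a, float)
            if m.shape != (n, n):
                raise ValueError("GRM shape does not match the sample set")
            mats.append(m)
        self.grms = mats
        if not self.names:
            self.names = [f"G{i + 1}" for i in range(len(mats))]

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class VarianceComponentFit:
    """REML estimates for one trait.

    ``sigma2`` holds the genetic components in spec order followed by the
    residual; ``pve`` covers the genetic components only, with
    ``Vp = sum(sigma2)`` as the denominator. ``loglik_trace`` records the
    restricted log-likelihood at every accepted iterate (non-decreasing).
    """

    sigma2: np.ndarray
    se_sigma2: np.ndarray
    pve: np.ndarray
    se_pve: np.ndarray
    logL: float
    n_iter: int
    converged: bool
    n: int
    names: list[str]
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_hsq(self) -> pd.DataFrame:
        """GCTA ``.hsq``-style summary table (Source / Variance / SE)."""
        rows = []
        vp = float(self.sigma2.sum())
        for i, name in enumerate(self.names):
            rows.append((f"V({name})", self.sigma2[i], self.se_sigma2[i]))
        rows.append(("V(e)", self.sigma2[-1], self.se_sigma2[-1]))
        rows.append(("Vp", vp, np.nan))
        for i, name in enumerate(self.names):
            rows.append((f"V({name})/Vp", self.pve[i], self.se_pve[i]))
        rows.append(("logL", self.logL, np.nan))
        rows.append(("n", float(self.n), np.nan))
        return pd.DataFrame(rows, columns=["Source", "Variance", "SE"])


@dataclass
class LRTResult:
    """Boundary likelihood-ratio test of the mitochondrial component."""

    statistic: float
    p_mixture: float   # 0.5*chi2_0 + 0.5*chi2_1 null (primary)
    p_chi2_1: float    # plain chi2_1 null (reported alongside)
    convention: str = "0.5*chi2_0 + 0.5*chi2_1"


# ---------------------------------------------------------------------------
# REML work kernels
# ---------------------------------------------------------------------------

def _inv_psd(v: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Inverse, log-determinant and Cholesky factor of an SPD matrix."""
    c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    inv = linalg.lapack.dpotri(c, lower=True)[0]
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv, logdet, c


class _DenseWork:
    """General REML algebra via explicit V inverse (any number of GRMs)."""

    def __init__(self, spec: MixedModelSpec):
        self.spec = spec
        self.n = spec.n

    def _v(self, sigma2: np.ndarray) -> np.ndarray:
        v = sigma2[-1] * np.eye(self.n)
        for s, a in zip(sigma2[:-1], self.spec.grms):
            v += s * a
        return v

    def ll_only(self, sigma2: np.ndarray) -> float:
        spec = self.spec
        v = self._v(sigma2)
        try:
            c, low = linalg.cho_factor(v, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                f"V not positive definite (cond {np.linalg.cond(v):.3e})") from exc
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        rhs = np.column_stack([spec.X, spec.y])
        sol = linalg.cho_solve((c, low), rhs, check_finite=False)
        vix, viy = sol[:, :-1], sol[:, -1]
        xtvix = spec.X.T @ vix
        cxx = linalg.cho_factor(xtvix, check_finite=False)
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cxx[0]))))
        beta = linalg.cho_solve(cxx, spec.X.T @ viy, check_finite=False)
        ypy = float(spec.y @ viy - (spec.X.T @ viy) @ beta)
        return -0.5 * (logdet_v + logdet_x + ypy)

    def full_eval(self, sigma2: np.ndarray):
        """Returns (ll, quads, traces, Py, apply_P)."""
        spec = self.spec
        v = self._v(sigma2)
        try:
            vi, logdet_v, _ = _inv_psd(v)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                f"V not positive definite (cond {np.linalg.cond(v):.3e})") from exc
        vix = vi @ spec.X
        xtvix = spec.X.T @ vix
        try:
            cxx = linalg.cho_factor(xtvix, check_finite=False)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                f"X'V^-1X singular (cond {np.linalg.cond(xtvix):.3e})") from exc
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cxx[0]))))
        p = vi - vix @ linalg.cho_solve(cxx, vix.T, check_finite=False)
        py = p @ spec.y
        ll = -0.5 * (logdet_v + logdet_x + float(spec.y @ py))
        quads, traces = [], []
        for a in spec.grms:
            quads.append(float(py @ (a @ py)))
            traces.append(float(np.sum(a * p)))
        quads.append(float(py @ py))
        traces.append(float(np.trace(p)))
        return ll, np.array(quads), np.array(traces), py, (lambda vec: p @ vec)


class _EigenWork:
    """Eigenbasis REML algebra for models with at most one GRM.

    With ``A = U diag(d) U'`` everything is rotated once; V is diagonal in
    that basis and each evaluation costs O(n p^2).
    """

    def __init__(self, spec: MixedModelSpec):
        self.spec = spec
        self.n = spec.n
        if len(spec.grms) == 1:
            d, u = np.linalg.eigh(spec.grms[0])
            self.d = d
            self.y = u.T @ spec.y
            self.x = u.T @ spec.X
        else:  # GRM-free: V already diagonal
            self.d = np.zeros(self.n)
            self.y = spec.y.copy()
            self.x = spec.X.copy()

    def _pieces(self, sigma2: np.ndarray):
        dv = (sigma2[0] * self.d + sigma2[-1]) if sigma2.size == 2 \
            else np.full(self.n, sigma2[-1])
        if dv.min() <= 0:
            raise linalg.LinAlgError("V not positive definite in eigenbasis")
        w = self.x / dv[:, None]
        xtvix = self.x.T @ w
        cxx = linalg.cho_factor(xtvix, check_finite=False)
        viy = self.y / dv
        beta = linalg.cho_solve(cxx, self.x.T @ viy, check_finite=False)
        py = viy - w @ beta
        logdet_v = float(np.sum(np.log(dv)))
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cxx[0]))))
        ll = -0.5 * (logdet_v + logdet_x + float(self.y @ py))
        return dv, w, cxx, py, ll

    def ll_only(self, sigma2: np.ndarray) -> float:
        return self._pieces(sigma2)[4]

    def full_eval(self, sigma2: np.ndarray):
        dv, w, cxx, py, ll = self._pieces(sigma2)
        quads, traces = [], []
        if sigma2.size == 2:
            quads.append(float(py @ (self.d * py)))
            m = linalg.cho_solve(cxx, w.T @ (self.d[:, None] * w), check_finite=False)
            traces.append(float(np.sum(self.d / dv) - np.trace(m)))
        quads.append(float(py @ py))
        m = linalg.cho_solve(cxx, w.T @ w, check_finite=False)
        traces.append(float(np.sum(1.0 / dv) - np.trace(m)))

        def apply_p(vec: np.ndarray) -> np.ndarray:
            return vec / dv - w @ linalg.cho_solve(cxx, w.T @ (vec / dv),
                                                   check_finite=False)

        return ll, np.array(quads), np.array(traces), py, apply_p

    def rotate_grms(self):
        """GRMs expressed in the eigenbasis (diagonal for the single GRM)."""
        if len(self.spec.grms) == 1:
            return [np.diag(self.d)]
        return []


def _make_work(spec: MixedModelSpec):
    return _EigenWork(spec) if len(spec.grms) <= 1 else _DenseWork(spec)


# ---------------------------------------------------------------------------
# Restricted likelihood (public)
# ---------------------------------------------------------------------------

def restricted_loglik(spec: MixedModelSpec, sigma2) -> float:
    """Restricted log-likelihood at the given variance components.

    ``sigma2`` lists the genetic components in spec order, residual last.
    The additive constant is dropped (see module docstring), so only
    differences between nested fits are meaningful across conventions.
    """
    sigma2 = np.asarray(sigma2, dtype=float).ravel()
    if sigma2.size != len(spec.grms) + 1:
        raise ValueError("need one variance per GRM plus the residual")
    return _DenseWork(spec).ll_only(sigma2)


# ---------------------------------------------------------------------------
# EM-REML with SQUAREM acceleration
# ---------------------------------------------------------------------------

def _em_update(sigma2: np.ndarray, quads: np.ndarray, traces: np.ndarray,
               n: int, floor: float) -> np.ndarray:
    new = sigma2 + sigma2 ** 2 / n * (quads - traces)
    if np.any(~np.isfinite(new)):
        raise FloatingPointError("NaN in EM variance update")
    return np.maximum(new, floor)


def fit_em_reml(spec: MixedModelSpec, tol: float = 1e-6,
                max_iter: int = 200) -> VarianceComponentFit:
    """Fit the variance components by (accelerated) EM-REML.

    Starts from an equal split of the phenotypic variance across all
    components and iterates EM-step pairs with SQUAREM extrapolation until
    the restricted log-likelihood changes by less than ``tol`` between
    accepted iterates (or the EM-step budget ``max_iter`` is spent, in
    which case the result is returned flagged unconverged). Components are
    floored at ``1e-6 * var(y)``.
    """
    n = spec.n
    n_comp = len(spec.grms) + 1
    vary = float(np.var(spec.y, ddof=1))
    floor = FLOOR_FRACTION * vary
    work = _make_work(spec)

    s0 = np.full(n_comp, vary / n_comp)
    trace = []
    converged = False
    n_em = 0
    final_eval = None
    while n_em < max_iter:
        ll0, q0, t0, py, apply_p = work.full_eval(s0)
        final_eval = (py, apply_p)
        if trace and abs(ll0 - trace[-1]) < tol:
            trace.append(ll0)
            converged = True
            break
        trace.append(ll0)
        s1 = _em_update(s0, q0, t0, n, floor)
        n_em += 1
        if n_em >= max_iter:
            s0 = s1
            break
        ll1, q1, t1, _, _ = work.full_eval(s1)
        s2 = _em_update(s1, q1, t1, n, floor)
        n_em += 1
        # SQUAREM extrapolation through the two EM steps, accepted only if
        # it does not lower the likelihood already reached at s1
        r = s1 - s0
        v = s2 - s1 - r
        nv = float(np.linalg.norm(v))
        if nv < 1e-300:
            s0 = s2
            continue
        alpha = min(-1.0, -float(np.linalg.norm(r)) / nv)
        cand = np.maximum(s0 - 2.0 * alpha * r + alpha * alpha * v, floor)
        try:
            ll_cand = work.ll_only(cand)
        except linalg.LinAlgError:
            ll_cand = -np.inf
        s0 = cand if ll_cand >= ll1 else s2

    if not converged:
        ll0, q0, t0, py, apply_p = work.full_eval(s0)
        trace.append(ll0)
        final_eval = (py, apply_p)
    sigma2 = s0
    ll = trace[-1]

    py, apply_p = final_eval
    grms = work.rotate_grms() if isinstance(work, _EigenWork) else spec.grms
    cov = _ai_cov(grms, py, apply_p)
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.nan
    se = np.sqrt(diag)
    pve, se_pve = _pve_delta(sigma2, cov)
    return VarianceComponentFit(
        sigma2=sigma2, se_sigma2=se, pve=pve, se_pve=se_pve,
        logL=float(ll), n_iter=n_em, converged=converged, n=n,
        names=list(spec.names), loglik_trace=np.asarray(trace))


def _ai_cov(grms: list, py: np.ndarray, apply_p) -> np.ndarray:
    """Inverse average-information matrix: AI_ij = 0.5 y'P A_i P A_j P y."""
    n_comp = len(grms) + 1
    a_py = [a @ py for a in grms] + [py]
    p_a_py = [apply_p(v) for v in a_py]
    ai = np.empty((n_comp, n_comp))
    for i in range(n_comp):
        for j in range(i, n_comp):
            ai[i, j] = ai[j, i] = 0.5 * float(a_py[i] @ p_a_py[j])
    try:
        return np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(ai)


def _pve_delta(sigma2: np.ndarray, cov: np.ndarray):
    """PVE_i = sigma2_i / sum(sigma2), SE by the delta method."""
    total = float(sigma2.sum())
    n_gen = sigma2.size - 1
    pve = sigma2[:n_gen] / total
    se = np.empty(n_gen)
    for i in range(n_gen):
        g = -sigma2[i] / total ** 2 * np.ones(sigma2.size)
        g[i] += 1.0 / total
        var = float(g @ cov @ g)
        se[i] = np.sqrt(var) if var >= 0 else np.nan
    return pve, se


# ---------------------------------------------------------------------------
# Likelihood-ratio test and prioritization
# ---------------------------------------------------------------------------

def lrt_mito(full: VarianceComponentFit, reduced: VarianceComponentFit) -> LRTResult:
    """LRT of the mitochondrial component: full (nuc+mt) vs reduced (nuc).

    The statistic ``2 * (logL_full - logL_reduced)`` is clipped at zero
    (tolerance-level noise can make it marginally negative). The primary
    p-value uses the boundary mixture ``0.5*chi2_0 + 0.5*chi2_1``; at a
    statistic of exactly 0 this gives p = 0.5.
    """
    if full.n != reduced.n:
        raise ValueError(
            f"full and reduced fits use different sample sets ({full.n} vs {reduced.n})")
    stat = max(0.0, 2.0 * (full.logL - reduced.logL))
    p_mix = 0.5 * float(chi2.sf(stat, df=1))
    p_plain = float(chi2.sf(stat, df=1))
    return LRTResult(statistic=stat, p_mixture=p_mix, p_chi2_1=p_plain)


def prioritize_phenotypes(lrt_by_trait: dict[str, LRTResult],
                          alpha: float = 0.05,
                          suggestive: float = 0.055) -> pd.DataFrame:
    """Rank traits by mitochondrial LRT p-value and flag the prioritized set.

    Traits with p <= ``alpha`` are prioritized; traits above ``alpha`` but
    with p <= ``suggestive`` are flagged suggestive. Ties sort by trait
    name for determinism.
    """
    rows = []
    for t, r in lrt_by_trait.items():
        if isinstance(r, LRTResult):
            rows.append({"trait": t, "lrt_statistic": r.statistic,
                         "p_mixture": r.p_mixture, "p_chi2_1": r.p_chi2_1})
        else:  # bare p-value
            rows.append({"trait": t, "lrt_statistic": np.nan,
                         "p_mixture": float(r), "p_chi2_1": np.nan})
    df = pd.DataFrame(rows).sort_values(
        ["p_mixture", "trait"], kind="mergesort").reset_index(drop=True)
    df["prioritized"] = df["p_mixture"] <= alpha
    df["suggestive"] = (~df["prioritized"]) & (df["p_mixture"] <= suggestive)
    return df
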