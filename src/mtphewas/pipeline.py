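"""Two-stage mt-PheWAS orchestration.

Stage 1 (polygenic prioritization): for every trait, fit the mixed model
with nuclear + mitochondrial GRMs and with the nuclear GRM alone, and rank
traits by the boundary LRT on the mitochondrial component.

Stage 2 (single-mtSNP scan): MAF-filter the mitochondrial panel and run
covariate-adjusted per-SNP regressions for every trait, then compare
per-trait significant counts with the m x alpha chance expectation and
with the per-trait mitochondrial PVE.

The scan deliberately covers *all* traits, not only the prioritized ones,
so the PVE-versus-count correlation that validates the prioritization is
always reproducible; ``prioritized_only=True`` restricts it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype import GenotypeMatrix, read_plink, split_genomes, filter_maf
from .grm import nuclear_grm, mito_grm, compute_pcs
from .reml import MixedModelSpec, fit_em_reml, lrt_mito, prioritize_phenotypes
from .assoc import run_mt_scan, expected_false_positives, summarize_counts

__all__ = ["RunConfig", "PhewasReport", "run_phewas", "run_pipeline", "render_summary"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-based pipeline configuration (CLI surface)."""

    plink_prefix: str
    phenotype_path: str
    traits: dict[str, str]                 # name -> "continuous" | "binary"
    covariates: tuple[str, ...] = ("age", "sex")
    maf_threshold: float = 0.01
    alpha_priority: float = 0.05
    alpha_suggestive: float = 0.055
    alpha_snp: float = 0.05
    n_pcs: int = 2
    reml_tol: float = 1e-6
    reml_max_iter: int = 200
    out_dir: str = "mtphewas_out"
    seed: int = 0
    prioritized_only: bool = False

    def __post_init__(self) -> None:
        for a in (self.maf_threshold, self.alpha_priority, self.alpha_snp):
            if not 0.0 < a < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if not self.traits:
            raise ValueError("at least one trait must be declared")
        bad = set(self.traits.values()) - {"continuous", "binary"}
        if bad:
            raise ValueError(f"unknown trait type(s): {sorted(bad)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


@dataclass
class PhewasReport:
    """All stage outputs of one run, individually serializable."""

    lrt: pd.DataFrame                     # per-trait PVE, LRT stat, both p-values
    fits: dict                            # trait -> (full, reduced) VarianceComponentFit
    assoc: pd.DataFrame                   # per (trait, SNP) association rows
    summary: pd.DataFrame                 # merged per-trait report table
    m_snps_tested: int
    expected_by_chance: float
    spearman_rho: float
    config_hash: str = ""
    seed: int = 0


def run_phewas(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
               traits: dict[str, str],
               covariates: tuple[str, ...] = ("age", "sex"),
               maf_threshold: float = 0.01,
               alpha_priority: float = 0.05,
               alpha_suggestive: float = 0.055,
               alpha_snp: float = 0.05,
               n_pcs: int = 2,
               reml_tol: float = 1e-6,
               reml_max_iter: int = 200,
               prioritized_only: bool = False) -> PhewasReport:
    """Run the full two-stage analysis in memory.

    ``phenotypes`` is indexed by sample_id with trait and covariate columns
    (missing values NaN). Nuclear PCs are computed here and appended to the
    fixed effects of both stages. Per-trait failures are logged and
    skipped; they never abort the run.
    """
    t0 = time.time()
    g_nuc, g_mt = split_genomes(genotypes)
    log.info("split: %d nuclear / %d mito SNPs, %d samples",
             g_nuc.n_snps, g_mt.n_snps, genotypes.n_samples)

    pcs = compute_pcs(g_nuc, k=n_pcs)
    pc_df = pd.DataFrame(pcs.scores, index=pcs.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(n_pcs)])
    ph = phenotypes.join(pc_df, how="inner")
    covs = tuple(covariates) + tuple(pc_df.columns)

    a_nuc = nuclear_grm(g_nuc)
    a_mt = mito_grm(g_mt)
    log.info("GRMs built in %.1fs", time.time() - t0)

    lrt_rows, lrt_by_trait, fits = [], {}, {}
    for trait, kind in traits.items():
        cols = [trait, *covs]
        sub = ph[cols].dropna()
        ids = list(sub.index)
        if len(ids) < len(covs) + 2:
            log.warning("trait %s: too few complete cases (%d); skipped", trait, len(ids))
            continue
        y = sub[trait].to_numpy(dtype=float)
        x = np.column_stack([np.ones(len(ids)), sub[list(covs)].to_numpy(dtype=float)])
        an = a_nuc.align(ids).values
        am = a_mt.align(ids).values
        try:
            full = fit_em_reml(MixedModelSpec(y, x, [an, am], names=["nuc", "mt"]),
                               tol=reml_tol, max_iter=reml_max_iter)
            red = fit_em_reml(MixedModelSpec(y, x, [an], names=["nuc"]),
                              tol=reml_tol, max_iter=reml_max_iter)
            res = lrt_mito(full, red)
        except Exception:
            log.exception("trait %s: REML stage failed; skipped", trait)
            continue
        fits[trait] = (full, red)
        lrt_by_trait[trait] = res
        lrt_rows.append({
            "trait": trait, "type": kind, "n": full.n,
            "pve_nuc": full.pve[0], "se_pve_nuc": full.se_pve[0],
            "pve_mt": full.pve[1], "se_pve_mt": full.se_pve[1],
            "logL_full": full.logL, "logL_reduced": red.logL,
            "lrt_statistic": res.statistic,
            "p_mixture": res.p_mixture, "p_chi2_1": res.p_chi2_1,
            "converged": full.converged and red.converged,
        })
        log.info("trait %s: n=%d pve_mt=%.4f LRT p=%.3g (%.1fs elapsed)",
                 trait, full.n, full.pve[1], res.p_mixture, time.time() - t0)
    lrt = pd.DataFrame(lrt_rows)
    priority = prioritize_phenotypes(lrt_by_trait, alpha=alpha_priority,
                                     suggestive=alpha_suggestive)

    scan_traits = dict(traits)
    if prioritized_only:
        keep = set(priority.loc[priority["prioritized"], "trait"])
        scan_traits = {t: k for t, k in scan_traits.items() if t in keep}

    g_mt_f = filter_maf(g_mt, maf_threshold)
    log.info("MAF filter at %.3f: %d -> %d mito SNPs",
             maf_threshold, g_mt.n_snps, g_mt_f.n_snps)
    assoc = run_mt_scan(g_mt_f, ph, scan_traits, covariates=covs)

    pve_map = dict(zip(lrt["trait"], lrt["pve_mt"])) if len(lrt) else {}
    counts = summarize_counts(assoc, alpha=alpha_snp, pve_per_trait=pve_map) \
        if len(assoc) else None
    expected = expected_false_positives(g_mt_f.n_snps, alpha_snp)

    summary = lrt.merge(priority[["trait", "prioritized", "suggestive"]],
                        on="trait", how="left")
    if counts is not None:
        summary = summary.merge(counts.counts[["trait", "n_significant",
                                               "expected_by_chance", "exceeds_chance"]],
                                on="trait", how="left")
    summary = summary.sort_values("p_mixture", kind="mergesort").reset_index(drop=True)
    log.info("pipeline finished in %.1fs", time.time() - t0)

    return PhewasReport(
        lrt=lrt, fits=fits, assoc=assoc, summary=summary,
        m_snps_tested=g_mt_f.n_snps, expected_by_chance=expected,
        spearman_rho=counts.spearman_rho if counts is not None else float("nan"),
    )


def run_pipeline(cfg: RunConfig) -> PhewasReport:
    """File-based entry point: read inputs, run, write the report bundle.

    Outputs under ``cfg.out_dir``: ``lrt.tsv``, ``assoc_<trait>.tsv``,
    ``summary.tsv`` and ``run_info.json`` (config hash + seed tag).
    """
    genotypes = read_plink(cfg.plink_prefix)
    phenotypes = pd.read_csv(cfg.phenotype_path, sep="\t", index_col="sample_id",
                             na_values="NA")
    phenotypes.index = phenotypes.index.astype(str)
    report = run_phewas(
        genotypes, phenotypes, cfg.traits, covariates=cfg.covariates,
        maf_threshold=cfg.maf_threshold, alpha_priority=cfg.alpha_priority,
        alpha_suggestive=cfg.alpha_suggestive, alpha_snp=cfg.alpha_snp,
        n_pcs=cfg.n_pcs, reml_tol=cfg.reml_tol, reml_max_iter=cfg.reml_max_iter,
        prioritized_only=cfg.prioritized_only)
    report.config_hash = cfg.config_hash()
    report.seed = cfg.seed

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.lrt.to_csv(out / "lrt.tsv", sep="\t", index=False, float_format="%.10g")
    for trait in report.assoc["trait"].unique() if len(report.assoc) else []:
        sub = report.assoc[report.assoc["trait"] == trait]
        _write_assoc_tsv(sub, out / f"assoc_{trait}.tsv")
    report.summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                          float_format="%.10g")
    (out / "run_info.json").write_text(json.dumps(
        {"config_hash": report.config_hash, "seed": cfg.seed,
         "m_snps_tested": report.m_snps_tested,
         "expected_by_chance": report.expected_by_chance}, indent=2))
    return report


def _write_assoc_tsv(sub: pd.DataFrame, path: Path) -> None:
    """PLINK .assoc-compatible column ordering."""
    out = pd.DataFrame({
        "CHR": sub["chrom"], "SNP": sub["snp_id"], "BP": sub["pos"],
        "A1": sub["a1"], "TEST": "ADD", "NMISS": sub["n"],
        "EFFECT": sub["effect"], "SE": sub["se"],
        "STAT": sub["statistic"], "P": sub["p_value"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def render_summary(report: PhewasReport, plot_path: str | None = None) -> str:
    """Human-readable per-trait report; optional PVE-vs-count plot.

    One line per trait: mito PVE with SE, both LRT p-values, the
    significant-SNP count against the m x alpha chance line, and the
    prioritization flag.
    """
    lines = [
        f"mt-PheWAS summary — {report.m_snps_tested} mtSNPs tested, "
        f"{report.expected_by_chance:.1f} associations expected by chance",
        f"{'trait':<20}{'mito PVE':>10}{'SE':>9}{'p(mix)':>9}{'p(chi2)':>9}"
        f"{'n sig':>7}{'flag':>12}",
    ]
    for _, r in report.summary.iterrows():
        flag = "prioritized" if r.get("prioritized") else (
            "suggestive" if r.get("suggestive") else "")
        nsig = r.get("n_significant")
        lines.append(
            f"{r['trait']:<20}{r['pve_mt']:>10.4f}{r['se_pve_mt']:>9.4f}"
            f"{r['p_mixture']:>9.3g}{r['p_chi2_1']:>9.3g}"
            f"{(int(nsig) if pd.notna(nsig) else 0):>7d}{flag:>12}")
    if np.isfinite(report.spearman_rho):
        lines.append(f"Spearman rho (mito PVE vs significant count): "
                     f"{report.spearman_rho:.3f}")
    text = "\n".join(lines)
    if plot_path is not None:
        _plot_pve_counts(report, plot_path)
    return text


def _plot_pve_counts(report: PhewasReport, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.summary
    fig, ax1 = plt.subplots(figsize=(7, 4))
    x = np.arange(len(df))
    ax1.bar(x, df["pve_mt"], yerr=df["se_pve_mt"], color="steelblue", alpha=0.8)
    ax1.set_ylabel("mitochondrial PVE")
    ax1.set_xticks(x, df["trait"], rotation=45, ha="right")
    ax2 = ax1.twinx()
    ax2.plot(x, df["n_significant"], "ko")
    ax2.axhline(report.expected_by_chance, ls="--", color="gray")
    ax2.set_ylabel("significant mtSNPs (p < alpha)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
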