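"""Genetic relationship matrices and principal components.

Two GRM flavours are built here:

* **nuclear-additive** — the standard GCTA-style additive GRM on diploid
  dosages: ``A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``
  with ``p_i`` the sample A1 frequency. Missing calls are mean-imputed to
  ``2 p_i`` (zero after centering).

* **mito-sharing** — the mitochondrial genome is haploid, so relatedness is
  the allelic-sharing (identity-by-state) fraction: for samples j, k,
  ``S_jk`` is the fraction of jointly observed haploid sites at which the
  two carry the same allele. Without missingness this equals
  ``(X X' + (1-X)(1-X)') / m`` for 0/1 coding, hence is positive
  semidefinite with unit diagonal.

An optional standardized-haploid variant of the mito GRM
(``(x - p)/sqrt(p(1-p))`` cross-products) is available for sensitivity
analysis via ``mito_grm(..., standardized=True)``.

Principal components follow the Eigenstrat recipe: column-standardized
genotypes (center ``2p``, scale ``sqrt(2p(1-p))``, missing -> 0 after
centering), then eigenvectors of the sample-by-sample covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, allele_frequencies, warn_monomorphic

__all__ = [
    "RelationshipMatrix",
    "PCMatrix",
    "nuclear_grm",
    "mito_grm",
    "compute_pcs",
    "write_gcta_grm",
    "read_gcta_grm",
    "write_grm_text",
    "read_grm_text",
]


@dataclass
class RelationshipMatrix:
    """Symmetric n x n relatedness matrix with provenance."""

    values: np.ndarray
    sample_ids: list[str]
    n_snps: int
    kind: str  # "nuclear-additive" | "mito-sharing"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def align(self, sample_ids: list[str]) -> "RelationshipMatrix":
        """Reorder/subset to the given sample IDs (all must be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids])
        return RelationshipMatrix(self.values[np.ix_(idx, idx)],
                                  list(sample_ids), self.n_snps, self.kind)


@dataclass
class PCMatrix:
    """Per-sample principal-component scores with eigenvalues."""

    scores: np.ndarray       # (n, k), unit-norm eigenvector columns
    eigenvalues: np.ndarray  # (k,), non-increasing
    sample_ids: list[str]


def _standardize_diploid(g: GenotypeMatrix) -> tuple[np.ndarray, int]:
    """Column-standardize diploid calls; returns (Z, m) with missing -> 0."""
    if (g.ploidy != 2).any():
        raise ValueError("diploid SNPs only")
    keep = warn_monomorphic(g)
    if keep.size == 0:
        raise ValueError("no polymorphic SNPs left to build the GRM from")
    x = g.calls[:, keep]
    p = np.nanmean(x, axis=0) / 2.0
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z[np.isnan(z)] = 0.0
    return z, keep.size


def nuclear_grm(g_nuc: GenotypeMatrix) -> RelationshipMatrix:
    """Additive GRM from diploid SNPs (monomorphic sites dropped with a warning)."""
    z, m = _standardize_diploid(g_nuc)
    a = (z @ z.T) / m
    return RelationshipMatrix(a, list(g_nuc.sample_ids), m, "nuclear-additive")


def mito_grm(g_mt: GenotypeMatrix, standardized: bool = False) -> RelationshipMatrix:
    """Allelic-sharing GRM from haploid SNPs.

    Entries are mean IBS over sites non-missing in *both* members of a pair
    (pairwise-complete denominators). A pair with no jointly observed site
    raises, naming the pair. With ``standardized=True`` the sensitivity
    variant ``(1/m) sum (x-p)(x'-p)/(p(1-p))`` is returned instead.
    """
    if (g_mt.ploidy != 1).any():
        raise ValueError("haploid SNPs only")
    if g_mt.n_snps == 0:
        raise ValueError("no haploid SNPs to build the sharing matrix from")
    if standardized:
        keep = warn_monomorphic(g_mt)
        x = g_mt.calls[:, keep]
        p = np.nanmean(x, axis=0)
        z = (x - p) / np.sqrt(p * (1.0 - p))
        z[np.isnan(z)] = 0.0
        s = (z @ z.T) / keep.size
        return RelationshipMatrix(s, list(g_mt.sample_ids), keep.size, "mito-sharing")

    x = g_mt.calls
    obs = (~np.isnan(x)).astype(float)
    x1 = np.nan_to_num(x)           # allele-1 indicator, 0 where missing
    x0 = obs - x1                   # allele-0 indicator
    agree = x1 @ x1.T + x0 @ x0.T
    counts = obs @ obs.T
    if (counts == 0).any():
        j, k = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"samples {g_mt.sample_ids[j]!r} and {g_mt.sample_ids[k]!r} share "
            "no jointly observed mitochondrial site")
    s = agree / counts
    s = (s + s.T) / 2.0
    return RelationshipMatrix(s, list(g_mt.sample_ids), g_mt.n_snps, "mito-sharing")


def compute_pcs(g_nuc: GenotypeMatrix, k: int = 2) -> PCMatrix:
    """Top-k principal components of standardized nuclear genotypes.

    Scores are the unit-norm eigenvectors of ``Z Z' / m`` sorted by
    eigenvalue descending; each column is signed so its largest-magnitude
    entry is positive.
    """
    n = g_nuc.n_samples
    if not 1 <= k < n:
        raise ValueError("require 1 <= k < n_samples")
    z, m = _standardize_diploid(g_nuc)
    cov = (z @ z.T) / m
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:k]
    scores = v[:, order]
    eigvals = w[order]
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return PCMatrix(scores, eigvals, list(g_nuc.sample_ids))


# ---------------------------------------------------------------------------
# GCTA binary GRM dialect
# ---------------------------------------------------------------------------

def write_gcta_grm(grm: RelationshipMatrix, prefix: str | Path,
                   pair_counts: np.ndarray | None = None) -> None:
    """Write ``<prefix>.grm.bin`` / ``.grm.N.bin`` / ``.grm.id``.

    Lower triangle (including diagonal), row-major, 4-byte little-endian
    floats; ``.grm.N.bin`` holds per-pair SNP counts (constant ``n_snps``
    unless ``pair_counts`` is given); ``.grm.id`` is two-column text.
    """
    prefix = Path(prefix)
    n = grm.n
    tri = np.tril_indices(n)
    vals = grm.values[tri].astype("<f4")
    Path(f"{prefix}.grm.bin").write_bytes(vals.tobytes())
    if pair_counts is None:
        counts = np.full(tri[0].size, grm.n_snps, dtype="<f4")
    else:
        counts = np.asarray(pair_counts, dtype=float)[tri].astype("<f4")
    Path(f"{prefix}.grm.N.bin").write_bytes(counts.tobytes())
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in grm.sample_ids:
            fh.write(f"{s}\t{s}\n")


def write_grm_text(grm: RelationshipMatrix, path: str | Path) -> None:
    """Plain-text alternative: square matrix as TSV with sample-ID header/index."""
    pd.DataFrame(grm.values, index=grm.sample_ids,
                 columns=grm.sample_ids).to_csv(path, sep="\t",
                                                float_format="%.10g")


def read_grm_text(path: str | Path, kind: str = "nuclear-additive",
                  n_snps: int = 0) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.to_numpy(), [str(s) for s in df.index],
                              n_snps, kind)


def read_gcta_grm(prefix: str | Path, kind: str = "nuclear-additive") -> RelationshipMatrix:
    """Read a GCTA binary GRM triplet back into a :class:`RelationshipMatrix`."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None,
                      dtype=str)[1].tolist()
    n = len(ids)
    vals = np.frombuffer(Path(f"{prefix}.grm.bin").read_bytes(), dtype="<f4")
    if vals.size != n * (n + 1) // 2:
        raise ValueError("GRM binary size does not match the ID list")
    a = np.zeros((n, n))
    tri = np.tril_indices(n)
    a[tri] = vals
    a = a + np.tril(a, -1).T
    counts = np.frombuffer(Path(f"{prefix}.grm.N.bin").read_bytes(), dtype="<f4")
    m = int(round(float(counts.max()))) if counts.size else 0
    return RelationshipMatrix(a, ids, m, kind)
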