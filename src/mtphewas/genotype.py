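"""Genotype container and PLINK binary (bed/bim/fam) input/output.

Calls are stored as counts of the A1 allele: diploid sites take values in
{0, 1, 2}, haploid (mitochondrial) sites in {0, 1}; missing calls are NaN.
Mitochondrial variants are recognised by chromosome code ("26", "M" or
"MT", case-insensitive) and carry ploidy 1. Any heterozygous-coded call at
a haploid site is treated as missing — array heterozygote calls on mtDNA
usually reflect heteroplasmy or clustering artefacts, neither of which a
haploid dosage can represent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "allele_frequencies",
    "filter_maf",
    "split_genomes",
]

#: chromosome codes understood as mitochondrial, upper-cased
MT_CODES = {"26", "M", "MT", "CHRM", "CHRMT"}

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK code -> A1 dosage (diploid): 00=hom A1, 01=missing, 10=het, 11=hom A2
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised for malformed PLINK binary files (bad magic, truncation)."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype store with per-SNP ploidy and metadata.

    Attributes
    ----------
    calls : (n_samples, n_snps) float array of A1-allele counts, NaN missing.
    sample_ids : length-n list of unique sample identifiers.
    snp_ids : length-m list of unique variant labels (mito: ``mt<pos>``).
    chrom : length-m array of chromosome codes (strings).
    pos : length-m int array of 1-based base-pair positions.
    a1, a2 : length-m allele label arrays.
    ploidy : length-m int array, 1 for mitochondrial sites else 2.
    """

    calls: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    ploidy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.a1 = np.asarray(self.a1, dtype=object)
        self.a2 = np.asarray(self.a2, dtype=object)
        if self.ploidy is None:
            self.ploidy = np.where(self._is_mt(), 1, 2)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int64)
        self._validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def _is_mt(self) -> np.ndarray:
        return np.array([str(c).upper() in MT_CODES for c in self.chrom])

    def _validate(self) -> None:
        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match calls rows")
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos)
                == len(self.a1) == len(self.a2) == len(self.ploidy) == m):
            raise ValueError("per-SNP metadata lengths do not match calls columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids are not unique")
        dip = self.ploidy == 2
        with np.errstate(invalid="ignore"):
            bad_dip = dip & np.any(~np.isnan(self.calls) & ~np.isin(self.calls, (0, 1, 2)), axis=0)
            hap = ~dip
            bad_hap = hap & np.any(~np.isnan(self.calls) & ~np.isin(self.calls, (0, 1)), axis=0)
        if bad_dip.any() or bad_hap.any():
            raise ValueError("calls outside the allowed dosage range for their ploidy")

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNPs (order given by ``index``), sharing no state."""
        idx = np.asarray(index)
        return GenotypeMatrix(
            calls=self.calls[:, idx].copy(),
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in np.atleast_1d(idx)],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            a1=self.a1[idx],
            a2=self.a2[idx],
            ploidy=self.ploidy[idx],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(
            calls=self.calls[idx, :].copy(),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
            snp_ids=list(self.snp_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            a1=self.a1.copy(),
            a2=self.a2.copy(),
            ploidy=self.ploidy.copy(),
        )


# ---------------------------------------------------------------------------
# PLINK binary codec (v1.0 SNP-major)
# ---------------------------------------------------------------------------

def read_plink(prefix_or_bed: str | Path,
               bim_path: str | Path | None = None,
               fam_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triplet into a :class:`GenotypeMatrix`.

    ``prefix_or_bed`` may be a fileset prefix (``data`` for ``data.bed`` ...)
    or the explicit ``.bed`` path together with ``bim_path``/``fam_path``.

    The bed payload is decoded per the v1.0 SNP-major 2-bit encoding
    (00 -> 2 copies of A1, 01 -> missing, 10 -> 1, 11 -> 0). Sites on the
    mitochondrial chromosome are stored haploid: homozygous codes map to
    dosage 1/0 and heterozygous codes become missing.
    """
    p = Path(prefix_or_bed)
    if bim_path is None:
        bed = p.with_suffix(".bed") if p.suffix != ".bed" else p
        bim = bed.with_suffix(".bim")
        fam = bed.with_suffix(".fam")
    else:
        bed, bim, fam = p, Path(bim_path), Path(fam_path)

    bim_df = pd.read_csv(bim, sep=r"\s+", header=None,
                         names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                         dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str})
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None,
                         names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                         dtype={"fid": str, "iid": str})
    n, m = len(fam_df), len(bim_df)

    raw = Path(bed).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes {raw[:2]!r}")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed}: only SNP-major mode (0x01) is supported")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + m * bytes_per_snp
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed}: payload is {len(raw) - 3} bytes, expected {expected - 3} "
            f"for {n} samples x {m} variants")

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample i sits at bits (2*(i%4)) of byte i//4
    codes = (data[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 0x03
    codes = codes.reshape(m, -1)[:, :n]          # (m, n)
    calls = _DECODE[codes].T.copy()              # (n, m) dosages

    is_mt = bim_df["chrom"].str.upper().isin(MT_CODES).to_numpy()
    if is_mt.any():
        hap = calls[:, is_mt]
        hap[hap == 1] = np.nan      # het-coded call at haploid site -> missing
        hap[hap == 2] = 1.0
        calls[:, is_mt] = hap

    return GenotypeMatrix(
        calls=calls,
        sample_ids=fam_df["iid"].tolist(),
        snp_ids=bim_df["snp_id"].tolist(),
        chrom=bim_df["chrom"].to_numpy(dtype=object),
        pos=bim_df["pos"].to_numpy(),
        a1=bim_df["a1"].to_numpy(dtype=object),
        a2=bim_df["a2"].to_numpy(dtype=object),
        ploidy=np.where(is_mt, 1, 2),
    )


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``g`` as a PLINK bed/bim/fam triplet (v1.0 SNP-major dialect).

    Round-trips bit-exactly with :func:`read_plink`: haploid dosage 1 is
    emitted as the homozygous-A1 code and NaN as the missing code.
    """
    prefix = Path(prefix)
    n, m = g.calls.shape

    dosage = g.calls.copy()
    hap = g.ploidy == 1
    if hap.any():
        col = dosage[:, hap]
        col[col == 1] = 2.0        # haploid carrier -> hom-A1 code
        dosage[:, hap] = col
    # dosage -> 2-bit code: 2->00, missing->01, 1->10, 0->11
    codes = np.full((n, m), 0b01, dtype=np.uint8)
    codes[dosage == 2] = 0b00
    codes[dosage == 1] = 0b10
    codes[dosage == 0] = 0b11

    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.ones((pad, m), dtype=np.uint8)])  # pad with missing
    c = codes.T.reshape(m, -1, 4)
    packed = (c[:, :, 0] | (c[:, :, 1] << 2) | (c[:, :, 2] << 4) | (c[:, :, 3] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())

    bim = pd.DataFrame({
        "chrom": g.chrom, "snp_id": g.snp_ids, "cm": 0,
        "pos": g.pos, "a1": g.a1, "a2": g.a2,
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": g.sample_ids, "iid": g.sample_ids, "pat": 0, "mat": 0,
        "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Allele frequencies and filters
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP A1 allele frequency and minor allele frequency.

    The denominator is per-allele: ploidy x number of non-missing samples.
    SNPs with no non-missing calls get NaN frequency (flagged undefined and
    excluded by downstream filters).
    """
    nonmiss = (~np.isnan(g.calls)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(g.calls, axis=0) / (g.ploidy * nonmiss)
    freq = np.where(nonmiss == 0, np.nan, freq)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame({
        "snp_id": g.snp_ids,
        "freq_a1": freq,
        "maf": maf,
        "n_obs": nonmiss.astype(int),
    })


def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Retain SNPs with MAF >= ``threshold`` (order preserved).

    All-missing SNPs (undefined frequency) are always dropped. With
    ``threshold=0`` monomorphic SNPs (maf exactly 0) are retained.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    af = allele_frequencies(g)
    keep = np.where(af["maf"].to_numpy() >= threshold)[0]
    return g.take_snps(keep)


def split_genomes(g: GenotypeMatrix) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Partition into (nuclear, mitochondrial) matrices by ploidy."""
    hap = g.ploidy == 1
    return g.take_snps(np.where(~hap)[0]), g.take_snps(np.where(hap)[0])


def warn_monomorphic(g: GenotypeMatrix) -> np.ndarray:
    """Indices of polymorphic SNPs; warns about monomorphic ones."""
    af = allele_frequencies(g)
    freq = af["freq_a1"].to_numpy()
    poly = np.isfinite(freq) & (freq > 0) & (freq < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        warnings.warn(f"excluding {n_mono} monomorphic/undefined SNP(s)", stacklevel=2)
    return np.where(poly)[0]
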