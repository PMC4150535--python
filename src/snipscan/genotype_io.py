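"""Reading and writing PLINK 1 binary genotype data and associated tables.

Genotypes are held as an ``int8`` matrix of minor-allele dosages with
:data:`MISSING` (= -1) marking no-calls.  Only the PLINK 1 binary triplet
(.bed/.bim/.fam, SNP-major) is supported; text .ped/.map files should be
converted externally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeDataset",
    "CovariateTable",
    "PlinkFormatError",
    "read_plink_binary",
    "write_plink_binary",
    "read_covariates",
    "write_results",
]

#: Sentinel for a missing genotype call in dosage matrices.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 1 2-bit codes (within a byte, LSB first): 00 = hom A1, 01 = missing,
# 10 = het, 11 = hom A2.  Dosage below counts the A1 allele.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported PLINK binary files."""


@dataclass(frozen=True)
class SnpRecord:
    """One .bim row: a SNP's map position and allele labels."""

    chromosome: str
    snp_id: str
    genetic_distance: float
    bp_position: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.bp_position < 0:
            raise ValueError(f"negative bp_position for {self.snp_id}")


@dataclass
class GenotypeDataset:
    """Individuals x SNPs minor-allele dosage matrix with metadata.

    ``genotypes[i, j]`` counts copies of SNP *j*'s minor allele carried by
    individual *i* (0/1/2, or :data:`MISSING`).  ``phenotype`` is a float
    vector with NaN for missing; binary phenotypes are coded 0 = control,
    1 = case.
    """

    genotypes: np.ndarray
    snps: list[SnpRecord]
    phenotype: np.ndarray
    phenotype_type: str  # "binary" | "quantitative"
    individual_ids: list[str]
    family_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if len(self.snps) != m:
            raise ValueError("snps length does not match genotype columns")
        if len(self.phenotype) != n:
            raise ValueError("phenotype length does not match individuals")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match individuals")
        if not self.family_ids:
            self.family_ids = list(self.individual_ids)
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype entries must be 0, 1, 2 or MISSING")
        self.phenotype = np.asarray(self.phenotype, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def snp_index(self, snp_id: str) -> int:
        for j, rec in enumerate(self.snps):
            if rec.snp_id == snp_id:
                return j
        raise KeyError(snp_id)


@dataclass
class CovariateTable:
    """Per-individual covariates aligned to a :class:`GenotypeDataset`.

    ``missing[i]`` is True for dataset individuals absent from the covariate
    file; they are excluded from regressions but kept for correlations.
    """

    values: np.ndarray
    names: list[str]
    individual_ids: list[str]
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    @classmethod
    def empty(cls, dataset: "GenotypeDataset") -> "CovariateTable":
        n = dataset.n_individuals
        return cls(
            values=np.empty((n, 0)),
            names=[],
            individual_ids=list(dataset.individual_ids),
            missing=np.zeros(n, dtype=bool),
        )


def _read_bim(bim_path: Path) -> list[SnpRecord]:
    df = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    records = [
        SnpRecord(r.chrom, r.snp, float(r.cm), int(r.bp), r.a1, r.a2)
        for r in df.itertuples(index=False)
    ]
    # positions must be non-decreasing within each chromosome
    last: dict[str, int] = {}
    for rec in records:
        prev = last.get(rec.chromosome)
        if prev is not None and rec.bp_position < prev:
            raise PlinkFormatError(
                f"SNP {rec.snp_id}: bp positions not sorted within "
                f"chromosome {rec.chromosome}"
            )
        last[rec.chromosome] = rec.bp_position
    return records


def _parse_phenotype(raw: pd.Series) -> tuple[np.ndarray, str]:
    vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    is_int = np.all(finite == np.round(finite)) if finite.size else True
    if is_int and np.all(np.isin(finite, [0, 1, 2, -9])):
        pheno = np.full(vals.shape, np.nan)
        pheno[vals == 1] = 0.0  # control
        pheno[vals == 2] = 1.0  # case
        return pheno, "binary"
    pheno = vals.copy()
    pheno[vals == -9] = np.nan
    return pheno, "quantitative"


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset into a :class:`GenotypeDataset`.

    Dosages are re-oriented so every column counts the dataset-wide minor
    allele (ties at frequency 0.5 keep the file's A1 orientation).  .fam
    phenotypes of 1/2 map to control/case; 0 and -9 to missing; anything
    non-integer is treated as a quantitative trait.
    """
    bed_path, bim_path, fam_path = Path(bed_path), Path(bim_path), Path(fam_path)
    snps = _read_bim(bim_path)
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(snps)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not a PLINK 1 .bed)")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: individual-major .bed files are not supported"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: size {len(raw)} does not match {m} SNPs x {n} "
            f"individuals (expected {expected}); truncated or wrong .bim/.fam?"
        )

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack the four 2-bit fields of each byte, LSB pair first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts) & 0b11
    geno = _CODE_TO_DOSAGE[codes.reshape(m, -1)[:, :n]].T.copy()  # (n, m)

    geno, snps = _orient_to_minor(geno, snps)
    pheno, ptype = _parse_phenotype(fam["pheno"])
    return GenotypeDataset(
        genotypes=geno,
        snps=snps,
        phenotype=pheno,
        phenotype_type=ptype,
        individual_ids=list(fam["iid"]),
        family_ids=list(fam["fid"]),
    )


def _orient_to_minor(
    geno: np.ndarray, snps: list[SnpRecord]
) -> tuple[np.ndarray, list[SnpRecord]]:
    """Flip columns whose counted allele is the major one (freq > 0.5)."""
    out_snps = list(snps)
    obs = geno != MISSING
    with np.errstate(invalid="ignore"):
        counts = np.where(obs, geno, 0).sum(axis=0).astype(float)
        n_obs = obs.sum(axis=0)
        freq = np.divide(counts, 2.0 * n_obs, out=np.full(geno.shape[1], np.nan),
                         where=n_obs > 0)
    for j in np.nonzero(freq > 0.5)[0]:
        col = geno[:, j]
        flipped = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
        geno[:, j] = flipped
        r = out_snps[j]
        out_snps[j] = SnpRecord(
            r.chromosome, r.snp_id, r.genetic_distance, r.bp_position,
            r.allele2, r.allele1,
        )
    return geno, out_snps


def write_plink_binary(dataset: GenotypeDataset, prefix) -> None:
    """Write ``dataset`` as ``prefix``.bed/.bim/.fam (SNP-major PLINK 1)."""
    prefix = Path(prefix)
    n, m = dataset.genotypes.shape

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for rec in dataset.snps:
            fh.write(
                f"{rec.chromosome}\t{rec.snp_id}\t{rec.genetic_distance:g}\t"
                f"{rec.bp_position}\t{rec.allele1}\t{rec.allele2}\n"
            )

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(n):
            p = dataset.phenotype[i]
            if np.isnan(p):
                ptxt = "-9"
            elif dataset.phenotype_type == "binary":
                ptxt = "2" if p == 1 else "1"
            else:
                ptxt = f"{p:g}"
            fh.write(
                f"{dataset.family_ids[i]}\t{dataset.individual_ids[i]}\t0\t0\t0\t{ptxt}\n"
            )

    bytes_per_snp = (n + 3) // 4
    buf = io.BytesIO()
    buf.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    code_lut = np.array([_DOSAGE_TO_CODE[0], _DOSAGE_TO_CODE[1],
                         _DOSAGE_TO_CODE[2], _DOSAGE_TO_CODE[MISSING]],
                        dtype=np.uint8)
    g = dataset.genotypes.T  # (m, n)
    idx = np.where(g == MISSING, 3, g)  # LUT slot 3 holds the missing code
    padded[:, :n] = code_lut[idx]
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(m, bytes_per_snp, 4) << shifts).sum(
        axis=2, dtype=np.uint16
    ).astype(np.uint8)
    buf.write(packed.tobytes())
    prefix.with_suffix(".bed").write_bytes(buf.getvalue())


def read_covariates(path, dataset: GenotypeDataset) -> CovariateTable:
    """Read a PLINK-layout covariate file (FID IID C1 C2 ...).

    Rows are matched to ``dataset`` individuals by individual ID; dataset
    individuals absent from the file are flagged in ``missing`` for exclusion
    from regression.
    """
    df = pd.read_csv(Path(path), sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("covariate file needs at least FID and IID columns")
    n_cov = df.shape[1] - 2
    names = [f"C{k + 1}" for k in range(n_cov)]
    by_id: dict[str, np.ndarray] = {}
    for ridx, row in enumerate(df.itertuples(index=False)):
        vals = np.empty(n_cov)
        for c in range(n_cov):
            cell = row[c + 2]
            try:
                vals[c] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric covariate value {cell!r} at row {ridx + 1}, "
                    f"column {c + 3}"
                ) from None
        by_id[row[1]] = vals

    n = dataset.n_individuals
    values = np.zeros((n, n_cov))
    missing = np.zeros(n, dtype=bool)
    for i, iid in enumerate(dataset.individual_ids):
        if iid in by_id:
            values[i] = by_id[iid]
        else:
            missing[i] = True
            values[i] = np.nan
    return CovariateTable(values, names, list(dataset.individual_ids), missing)


_RESULT_COLUMNS = [
    "CHR", "ANCHOR_SNP", "ANCHOR_BP", "PARTNER_SNP", "PARTNER_BP",
    "R2", "SCORE", "AI_STAT", "AI_P", "SNP_STAT", "SNP_P", "STATUS",
]


def write_results(results: Sequence, path) -> None:
    """Write scan results as a tab-separated table, one row per anchor SNP.

    Missing values (no partner, degenerate fit, ...) are written as ``NA``.
    ``results`` holds :class:`snipscan.scan.ScanRow` objects.
    """

    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, float):
            return "NA" if np.isnan(x) else f"{x:.6g}"
        return str(x)

    with open(Path(path), "w") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for row in results:
            fh.write(
                "\t".join(
                    fmt(v)
                    for v in (
                        row.chromosome, row.anchor_id, row.anchor_bp,
                        row.partner_id, row.partner_bp, row.r2, row.score,
                        row.ai_statistic, row.ai_p, row.single_snp_statistic,
                        row.single_snp_p, row.status,
                    )
                )
                + "\n"
            )
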