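"""Readers and writers for the pipeline's on-disk formats.

Summary statistics travel as tab-separated tables with a header (columns
SNP, CHR, BP, A1, A2, one of Z or BETA+SE, P, N; optional FREQ, INFO;
common aliases are mapped case-insensitively; missing token ``NA``).
Genotypes use the PLINK-1 binary triplet (.bed/.bim/.fam, SNP-major).
Loci export as BED intervals (0-based half-open on disk; the in-memory
convention is 1-based inclusive).  GRMs use the GCTA binary triplet.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypePanel, P_FLOOR, SummaryStats, ValidationError
from .grm import Grm

logger = logging.getLogger(__name__)

__all__ = ["read_sumstats", "write_sumstats", "read_plink", "write_plink",
           "write_loci_bed", "read_regions_bed", "write_grm", "read_grm",
           "read_cohort", "write_cohort"]

_NA = "NA"

#: case-insensitive aliases for required/optional summary-stat columns
_ALIASES = {
    "snp": {"snp", "rsid", "markername", "id", "variant_id"},
    "chrom": {"chr", "chrom", "chromosome"},
    "pos": {"bp", "pos", "position", "base_pair_location"},
    "a1": {"a1", "effect_allele", "allele1", "ea"},
    "a2": {"a2", "other_allele", "allele2", "oa", "ref"},
    "z": {"z", "zscore", "z_score"},
    "beta": {"beta", "b", "effect"},
    "se": {"se", "stderr", "standard_error"},
    "p": {"p", "pval", "pvalue", "p_value"},
    "n": {"n", "nobs", "sample_size"},
    "freq": {"freq", "af", "eaf", "maf_freq", "frq"},
    "info": {"info", "imputation_quality"},
}

_BASES = set("ACGT")


def _canonical_columns(columns) -> dict:
    mapping = {}
    for col in columns:
        low = col.strip().lower()
        for canon, aliases in _ALIASES.items():
            if low in aliases and canon not in mapping.values():
                mapping[col] = canon
                break
    return mapping


def read_sumstats(path) -> SummaryStats:
    """Read a tab-separated summary-statistics table.

    Rows violating the invariants (non-autosomal chromosome,
    non-positive position, multi-base or non-ACGT alleles, unusable
    p-value) are dropped with per-reason counts logged; ``z`` is derived
    from BETA/SE when absent; p-values of 0 are floored at ``1e-300``.
    """
    raw = pd.read_csv(path, sep="\t", na_values=[_NA])
    mapping = _canonical_columns(raw.columns)
    t = raw.rename(columns=mapping)
    for col in ("snp", "chrom", "pos", "a1", "a2", "p", "n"):
        if col not in t.columns:
            raise ValidationError(f"missing required column for {col!r}")
    if "z" not in t.columns:
        if not {"beta", "se"} <= set(t.columns):
            raise ValidationError("need Z or BETA+SE columns")
        t["z"] = t["beta"].astype(float) / t["se"].astype(float)

    counts: dict[str, int] = {}

    def drop(mask, reason):
        bad = int(mask.sum())
        if bad:
            counts[reason] = counts.get(reason, 0) + bad
        return t[~mask]

    t["chrom"] = pd.to_numeric(t["chrom"], errors="coerce")
    t = drop(~t["chrom"].isin(range(1, 23)), "non_autosomal")
    t["chrom"] = t["chrom"].astype(int)
    t["pos"] = pd.to_numeric(t["pos"], errors="coerce")
    t = drop(~(t["pos"] > 0) | t["pos"].isna(), "bad_position")
    t["pos"] = t["pos"].astype(int)
    for col in ("a1", "a2"):
        t[col] = t[col].astype(str).str.upper()
        t = drop(~t[col].isin(_BASES), f"bad_allele_{col}")
    floored = int((t["p"] == 0).sum())
    if floored:
        counts["p_floored"] = floored
    t["p"] = np.clip(t["p"].astype(float), P_FLOOR, 1.0)
    t = drop(t["p"].isna() | t["z"].isna(), "missing_statistic")
    t = drop(t.duplicated(subset=["chrom", "pos", "a1", "a2"]), "duplicate")
    if counts:
        logger.info("read_sumstats %s: dropped/adjusted rows by reason: %s",
                    path, counts)
    if len(t) == 0:
        raise ValidationError("zero valid rows after parsing")
    return SummaryStats(t.reset_index(drop=True))


def write_sumstats(ss: SummaryStats, path) -> None:
    t = ss.table.copy()
    upper = {"snp": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1",
             "a2": "A2", "z": "Z", "beta": "BETA", "se": "SE", "p": "P",
             "n": "N", "freq": "FREQ", "info": "INFO"}
    t = t.rename(columns={k: v for k, v in upper.items() if k in t.columns})
    t.to_csv(path, sep="\t", index=False, na_rep=_NA)


# ----------------------------------------------------------------------
# PLINK-1 binary triplet

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])     # SNP-major
# 2-bit codes, low bits = first sample: 00 hom A1, 10 het, 11 hom A2, 01 missing
_CODE_FOR_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_FOR_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write .bed/.bim/.fam; A1 (the counted allele) is the effect allele."""
    prefix = Path(prefix)
    v = panel.variants
    bim = pd.DataFrame({
        0: v["chrom"], 1: v["snp"], 2: 0, 3: v["pos"],
        4: v["a1"], 5: v["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", index=False, header=False)
    fam = pd.DataFrame({0: panel.samples, 1: panel.samples,
                        2: 0, 3: 0, 4: 0, 5: -9})
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", index=False, header=False)

    n = panel.n_samples
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.full((panel.n_variants, n), 0b01, dtype=np.uint8)
        d = panel.dosages
        for dose, code in _CODE_FOR_DOSAGE.items():
            codes[(d.T == dose)] = code
        packed = np.zeros((panel.n_variants, n_bytes), dtype=np.uint8)
        for k in range(4):
            cols = np.arange(k, n, 4)
            packed[:, :cols.size] |= codes[:, cols] << (2 * k)
        fh.write(packed.tobytes())


def read_plink(prefix) -> GenotypePanel:
    """Read a PLINK-1 triplet into a :class:`GenotypePanel`.

    Missing genotypes become ``NaN``; allele frequencies are recomputed
    from the dosages (clipped away from 0 and 1).
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    samples = fam[1].astype(str).tolist()
    dup = fam[1][fam[1].duplicated()].astype(str).tolist()
    if dup:
        raise ValidationError(f"duplicate sample ids in .fam: {', '.join(dup)}")
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"])
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    blob = Path(prefix.with_suffix(".bed")).read_bytes()
    if blob[:3] != _BED_MAGIC:
        raise ValidationError(".bed magic bytes do not match SNP-major PLINK-1")
    body = np.frombuffer(blob, dtype=np.uint8, offset=3)
    if body.size != n_bytes * m:
        raise ValidationError(
            f".bed payload has {body.size} bytes, expected {n_bytes * m} "
            f"for {n} samples x {m} variants")
    codes = body.reshape(m, n_bytes)
    dosages = np.empty((n, m))
    for k in range(4):
        cols = np.arange(k, n, 4)
        dosages[cols, :] = _DOSAGE_FOR_CODE[(codes[:, :cols.size] >> (2 * k)) & 0b11].T
    freq = np.nanmean(dosages, axis=0) / 2.0
    variants = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    variants["freq"] = np.clip(freq, 1e-6, 1 - 1e-6)
    return GenotypePanel(dosages, variants, samples)


# ----------------------------------------------------------------------
# BED intervals (0-based half-open on disk)

def write_loci_bed(loci, path) -> None:
    """Loci (1-based inclusive) to BED (0-based half-open)."""
    with open(path, "w") as fh:
        for locus in loci:
            name = getattr(locus, "lead", getattr(locus, "label", "."))
            fh.write(f"chr{locus.chrom}\t{locus.start - 1}\t{locus.end}"
                     f"\t{name}\n")


def read_regions_bed(path) -> list:
    """BED intervals to :class:`ExclusionRegion` (1-based inclusive)."""
    from .overlap import ExclusionRegion
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom = int(parts[0].removeprefix("chr"))
            start0, end0 = int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            regions.append(ExclusionRegion(chrom, start0 + 1, end0, label))
    return regions


# ----------------------------------------------------------------------
# GCTA GRM binary triplet

def write_grm(grm: Grm, prefix) -> None:
    """grm.bin / grm.N.bin / grm.id in GCTA's lower-triangle layout."""
    prefix = Path(prefix)
    n = grm.n
    idx = np.tril_indices(n)
    order = np.lexsort((idx[1], idx[0]))       # row-major over (i, j<=i)
    lower = grm.matrix[idx][order].astype("<f4")
    lower.tofile(f"{prefix}.grm.bin")
    np.full(lower.size, grm.m_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in grm.samples:
            fh.write(f"{s}\t{s}\n")


def read_grm(prefix) -> Grm:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    lower = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if lower.size != n * (n + 1) // 2:
        raise ValidationError("GRM binary size does not match id count")
    m = int(np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")[0])
    a = np.zeros((n, n))
    a[np.tril_indices(n)] = lower
    a = a + np.tril(a, -1).T
    return Grm(a, ids, m)


# ----------------------------------------------------------------------
# cohort tables

def read_cohort(path):
    from .containers import CohortTable
    return CohortTable(pd.read_csv(path, sep="\t", na_values=[_NA]))


def write_cohort(cohort, path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False, na_rep=_NA)
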