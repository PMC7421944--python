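"""Core in-memory containers shared across the pipeline.

All genomic coordinates are 1-based inclusive base-pair positions on
autosomes (chromosomes 1-22).  On-disk BED exports are 0-based half-open;
the conversion lives in :mod:`pleiokit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every variant map carries, in canonical order.
VARIANT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "freq"]

#: Required summary-statistic columns ("a1" is the effect allele).
SUMSTAT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "z", "p", "n"]

#: Smallest representable p-value; z statistics are capped accordingly.
P_FLOOR = 1e-300


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class GenotypePanel:
    """n x m hard-call dosage matrix with its variant map.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` array with entries in ``[0, 2]``;
        ``NaN`` marks a missing genotype.
    variants
        Data frame with columns ``snp, chrom, pos, a1, a2, freq`` (an
        optional ``info`` imputation-quality column is passed through).
        Positions must be strictly increasing within each chromosome.
    samples
        Unique sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        _check(self.dosages.ndim == 2, "dosages must be 2-D (samples x variants)")
        if not self.samples:
            self.samples = [f"S{i}" for i in range(self.dosages.shape[0])]
        self.samples = list(self.samples)
        _check(len(self.samples) == self.dosages.shape[0],
               "sample count does not match dosage rows")
        _check(len(set(self.samples)) == len(self.samples),
               "duplicate sample ids")
        v = self.variants.reset_index(drop=True)
        for col in VARIANT_COLUMNS:
            _check(col in v.columns, f"variant map missing column {col!r}")
        _check(len(v) == self.dosages.shape[1],
               "variant count does not match dosage columns")
        _check(v["chrom"].between(1, 22).all(), "chromosomes must be 1-22")
        for _, grp in v.groupby("chrom"):
            _check((np.diff(grp["pos"].to_numpy()) > 0).all(),
                   "positions must be strictly increasing within chromosome")
        freq = v["freq"].to_numpy(float)
        _check(((freq > 0) & (freq < 1)).all(), "frequencies must be in (0,1)")
        with np.errstate(invalid="ignore"):
            _check(bool(np.nanmin(self.dosages) >= 0.0) and
                   bool(np.nanmax(self.dosages) <= 2.0),
                   "dosages must lie in [0, 2]")
        self.variants = v

    # -- basic geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, index) -> "GenotypePanel":
        """New panel restricted to the variant positions in ``index``."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(self.dosages[:, index],
                             self.variants.iloc[index].reset_index(drop=True),
                             self.samples)

    def standardized(self) -> np.ndarray:
        """Mean-imputed, column-standardized dosage matrix (float64)."""
        x = self.dosages.copy()
        mu = np.nanmean(x, axis=0)
        nan = np.isnan(x)
        if nan.any():
            x[nan] = np.broadcast_to(mu, x.shape)[nan]
        sd = x.std(axis=0)
        sd[sd == 0] = np.nan
        return (x - mu) / sd


@dataclass
class SummaryStats:
    """Per-variant GWAS results for a single trait.

    Wraps a data frame with columns ``snp, chrom, pos, a1, a2, z, p, n``
    plus optional ``beta, se, freq, info``.  ``a1`` is the effect allele;
    ``z`` is signed toward ``a1``.  p-values are floored at ``P_FLOOR``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        for col in SUMSTAT_COLUMNS:
            _check(col in t.columns, f"summary statistics missing column {col!r}")
        t["p"] = np.clip(t["p"].to_numpy(float), P_FLOOR, 1.0)
        _check(t["chrom"].between(1, 22).all(), "chromosomes must be 1-22")
        _check((t["pos"].to_numpy() > 0).all(), "positions must be positive")
        dup = t.duplicated(subset=["chrom", "pos", "a1", "a2"])
        _check(not dup.any(), "duplicate (chrom, pos, allele) rows")
        if "beta" in t.columns and "se" in t.columns:
            ok = np.isfinite(t["beta"]) & np.isfinite(t["se"]) & (t["se"] > 0)
            mismatch = ok & (np.sign(t["beta"]) * np.sign(t["z"]) < 0)
            _check(not mismatch.any(), "z and beta/se disagree in sign")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy(float)

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.table["n"].to_numpy(float)

    def neg_log10_p(self) -> np.ndarray:
        return -np.log10(self.p)

    def significant(self, threshold: float = 5e-8) -> pd.DataFrame:
        return self.table[self.table["p"] < threshold]


@dataclass
class CohortTable:
    """Per-subject brainstem volumes, covariates and diagnosis labels.

    Required columns: ``subject, diagnosis, sex, age, icv, site`` and the
    five volumes ``wbs, midbrain, pons, scp, medulla`` (mm^3).  The label
    ``"control"`` marks healthy comparison subjects.
    """

    table: pd.DataFrame

    VOLUMES = ["wbs", "midbrain", "pons", "scp", "medulla"]
    COVARIATES = ["sex", "age", "icv", "site"]

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        needed = ["subject", "diagnosis"] + self.COVARIATES + self.VOLUMES
        for col in needed:
            _check(col in t.columns, f"cohort table missing column {col!r}")
        _check((t[self.VOLUMES].to_numpy(float) > 0).all(),
               "volumes must be positive")
        _check(t["age"].between(0, 120).all(), "ages must be in [0, 120]")
        self.table = t

    @property
    def diagnoses(self) -> list:
        labels = [d for d in self.table["diagnosis"].unique() if d != "control"]
        return sorted(labels)

    def group(self, diagnosis: str) -> pd.DataFrame:
        return self.table[self.table["diagnosis"] == diagnosis]
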