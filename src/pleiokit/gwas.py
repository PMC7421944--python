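"""Variant QC, per-SNP association and discovery-replication concordance.

The association model is ordinary least squares of phenotype on dosage
with nuisance covariates, computed by residualizing both phenotype and
dosage on the covariates (Frisch-Waugh-Lovell), which equals the full
multiple regression exactly once the degrees of freedom are taken from
the full model (``n - k - 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import GenotypePanel, P_FLOOR, SummaryStats, ValidationError

__all__ = [
    "QcThresholds",
    "hwe_exact_test",
    "qc_filter",
    "GwasModel",
    "GwasResults",
    "run_gwas",
    "lambda_gc",
    "replication_concordance",
    "ReplicationReport",
]

#: median of the chi-square(1) distribution
CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class QcThresholds:
    """Variant-level QC thresholds.

    A variant is removed when its imputation INFO score is < ``min_info``
    (only if an INFO column is present), its minor allele frequency is
    < ``min_maf``, its genotype missingness exceeds ``max_missing``, or
    its Hardy-Weinberg exact-test p-value falls below ``hwe_p_floor``.
    """

    min_info: float = 0.5
    min_maf: float = 0.05
    max_missing: float = 0.05
    hwe_p_floor: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("min_info", "min_maf", "max_missing", "hwe_p_floor"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1)")


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count (the standard exact SNP-HWE formulation).
    """
    for c in (n_hom1, n_het, n_hom2):
        if c < 0 or int(c) != c:
            raise ValidationError("genotype counts must be nonnegative integers")
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValidationError("total genotype count must be >= 1")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # log P(het = h | allele counts) up to a shared constant
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logprob = (hets * math.log(2.0)
               - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1))
    logprob -= logprob.max()
    prob = np.exp(logprob)
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def _hardcall_counts(col: np.ndarray):
    """Genotype counts (hom-ref, het, hom-alt) from a hard-call column."""
    x = col[~np.isnan(col)]
    g = np.rint(x).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def qc_filter(panel: GenotypePanel, thresholds: QcThresholds | None = None):
    """Apply variant QC; returns ``(filtered_panel, exclusion_log)``.

    The exclusion log records one reason per removed variant, the first
    failing rule in the fixed order info, maf, missing, hwe.
    """
    if panel.n_variants == 0:
        raise ValidationError("empty panel")
    thresholds = thresholds or QcThresholds()
    x = panel.dosages
    missing = np.isnan(x).mean(axis=0)
    freq = np.nanmean(x, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    info = (panel.variants["info"].to_numpy(float)
            if "info" in panel.variants.columns else None)

    reasons = {}
    for j in range(panel.n_variants):
        if info is not None and info[j] < thresholds.min_info:
            reasons[j] = "info"
        elif maf[j] < thresholds.min_maf:
            reasons[j] = "maf"
        elif missing[j] > thresholds.max_missing:
            reasons[j] = "missing"
        else:
            counts = _hardcall_counts(x[:, j])
            if sum(counts) and hwe_exact_test(*counts) < thresholds.hwe_p_floor:
                reasons[j] = "hwe"
    keep = np.array([j for j in range(panel.n_variants) if j not in reasons])
    if keep.size == 0:
        raise ValidationError("empty panel after QC")
    log = pd.DataFrame({
        "snp": panel.variants["snp"].iloc[list(reasons)].to_numpy(),
        "reason": list(reasons.values()),
    })
    return panel.subset_variants(keep), log


# ----------------------------------------------------------------------
# association

def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Intercept + numeric covariates with categoricals expanded to indicators."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
        else:
            parts.append(s.astype(float))
    frame = pd.concat(parts, axis=1)
    return frame.to_numpy(float), list(frame.columns)


def _check_full_rank(xmat: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(xmat)
    if rank < xmat.shape[1]:
        # pivoted QR flags the dependent columns by name
        from scipy.linalg import qr
        _, r, piv = qr(xmat, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValidationError(f"rank-deficient covariates: {', '.join(bad)}")


class GwasModel:
    """Per-SNP OLS association of a phenotype on dosages with covariates.

    Parameters
    ----------
    panel
        Genotype panel (missing dosages are mean-imputed per variant).
    phenotype
        Length-n vector without missing values.
    covariates
        Data frame of nuisance covariates; categorical columns are
        expanded to indicators and an intercept is always included.
    adjust_for
        Optional extra covariate (e.g. whole-brainstem volume when
        analysing a regional volume); appended to the covariate set.
    """

    def __init__(self, panel: GenotypePanel, phenotype, covariates=None,
                 adjust_for=None):
        self.panel = panel
        y = np.asarray(phenotype, dtype=float)
        if y.ndim != 1 or y.shape[0] != panel.n_samples:
            raise ValidationError("phenotype must be a length-n vector")
        if np.isnan(y).any():
            raise ValidationError("phenotype contains missing values")
        self.phenotype = y
        if covariates is None:
            covariates = pd.DataFrame(index=np.arange(panel.n_samples))
        self.covariates = covariates.reset_index(drop=True)
        if adjust_for is not None:
            extra = np.asarray(adjust_for, dtype=float)
            self.covariates = self.covariates.assign(adjust_for=extra)

    def fit(self) -> "GwasResults":
        xmat, names = _design_matrix(self.covariates)
        _check_full_rank(xmat, names)
        n, k = xmat.shape
        q, _ = np.linalg.qr(xmat)
        y = self.phenotype
        y_r = y - q @ (q.T @ y)

        d = self.panel.dosages
        mu = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), mu, d)
        d_r = d - q @ (q.T @ d)

        sxx = np.einsum("ij,ij->j", d_r, d_r)
        sxy = d_r.T @ y_r
        syy = float(y_r @ y_r)
        df = n - k - 1
        constant = sxx <= 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(constant, np.nan, sxy / sxx)
            sse = syy - beta ** 2 * sxx
            sigma2 = sse / df
            se = np.sqrt(sigma2 / sxx)
            tstat = beta / se
        p = np.clip(2.0 * stats.t.sf(np.abs(tstat), df), P_FLOOR, 1.0)
        p[constant] = np.nan

        table = self.panel.variants[["snp", "chrom", "pos", "a1", "a2"]].copy()
        table["freq"] = np.mean(d, axis=0) / 2.0
        table["beta"] = beta
        table["se"] = se
        table["z"] = tstat
        table["p"] = p
        table["n"] = n
        table["reason"] = np.where(constant, "constant_dosage", "")
        return GwasResults(table, df=df, n=n)


@dataclass
class GwasResults:
    """Per-variant association results plus fit diagnostics."""

    table: pd.DataFrame
    df: int
    n: int

    @property
    def sumstats(self) -> SummaryStats:
        ok = self.table["reason"] == ""
        return SummaryStats(self.table.loc[ok, ["snp", "chrom", "pos", "a1",
                                                "a2", "freq", "beta", "se",
                                                "z", "p", "n"]])

    @property
    def lambda_gc(self) -> float:
        ok = self.table["reason"] == ""
        return lambda_gc(z=self.table.loc[ok, "z"].to_numpy(float))

    def summary(self) -> str:
        m = int((self.table["reason"] == "").sum())
        top = self.table.loc[self.table["reason"] == "", "p"].min()
        return (f"GWAS: {m} variants, n={self.n}, df={self.df}, "
                f"lambda_GC={self.lambda_gc:.3f}, min p={top:.3g}")


def run_gwas(panel: GenotypePanel, phenotype, covariates=None,
             adjust_for=None) -> GwasResults:
    """Functional wrapper around :class:`GwasModel`."""
    return GwasModel(panel, phenotype, covariates, adjust_for).fit()


def lambda_gc(p=None, z=None) -> float:
    """Genomic inflation factor: median chi-square over its null median."""
    if z is not None:
        chi2 = np.asarray(z, dtype=float) ** 2
    elif p is not None:
        chi2 = stats.chi2.isf(np.asarray(p, dtype=float), 1)
    else:
        raise ValueError("provide p or z")
    return float(np.median(chi2) / CHI2_MEDIAN)


# ----------------------------------------------------------------------
# replication

@dataclass
class ReplicationReport:
    """Concordance of discovery lead SNPs in a replication sample."""

    n_leads: int
    n_same_direction: int
    sign_test_p: float
    n_nominal: int                 # replication p < 0.05
    n_gws: int                     # replication p < 5e-8

    def summary(self) -> str:
        return (f"{self.n_same_direction}/{self.n_leads} same direction "
                f"(sign-test p={self.sign_test_p:.3g}); "
                f"{self.n_nominal} nominal, {self.n_gws} genome-wide significant")


def replication_concordance(discovery_leads: SummaryStats,
                            replication: SummaryStats) -> ReplicationReport:
    """Effect-direction and significance concordance for lead SNPs.

    Leads are matched to the replication table by (chromosome, position)
    with allele harmonization (z flipped when the effect allele is
    swapped; strand-ambiguous variants dropped).
    """
    from .overlap import harmonize_pair
    pair = harmonize_pair(discovery_leads, replication)
    if len(pair.table) == 0:
        raise ValidationError("no matchable lead SNPs in replication")
    z1 = pair.z1
    z2 = pair.z2
    same = int(np.sum(np.sign(z1) * np.sign(z2) > 0))
    n = len(z1)
    test = stats.binomtest(same, n, 0.5, alternative="greater")
    p2 = pair.p2
    return ReplicationReport(
        n_leads=n,
        n_same_direction=same,
        sign_test_p=float(test.pvalue),
        n_nominal=int(np.sum(p2 < 0.05)),
        n_gws=int(np.sum(p2 < 5e-8)),
    )
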