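"""Synthetic genotypes, summary statistics, phenotypes and clinical cohorts.

The generators produce data with the statistical structure the downstream
stages assume: block-wise linkage disequilibrium from a latent-Gaussian
(copula) genotype model, a two-trait causal mixture with a tunable shared
fraction and sign concordance, phenotypes with a target SNP heritability,
and clinical cohorts with covariate structure and per-diagnosis volume
offsets.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CohortTable, GenotypePanel, P_FLOOR, SummaryStats

__all__ = [
    "SimulationConfig",
    "simulate_ld_genotypes",
    "simulate_sumstats_pair",
    "simulate_phenotype",
    "simulate_clinical_cohort",
    "SumstatsTruth",
    "PhenotypeTruth",
    "DEFAULT_DIAGNOSES",
]

# Non-ambiguous allele pairs only (no A/T or C/G), so harmonization keeps all.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_BLOCK_GAP_BP = 2_000_000     # inter-block spacing, beyond any LD window
_SNP_SPACING_BP = 1_000       # intra-block spacing


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    """Parameters of the paired-trait generative model.

    ``pi_a``/``pi_b``/``pi_shared`` are the fractions of SNPs causal for
    trait A only, trait B only, and both.  ``sign_concordance`` is the
    probability that a shared causal SNP has same-sign effects in the two
    traits; 0.5 decouples effect directions (zero effect correlation)
    while preserving the overlap in causal variants.
    """

    m_snps: int = 10_000
    n1: int = 30_000
    n2: int = 30_000
    maf_range: tuple = (0.05, 0.5)
    block_size: int = 40
    block_rho: float = 0.8
    pi_a: float = 0.0
    pi_b: float = 0.0
    pi_shared: float = 0.01
    sign_concordance: float = 0.5
    h2_a: float = 0.4
    h2_b: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ConfigError("m_snps must be >= 1")
        if self.n1 < 1 or self.n2 < 1:
            raise ConfigError("n1 and n2 must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")
        if not (0 <= self.block_rho < 1):
            raise ConfigError("block_rho must be in [0, 1)")
        for name in ("pi_a", "pi_b", "pi_shared"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.pi_a + self.pi_b + self.pi_shared > 1 + 1e-12:
            raise ConfigError("pi_a + pi_b + pi_shared must be <= 1")
        if not (0 <= self.sign_concordance <= 1):
            raise ConfigError("sign_concordance must be in [0, 1]")
        for name in ("h2_a", "h2_b"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")


def _block_slices(m: int, block_size: int):
    return [slice(s, min(s + block_size, m)) for s in range(0, m, block_size)]


def _variant_map(m: int, block_size: int, freqs: np.ndarray,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Variant map with blocks laid out contiguously across chromosomes 1-22."""
    slices = _block_slices(m, block_size)
    n_blocks = len(slices)
    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    per_chrom_cursor = {}
    for b, sl in enumerate(slices):
        c = 1 + (b * 22) // n_blocks
        start = per_chrom_cursor.get(c, 1_000_000) + _BLOCK_GAP_BP
        k = sl.stop - sl.start
        chrom[sl] = c
        pos[sl] = start + _SNP_SPACING_BP * np.arange(k)
        per_chrom_cursor[c] = int(pos[sl][-1])
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), m)]
    return pd.DataFrame({
        "snp": [f"rs{c}_{p}" for c, p in zip(chrom, pos)],
        "chrom": chrom,
        "pos": pos,
        "a1": [p[0] for p in pairs],
        "a2": [p[1] for p in pairs],
        "freq": freqs,
    })


def simulate_ld_genotypes(config: SimulationConfig,
                          n_samples: int | None = None) -> GenotypePanel:
    """Hard-call genotypes from an AR(1) latent-Gaussian copula.

    Within each block, two latent haplotype processes per individual follow
    an AR(1) autocorrelation ``block_rho**|i-j|``; each is thresholded at
    the allele-frequency quantile and summed into a {0,1,2} dosage, which
    yields Hardy-Weinberg genotypes with controllable LD.  Blocks are
    mutually independent and separated by more than any LD window.
    """
    n = int(n_samples if n_samples is not None else config.n1)
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    variants = _variant_map(m, config.block_size, freqs, rng)
    thresholds = stats.norm.ppf(1.0 - freqs)       # P(latent > t) = freq
    rho = config.block_rho
    dosages = np.empty((n, m), dtype=float)
    for sl in _block_slices(m, config.block_size):
        k = sl.stop - sl.start
        # two haplotypes per person, AR(1) across SNPs
        eps = rng.standard_normal((2, n, k))
        lat = np.empty_like(eps)
        lat[:, :, 0] = eps[:, :, 0]
        sq = np.sqrt(1.0 - rho * rho)
        for j in range(1, k):
            lat[:, :, j] = rho * lat[:, :, j - 1] + sq * eps[:, :, j]
        dosages[:, sl] = ((lat[0] > thresholds[sl]).astype(float)
                          + (lat[1] > thresholds[sl]))
    return GenotypePanel(dosages, variants)


# ----------------------------------------------------------------------
# paired summary statistics

@dataclass
class SumstatsTruth:
    """Bookkeeping of the true generative state behind a simulated pair."""

    component: np.ndarray          # 0 null, 1 A-only, 2 B-only, 3 shared
    beta_a: np.ndarray             # standardized-scale true effects, trait A
    beta_b: np.ndarray
    shared_sign: np.ndarray        # +1 / -1 at shared causals, 0 elsewhere

    @property
    def shared_index(self) -> np.ndarray:
        return np.flatnonzero(self.component == 3)

    def same_sign_fraction(self) -> float:
        idx = self.shared_index
        if idx.size == 0:
            return float("nan")
        return float(np.mean(self.shared_sign[idx] > 0))


def _block_correlation(x: np.ndarray, ridge: float = 0.02) -> np.ndarray:
    """Shrunk empirical correlation of a dosage block, guaranteed PD."""
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = 1.0
    r = (xc / sd).T @ (xc / sd) / x.shape[0]
    np.fill_diagonal(r, 1.0)
    k = r.shape[0]
    out = (1.0 - ridge) * r + ridge * np.eye(k)
    # PD by construction for ridge > 0 unless the estimate is degenerate;
    # escalate the ridge in that case rather than fail.
    for _ in range(6):
        try:
            np.linalg.cholesky(out)
            return out
        except np.linalg.LinAlgError:
            ridge = min(1.0, ridge * 4)
            out = (1.0 - ridge) * r + ridge * np.eye(k)
    raise np.linalg.LinAlgError("block correlation not positive definite")


def simulate_sumstats_pair(config: SimulationConfig, panel: GenotypePanel):
    """Paired GWAS z-scores under a bivariate causal mixture.

    Each SNP is causal for trait A only (probability ``pi_a``), trait B
    only (``pi_b``), both (``pi_shared``), or neither.  Standardized
    causal effects are Gaussian with variance ``h2 / E[n_causal]``; shared
    effects have proportional magnitudes with the trait-B sign flipped
    with probability ``1 - sign_concordance``.  Marginal z-scores are
    drawn per LD block as ``z ~ N(sqrt(N) R beta, R)`` with ``R`` the
    (shrunk) empirical block correlation of the panel --- the standard
    large-sample GWAS approximation.

    Returns ``(ss_a, ss_b, truth)``.
    """
    m = config.m_snps
    if panel.n_variants < m:
        raise ConfigError("panel has fewer variants than config.m_snps")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    u = rng.random(m)
    component = np.zeros(m, dtype=int)
    component[u < config.pi_a] = 1
    component[(u >= config.pi_a) & (u < config.pi_a + config.pi_b)] = 2
    upper = config.pi_a + config.pi_b + config.pi_shared
    component[(u >= config.pi_a + config.pi_b) & (u < upper)] = 3

    exp_causal_a = max(m * (config.pi_a + config.pi_shared), 1.0)
    exp_causal_b = max(m * (config.pi_b + config.pi_shared), 1.0)
    var_a = config.h2_a / exp_causal_a
    var_b = config.h2_b / exp_causal_b

    beta_a = np.zeros(m)
    beta_b = np.zeros(m)
    is_a = (component == 1) | (component == 3)
    is_b_only = component == 2
    shared = component == 3
    beta_a[is_a] = rng.normal(0.0, np.sqrt(var_a), is_a.sum())
    beta_b[is_b_only] = rng.normal(0.0, np.sqrt(var_b), is_b_only.sum())
    shared_sign = np.zeros(m)
    ssign = np.where(rng.random(shared.sum()) < config.sign_concordance, 1.0, -1.0)
    shared_sign[shared] = ssign
    beta_b[shared] = shared_sign[shared] * beta_a[shared] * np.sqrt(var_b / max(var_a, 1e-300))

    z1 = np.empty(m)
    z2 = np.empty(m)
    for sl in _block_slices(m, config.block_size):
        x = panel.dosages[:, sl]
        r = _block_correlation(np.nan_to_num(x))
        chol = np.linalg.cholesky(r)
        mu1 = np.sqrt(config.n1) * (r @ beta_a[sl])
        mu2 = np.sqrt(config.n2) * (r @ beta_b[sl])
        k = sl.stop - sl.start
        z1[sl] = mu1 + chol @ rng.standard_normal(k)
        z2[sl] = mu2 + chol @ rng.standard_normal(k)

    variants = panel.variants.iloc[:m]

    def _ss(z: np.ndarray, n: int) -> SummaryStats:
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
        t = variants[["snp", "chrom", "pos", "a1", "a2", "freq"]].copy()
        t["z"] = z
        t["p"] = p
        t["n"] = n
        return SummaryStats(t)

    truth = SumstatsTruth(component, beta_a, beta_b, shared_sign)
    return _ss(z1, config.n1), _ss(z2, config.n2), truth


# ----------------------------------------------------------------------
# individual-level phenotypes

@dataclass
class PhenotypeTruth:
    causal_index: np.ndarray
    beta_std: np.ndarray           # per-causal standardized effects
    genetic_values: np.ndarray
    realized_h2: float


def simulate_phenotype(panel: GenotypePanel, h2: float, n_causal: int,
                       seed: int = 0):
    """Phenotype ``y = Z beta + e`` with genetic variance fraction ``h2``.

    ``Z`` is the standardized dosage matrix.  The noise variance is scaled
    to the realized sample variance of the genetic values, so the realized
    heritability matches ``h2`` in expectation (exactly at the boundaries
    0 and 1).  Returns ``(y, PhenotypeTruth)``.
    """
    if not 0 <= h2 <= 1:
        raise ConfigError("h2 must be in [0, 1]")
    if n_causal > panel.n_variants:
        raise ConfigError("n_causal exceeds number of variants")
    rng = np.random.default_rng(seed)
    z = panel.standardized()
    causal = np.sort(rng.choice(panel.n_variants, size=n_causal, replace=False))
    beta = rng.standard_normal(n_causal)
    g = z[:, causal] @ beta if (h2 > 0 and n_causal > 0) else np.zeros(panel.n_samples)
    var_g = float(g.var()) if h2 > 0 else 0.0
    if h2 == 0 or var_g == 0:
        y = rng.standard_normal(panel.n_samples)
        g = np.zeros_like(y)
        beta = np.zeros_like(beta)
        realized = 0.0
    elif h2 == 1:
        y = g
        realized = 1.0
    else:
        sigma_e = np.sqrt(var_g * (1.0 - h2) / h2)
        y = g + sigma_e * rng.standard_normal(panel.n_samples)
        realized = var_g / float(y.var())
    return y, PhenotypeTruth(causal, beta, g, float(realized))


# ----------------------------------------------------------------------
# clinical cohorts

DEFAULT_DIAGNOSES = ["adhd", "asd", "bd", "mdd", "scz", "sczrisk",
                     "psymix", "dem", "mci", "ms", "pd"]

#: regional baselines (mm^3) and residual SDs of the generative model
_REGION_BASE = {"midbrain": 6500.0, "pons": 15000.0, "scp": 300.0,
                "medulla": 4600.0}
_REGION_SD = {"midbrain": 450.0, "pons": 1300.0, "scp": 55.0, "medulla": 380.0}
_WBS_EXTRA_SD = 600.0          # independent noise on top of the regional sum
#: residual SD of the whole brainstem given covariates (sum of parts + noise)
_WBS_RESID_SD = float(np.sqrt(sum(v ** 2 for v in _REGION_SD.values())
                              + _WBS_EXTRA_SD ** 2))

_COVARIATE_BETAS = {
    # per-region multipliers of (sex, centred age, centred age^2, std ICV)
    "sex": 0.35, "age": -0.012, "age2": -0.0004, "icv": 0.25,
}


def simulate_clinical_cohort(effects: dict | None = None,
                             n_cases: int = 300,
                             n_controls: int = 600,
                             n_sites: int = 2,
                             diagnoses: list | None = None,
                             seed: int = 0) -> CohortTable:
    """Clinical cohort with covariate structure and diagnosis offsets.

    ``effects`` maps ``diagnosis -> {volume -> Cohen's d}``; offsets are
    expressed in residual-SD units of the generating model, so a
    covariate-adjusted contrast recovers them directly.  The whole
    brainstem is the sum of the four regional volumes plus independent
    noise (plus its own offset when requested), which makes contrasts
    with and without the whole-brainstem covariate genuinely different.
    Controls form a single pool shared across diagnoses, spread over all
    scanner sites.
    """
    if diagnoses is None:
        diagnoses = DEFAULT_DIAGNOSES
    effects = effects or {}
    for diag, per_vol in effects.items():
        for vol in per_vol:
            if vol not in CohortTable.VOLUMES:
                raise ConfigError(f"unknown volume {vol!r} for diagnosis {diag!r}")
    if n_cases < 2 or n_controls < 2:
        raise ConfigError("need at least 2 cases and 2 controls per group")
    rng = np.random.default_rng(seed)

    rows = []
    groups = [("control", n_controls)] + [(d, n_cases) for d in diagnoses]
    sid = 0
    for diag, n in groups:
        sex = rng.integers(0, 2, n).astype(float)
        age = rng.uniform(20.0, 80.0, n)
        icv = rng.normal(1.5e6, 1.5e5, n)
        site = rng.integers(0, n_sites, n)
        age_c, age2_c = age - 50.0, (age - 50.0) ** 2
        icv_s = (icv - 1.5e6) / 1.5e5
        site_fx = np.linspace(-0.2, 0.2, n_sites)[site]
        per_vol = effects.get(diag, {})
        vols = {}
        for region, base in _REGION_BASE.items():
            sd = _REGION_SD[region]
            mean = (base
                    + sd * (_COVARIATE_BETAS["sex"] * sex
                            + _COVARIATE_BETAS["age"] * age_c
                            + _COVARIATE_BETAS["age2"] * age2_c
                            + _COVARIATE_BETAS["icv"] * icv_s
                            + site_fx)
                    + sd * per_vol.get(region, 0.0))
            vols[region] = mean + sd * rng.standard_normal(n)
        wbs = (sum(vols.values())
               + _WBS_RESID_SD * per_vol.get("wbs", 0.0)
               + _WBS_EXTRA_SD * rng.standard_normal(n))
        for i in range(n):
            rows.append({
                "subject": f"sub{sid}", "diagnosis": diag,
                "sex": sex[i], "age": age[i], "icv": icv[i],
                "site": f"site{site[i]}",
                "wbs": wbs[i],
                **{r: vols[r][i] for r in _REGION_BASE},
            })
            sid += 1
    return CohortTable(pd.DataFrame(rows))
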