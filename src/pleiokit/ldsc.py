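"""LD scores and LD-score regression for heritability and genetic correlation.

Under a polygenic model the expected association chi-square of variant j
is ``E[chi2_j] = 1 + N h2 l_j / M`` with ``l_j`` the LD score (sum of
adjusted r^2 with neighbours); regressing chi-square on LD score
therefore yields the SNP heritability from the slope while the intercept
absorbs confounding inflation.  The cross-trait analogue regresses
``z1 * z2`` on the LD score; the slope is ``sqrt(N1 N2) rho_g / M`` and
the genetic correlation is ``rg = rho_g / sqrt(h2_1 h2_2)``.  Standard
errors come from a delete-one block jackknife over contiguous variant
blocks.  Regression weights are ``1 / max(l, 1)``; the optional two-step
variant estimates the intercept from the chi-square < 30 subset first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypePanel, SummaryStats, ValidationError
from .overlap import HarmonizedPair, harmonize_pair

__all__ = ["LdScoreTable", "ld_scores", "LdscH2", "LdscH2Results",
           "LdscRg", "LdscRgResults"]

_MIN_VARIANTS = 200


@dataclass
class LdScoreTable:
    """Per-variant LD scores from a reference panel."""

    table: pd.DataFrame            # snp chrom pos l2
    window_bp: int
    n_ref: int

    @property
    def l2(self) -> np.ndarray:
        return self.table["l2"].to_numpy(float)


def ld_scores(panel: GenotypePanel, window_bp: int = 1_000_000) -> LdScoreTable:
    """l_j = sum over neighbours within the window of adjusted r^2.

    The small-sample adjustment ``r2 - (1 - r2)/(n_ref - 2)`` makes the
    estimate unbiased for the population r^2; a variant's own
    contribution is exactly 1.
    """
    n = panel.n_samples
    if n < 3:
        raise ValidationError("need at least 3 reference samples")
    z = np.nan_to_num(panel.standardized())
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    m = panel.n_variants
    l2 = np.ones(m)                    # self term: adjusted r^2(j,j) = 1
    hi = 0
    for j in range(m):
        if hi <= j:
            hi = j + 1
        while (hi < m and chrom[hi] == chrom[j]
               and pos[hi] - pos[j] <= window_bp):
            hi += 1
        if hi == j + 1:
            continue
        r = (z[:, j] @ z[:, j + 1:hi]) / n
        r2 = r * r
        adj = r2 - (1.0 - r2) / (n - 2)
        l2[j] += adj.sum()
        l2[j + 1:hi] += adj
    out = panel.variants[["snp", "chrom", "pos"]].copy()
    out["l2"] = l2
    return LdScoreTable(out, window_bp, n)


# ----------------------------------------------------------------------
# weighted regression helpers (shared design: [1, l2])

def _wls(y: np.ndarray, l2: np.ndarray, w: np.ndarray,
         fixed_intercept: float | None = None):
    """Weighted least squares of y on [1, l2]; returns (intercept, slope)."""
    if fixed_intercept is not None:
        yy = y - fixed_intercept
        slope = float((w * l2 * yy).sum() / (w * l2 * l2).sum())
        return fixed_intercept, slope
    x0, x1 = w.sum(), (w * l2).sum()
    x2 = (w * l2 * l2).sum()
    b0, b1 = (w * y).sum(), (w * l2 * y).sum()
    det = x0 * x2 - x1 * x1
    intercept = (x2 * b0 - x1 * b1) / det
    slope = (x0 * b1 - x1 * b0) / det
    return float(intercept), float(slope)


def _jackknife(values: np.ndarray) -> float:
    """Delete-one jackknife standard error from pseudovalue estimates."""
    g = values.size
    mean = values.mean()
    return float(np.sqrt((g - 1) / g * ((values - mean) ** 2).sum()))


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    n_blocks = max(2, min(n_blocks, m))
    return np.linspace(0, m, n_blocks + 1).astype(int)


@dataclass
class LdscH2Results:
    h2: float
    intercept: float
    se_h2: float
    mean_chi2: float
    m: int

    def summary(self) -> str:
        return (f"LDSC h2={self.h2:.3f} (se {self.se_h2:.3f}), "
                f"intercept={self.intercept:.3f}, "
                f"mean chi2={self.mean_chi2:.3f}, m={self.m}")


class LdscH2:
    """Heritability from the regression of chi-square on LD score."""

    def __init__(self, ss: SummaryStats, ld: LdScoreTable,
                 two_step: bool = False, n_blocks: int = 200):
        merged = ss.table.merge(ld.table[["chrom", "pos", "l2"]],
                                on=["chrom", "pos"])
        if len(merged) < _MIN_VARIANTS:
            raise ValidationError(
                f"fewer than {_MIN_VARIANTS} variants matched to LD scores")
        self.merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)
        self.two_step = two_step
        self.n_blocks = n_blocks

    def _estimate(self, chi2, l2, n_bar, m, keep=None):
        if keep is not None:
            chi2, l2 = chi2[keep], l2[keep]
        w = 1.0 / np.maximum(l2, 1.0)
        fixed = None
        if self.two_step:
            sub = chi2 < 30
            fixed, _ = _wls(chi2[sub], l2[sub], w[sub])
        intercept, slope = _wls(chi2, l2, w, fixed)
        return intercept, slope * m / n_bar

    def fit(self) -> LdscH2Results:
        t = self.merged
        chi2 = t["z"].to_numpy(float) ** 2
        l2 = t["l2"].to_numpy(float)
        n_bar = float(t["n"].mean())
        m = len(t)
        intercept, h2 = self._estimate(chi2, l2, n_bar, m)
        bounds = _block_bounds(m, min(self.n_blocks, max(2, -(-m // 100))))
        pseudo = []
        for b in range(len(bounds) - 1):
            keep = np.ones(m, dtype=bool)
            keep[bounds[b]:bounds[b + 1]] = False
            pseudo.append(self._estimate(chi2, l2, n_bar, m, keep)[1])
        return LdscH2Results(h2, intercept, _jackknife(np.array(pseudo)),
                             float(chi2.mean()), m)


@dataclass
class LdscRgResults:
    rg: float
    se: float
    p: float
    h2_1: float
    h2_2: float
    intercept_1: float
    intercept_2: float
    intercept_cross: float
    m: int
    defined: bool = True

    def summary(self) -> str:
        if not self.defined:
            return ("LDSC rg undefined: non-positive heritability "
                    f"(h2_1={self.h2_1:.3f}, h2_2={self.h2_2:.3f})")
        return (f"LDSC rg={self.rg:.3f} (se {self.se:.3f}, p={self.p:.3g}); "
                f"h2_1={self.h2_1:.3f}, h2_2={self.h2_2:.3f}, "
                f"cross-intercept={self.intercept_cross:.3f}")


class LdscRg:
    """Genetic correlation from cross-trait LD-score regression.

    Accepts either a :class:`HarmonizedPair` or two summary-statistic
    sets (harmonized internally on chromosome/position with allele
    alignment).
    """

    def __init__(self, ss1, ss2=None, ld: LdScoreTable | None = None,
                 n_blocks: int = 200, n1: float | None = None,
                 n2: float | None = None):
        if isinstance(ss1, HarmonizedPair):
            pair = ss1
            if ld is None:
                ld = ss2
            if n1 is None or n2 is None:
                raise ValidationError(
                    "supply n1 and n2 when passing a HarmonizedPair")
        else:
            pair = harmonize_pair(ss1, ss2)
            # effective sample size: median reported N per trait
            n1 = float(np.median(ss1.n)) if n1 is None else n1
            n2 = float(np.median(ss2.n)) if n2 is None else n2
        if ld is None:
            raise ValidationError("LD score table required")
        merged = pair.table.merge(ld.table[["chrom", "pos", "l2"]],
                                  on=["chrom", "pos"])
        if len(merged) < _MIN_VARIANTS:
            raise ValidationError(
                f"fewer than {_MIN_VARIANTS} variants matched to LD scores")
        self.merged = merged.sort_values(["chrom", "pos"]).reset_index(drop=True)
        self.n1 = float(n1)
        self.n2 = float(n2)
        self.n_blocks = n_blocks

    def _all_estimates(self, keep=None):
        t = self.merged
        z1 = t["z1"].to_numpy(float)
        z2 = t["z2"].to_numpy(float)
        l2 = t["l2"].to_numpy(float)
        m = len(t)
        if keep is not None:
            z1, z2, l2 = z1[keep], z2[keep], l2[keep]
        w = 1.0 / np.maximum(l2, 1.0)
        i1, s1 = _wls(z1 ** 2, l2, w)
        i2, s2 = _wls(z2 ** 2, l2, w)
        ic, sc = _wls(z1 * z2, l2, w)
        h2_1 = s1 * m / self.n1
        h2_2 = s2 * m / self.n2
        rho_g = sc * m / np.sqrt(self.n1 * self.n2)
        return i1, i2, ic, h2_1, h2_2, rho_g

    def fit(self) -> LdscRgResults:
        m = len(self.merged)
        i1, i2, ic, h2_1, h2_2, rho_g = self._all_estimates()
        if h2_1 <= 0 or h2_2 <= 0:
            return LdscRgResults(np.nan, np.nan, np.nan, h2_1, h2_2,
                                 i1, i2, ic, m, defined=False)
        rg = rho_g / np.sqrt(h2_1 * h2_2)
        bounds = _block_bounds(m, min(self.n_blocks, max(2, -(-m // 100))))
        pseudo = []
        for b in range(len(bounds) - 1):
            keep = np.ones(m, dtype=bool)
            keep[bounds[b]:bounds[b + 1]] = False
            _, _, _, j1, j2, jr = self._all_estimates(keep)
            if j1 > 0 and j2 > 0:
                pseudo.append(jr / np.sqrt(j1 * j2))
        se = _jackknife(np.array(pseudo)) if len(pseudo) >= 2 else np.nan
        p = (2.0 * stats.norm.sf(abs(rg / se))
             if np.isfinite(se) and se > 0 else np.nan)
        return LdscRgResults(float(rg), se, float(p), h2_1, h2_2,
                             i1, i2, ic, m)
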