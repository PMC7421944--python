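"""Case-control contrasts of brainstem volumes with covariate adjustment.

Each contrast is a linear model of one volume on a case indicator plus
sex, age, age^2, ICV and scanner site (and optionally whole-brainstem
volume for the regional measures).  The covariate-adjusted effect size
is converted to Cohen's d from the group-term t statistic,

    d = t * (n1 + n2) / (sqrt(n1 * n2) * sqrt(df)),

with negative d meaning cases have smaller volumes.  The full design is
one whole-brainstem test plus four regional tests each with and without
the whole-brainstem covariate per diagnosis (9 tests; 99 for the 11
standard diagnostic groups), corrected together by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CohortTable, ValidationError

__all__ = ["ContrastResult", "group_contrast", "clinical_matrix",
           "ClinicalMatrixResults", "bh_fdr"]


@dataclass
class ContrastResult:
    """One covariate-adjusted case-control volume contrast."""

    diagnosis: str
    volume: str
    adjusted_for_wbs: bool
    beta: float                    # mm^3, cases relative to controls
    t: float
    df: int
    p: float
    cohens_d: float
    n_cases: int
    n_controls: int
    q: float = np.nan              # BH-adjusted, filled by clinical_matrix
    error: str = ""


def _contrast_design(sub: pd.DataFrame, volume: str, adjust_wbs: bool):
    y = sub[volume].to_numpy(float)
    case = (sub["diagnosis"] != "control").to_numpy(float)
    age = sub["age"].to_numpy(float) - sub["age"].mean()
    icv = sub["icv"].to_numpy(float)
    icv = (icv - icv.mean()) / icv.std()
    cols = [np.ones_like(y), case, sub["sex"].to_numpy(float),
            age, age ** 2, icv]
    sites = sorted(sub["site"].unique())
    if len(sites) > 1:
        for s in sites[1:]:
            cols.append((sub["site"] == s).to_numpy(float))
    if adjust_wbs:
        wbs = sub["wbs"].to_numpy(float)
        cols.append((wbs - wbs.mean()) / wbs.std())
    return y, np.column_stack(cols)


def group_contrast(cohort: CohortTable, diagnosis: str, volume: str,
                   adjust_wbs: bool = False) -> ContrastResult:
    """Linear-model contrast of one diagnosis against its site-matched controls.

    Controls are restricted to subjects imaged at a scanner site shared
    with at least one case; site enters as a fixed effect when more than
    one site remains.
    """
    if volume not in CohortTable.VOLUMES:
        raise ValidationError(f"unknown volume {volume!r}")
    if adjust_wbs and volume == "wbs":
        raise ValidationError(
            "cannot adjust the whole-brainstem contrast for itself")
    cases = cohort.group(diagnosis)
    if len(cases) == 0:
        raise ValidationError(f"no subjects with diagnosis {diagnosis!r}")
    case_sites = set(cases["site"])
    controls = cohort.table[(cohort.table["diagnosis"] == "control")
                            & cohort.table["site"].isin(case_sites)]
    if len(controls) == 0:
        raise ValidationError(
            f"no controls share a scanner site with {diagnosis!r} cases")
    sub = pd.concat([cases, controls]).reset_index(drop=True)

    y, x = _contrast_design(sub, volume, adjust_wbs)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("rank-deficient design in contrast")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = len(y) - x.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(x.T @ x)
    t = float(beta[1] / np.sqrt(cov[1, 1]))
    p = float(2.0 * stats.t.sf(abs(t), df))
    n1, n2 = len(cases), len(controls)
    d = t * (n1 + n2) / (np.sqrt(n1 * n2) * np.sqrt(df))
    return ContrastResult(diagnosis, volume, adjust_wbs, float(beta[1]),
                          t, df, p, float(d), n1, n2)


@dataclass
class ClinicalMatrixResults:
    """The full contrast matrix with pooled BH correction."""

    results: list
    q_level: float

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])

    def rejections(self) -> pd.DataFrame:
        t = self.table
        return t[(t["error"] == "") & (t["q"] <= self.q_level)]

    def summary(self) -> str:
        t = self.table
        ok = (t["error"] == "").sum()
        return (f"clinical matrix: {len(t)} contrasts ({ok} fitted), "
                f"{len(self.rejections())} significant at q<={self.q_level:g}")


def clinical_matrix(cohort: CohortTable, q_level: float = 0.05,
                    diagnoses: list | None = None) -> ClinicalMatrixResults:
    """All contrasts for every diagnosis, BH-corrected across the matrix.

    Per diagnosis: whole brainstem, then each regional volume without
    and with the whole-brainstem covariate (9 tests).  Failing cells are
    flagged and skipped by the correction; the matrix continues.
    """
    if diagnoses is None:
        diagnoses = cohort.diagnoses
    regional = [v for v in CohortTable.VOLUMES if v != "wbs"]
    results = []
    for diag in diagnoses:
        cells = [("wbs", False)] + [(v, adj) for v in regional
                                    for adj in (False, True)]
        for volume, adj in cells:
            try:
                results.append(group_contrast(cohort, diag, volume, adj))
            except ValidationError as exc:
                results.append(ContrastResult(diag, volume, adj,
                                              *( [np.nan] * 5 ), 0, 0,
                                              error=str(exc)))
    pvals = np.array([r.p for r in results])
    ok = np.isfinite(pvals)
    if ok.any():
        q, _ = bh_fdr(pvals[ok], q_level)
        for r, qi in zip([r for r, k in zip(results, ok) if k], q):
            r.q = float(qi)
    return ClinicalMatrixResults(results, q_level)


def bh_fdr(p, q_level: float = 0.05):
    """Benjamini-Hochberg step-up; returns (q-values, rejection mask).

    q-values are the cumulative minima of ``m * p / rank`` taken from
    the largest rank downwards; rejections are ``q <= q_level``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must be in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, q <= q_level
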