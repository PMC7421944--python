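"""Genomic relationship matrix and GREML variance-component estimation.

SNP heritability is estimated by restricted maximum likelihood under

    y = X b + g + e,   g ~ N(0, A s2_g),   e ~ N(0, I s2_e),

where ``A`` is the GRM built from standardized dosages.  The fit uses
average-information (AI) updates with an EM fallback, all evaluated in
the eigenbasis of ``A`` where every solve is diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypePanel, ValidationError
from .gwas import _design_matrix

logger = logging.getLogger(__name__)

__all__ = ["Grm", "compute_grm", "Greml", "GremlResults"]

_VAR_FLOOR = 1e-8   # variance components are clamped here, never exactly 0


@dataclass
class Grm:
    """n x n genomic relationship matrix with sample ids."""

    matrix: np.ndarray
    samples: list
    m_snps: int

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("GRM must be square")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValidationError("GRM must be symmetric")
        if len(self.samples) != a.shape[0]:
            raise ValidationError("sample ids do not match GRM size")
        self.matrix = a

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eig(self):
        """Cached eigendecomposition (eigenvalues, eigenvectors)."""
        if not hasattr(self, "_eig"):
            self._eig = np.linalg.eigh(self.matrix)
        return self._eig


def compute_grm(panel: GenotypePanel) -> Grm:
    """GCTA-style GRM: A_jk = (1/M) sum_i (x_ij-2p_i)(x_ik-2p_i)/(2p_i(1-p_i)).

    Allele frequencies are estimated in-sample; missing dosages are mean
    imputed (contributing zero to the centred products).
    """
    x = panel.dosages
    p = np.nanmean(x, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("monomorphic variant present; run QC first")
    w = (np.where(np.isnan(x), 2.0 * p, x) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    a = (w @ w.T) / panel.n_variants
    return Grm(a, list(panel.samples), panel.n_variants)


@dataclass
class GremlResults:
    """REML variance components, heritability and uncertainties."""

    sigma2_g: float
    sigma2_e: float
    se_sigma2_g: float
    se_sigma2_e: float
    h2: float
    se_h2: float
    loglik: float
    converged: bool
    n_iter: int

    def summary(self) -> str:
        flag = "" if self.converged else "  [NOT CONVERGED]"
        return (f"GREML: h2={self.h2:.3f} (se {self.se_h2:.3f}); "
                f"s2_g={self.sigma2_g:.4g} (se {self.se_sigma2_g:.3g}), "
                f"s2_e={self.sigma2_e:.4g} (se {self.se_sigma2_e:.3g}); "
                f"logL={self.loglik:.3f}, {self.n_iter} iterations{flag}")


class Greml:
    """REML fit of a single genetic variance component against a GRM.

    Parameters
    ----------
    y
        Phenotype vector, one entry per GRM sample.
    grm
        :class:`Grm` (or a raw symmetric matrix).
    covariates
        Optional data frame of fixed effects; an intercept is always
        included.
    """

    def __init__(self, y, grm, covariates: pd.DataFrame | None = None):
        self.y = np.asarray(y, dtype=float)
        if not isinstance(grm, Grm):
            a = np.asarray(grm, float)
            grm = Grm(a, [f"s{i}" for i in range(a.shape[0])], 0)
        if self.y.shape[0] != grm.n:
            raise ValidationError("phenotype and GRM are not conformable")
        self.grm = grm
        self.a = grm.matrix
        n = self.y.shape[0]
        if covariates is None:
            covariates = pd.DataFrame(index=np.arange(n))
        self.x, names = _design_matrix(covariates.reset_index(drop=True))
        if np.linalg.matrix_rank(self.x) < self.x.shape[1]:
            raise ValidationError("rank-deficient covariates")

    # -- internal: everything in the eigenbasis of A -------------------
    def _profile(self, sg, se, lam, yt, xt):
        v = sg * lam + se
        vinv = 1.0 / v
        xtv = xt * vinv[:, None]
        xtvx = xt.T @ xtv
        b = np.linalg.inv(xtvx)
        viy = vinv * yt
        xtviy = xt.T @ viy
        py = viy - xtv @ (b @ xtviy)
        ypy = float(yt @ py)
        sign, logdet_xvx = np.linalg.slogdet(xtvx)
        ll = -0.5 * (np.log(v).sum() + logdet_xvx + ypy)
        t = xtv @ b                      # V^-1 X B
        pdiag = vinv - np.einsum("ij,ij->i", t, xtv)
        return ll, py, pdiag, (vinv, xtv, b)

    def _apply_p(self, u, cache, xt):
        vinv, xtv, b = cache
        return vinv * u - xtv @ (b @ (xt.T @ (vinv * u)))

    def fit(self, max_iter: int = 100, tol: float = 1e-6) -> GremlResults:
        lam, u = self.grm.eig()
        if lam.max() - lam.min() < 0.1:
            logger.warning("h2 weakly identified: GRM is close to identity")
        yt = u.T @ self.y
        xt = u.T @ self.x
        vy = float(self.y.var())
        theta = np.array([0.5 * vy, 0.5 * vy])
        ll_prev = -np.inf
        ai = np.eye(2)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            ll, py, pdiag, cache = self._profile(theta[0], theta[1], lam, yt, xt)
            weights = [lam, np.ones_like(lam)]
            score = np.empty(2)
            upk = []
            for k, w in enumerate(weights):
                tr_pw = float(pdiag @ w)
                quad = float(py @ (w * py))
                score[k] = -0.5 * (tr_pw - quad)
                upk.append(self._apply_p(w * py, cache, xt))
            ai = 0.5 * np.array(
                [[float((weights[k] * py) @ upk[l]) for l in range(2)]
                 for k in range(2)])
            if abs(ll - ll_prev) < tol and it > 1:
                converged = True
                break
            step = np.linalg.pinv(ai) @ score
            proposal = theta + step
            if np.any(~np.isfinite(proposal)):
                proposal = theta.copy()
            new_ll, *_ = self._profile(max(proposal[0], _VAR_FLOOR),
                                       max(proposal[1], _VAR_FLOOR),
                                       lam, yt, xt)
            if not np.isfinite(new_ll) or new_ll < ll - 1e-10:
                # EM fallback: guaranteed ascent direction
                n = yt.size
                for k, w in enumerate(weights):
                    tr_pw = float(pdiag @ w)
                    quad = float(py @ (w * py))
                    proposal[k] = theta[k] + theta[k] ** 2 * (quad - tr_pw) / n
            theta = np.maximum(proposal, _VAR_FLOOR)
            ll_prev = ll
        if not converged:
            logger.warning("GREML did not converge in %d iterations", max_iter)
        sg, se_comp = float(theta[0]), float(theta[1])
        cov = np.linalg.pinv(ai)
        se_sg = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_se = float(np.sqrt(max(cov[1, 1], 0.0)))
        tot = sg + se_comp
        h2 = sg / tot
        grad = np.array([se_comp, -sg]) / tot ** 2
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        return GremlResults(sg, se_comp, se_sg, se_se, h2, se_h2,
                            float(ll), converged, it)
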