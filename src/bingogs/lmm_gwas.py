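"""Mixed-model association scan (EMMAX-style approximation).

Variance components are estimated once under the null model (kinship +
covariates), the data are rotated into the kinship eigenbasis, and each
marker is then tested with a generalized-least-squares slope test in that
rotated space. With K = I and no covariates beyond the intercept this
reduces exactly to per-marker OLS t-tests. An exact per-marker REML refit
is available behind ``exact=True`` for small scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from bingogs.data_io import GenotypeMatrix
from bingogs.kinship_gblup import GRM, RemlFit, VarianceComponents, pca_covariates, reml_fit

logger = logging.getLogger(__name__)


@dataclass
class GWASResult:
    marker_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.marker_ids)
        if not (len(self.beta) == len(self.se) == len(self.p) == k):
            raise ValueError("GWASResult fields differ in length")

    def pvalue_of(self, marker_id: str) -> float:
        return float(self.p[self.marker_ids.index(marker_id)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.marker_ids, self.p.tolist()))


def fit_null_lmm(y: np.ndarray, K: GRM, X: np.ndarray | None = None) -> RemlFit:
    """REML fit of the covariates-only null model; caches the eigen-rotation.

    ``X`` must include the intercept (prepended automatically when omitted).
    Collinear covariates raise, naming the offending columns.
    """
    n = len(np.asarray(y).ravel())
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        bad = [
            j for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == r
        ]
        raise ValueError(f"collinear covariate columns: {bad}")
    return reml_fit(y, K, X)


def score_markers(
    geno: GenotypeMatrix,
    null_fit: RemlFit,
    marker_scope: Sequence[str] | None = None,
    exact: bool = False,
    collinear_tol: float = 1e-10,
) -> GWASResult:
    """Per-marker GLS slope test in the rotated space; two-sided Wald p.

    Monomorphic or covariate-collinear markers get beta = 0, p = 1 (logged).
    ``geno`` must cover the same samples, in the same order, as the null fit.
    """
    ids = list(marker_scope) if marker_scope is not None else geno.marker_ids
    idx = geno.index_of(ids)
    X = geno.imputed()[:, idx]
    n = geno.n_samples
    if n != null_fit.y_rot.size:
        raise ValueError("genotype sample count does not match null fit")

    if exact:
        return _score_exact(X, ids, geno, null_fit)

    U = null_fit.eigvecs
    w = null_fit.weights
    sqw = np.sqrt(w)
    Xs = null_fit.x_rot * sqw[:, None]
    yw = null_fit.y_rot * sqw
    q = Xs.shape[1]
    Q, _ = np.linalg.qr(Xs)
    y_r = yw - Q @ (Q.T @ yw)

    M = (U.T @ X) * sqw[:, None]          # rotated, weighted marker columns
    M_r = M - Q @ (Q.T @ M)               # residualized on covariates
    mss = np.einsum("ij,ij->j", M_r, M_r)
    raw_ss = np.einsum("ij,ij->j", M, M)
    ok = mss > collinear_tol * np.maximum(raw_ss, 1.0)

    beta = np.zeros(len(ids))
    se = np.zeros(len(ids))
    p = np.ones(len(ids))
    df = n - q - 1
    if df <= 0:
        raise ValueError("not enough samples for the marker test")
    if ok.any():
        num = M_r[:, ok].T @ y_r
        beta_ok = num / mss[ok]
        rss = float(y_r @ y_r) - beta_ok * num
        rss = np.clip(rss, 0.0, None)
        s2 = rss / df
        se_ok = np.sqrt(np.clip(s2 / mss[ok], 1e-300, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta_ok / se_ok
        p_ok = 2.0 * stats.t.sf(np.abs(t), df)
        beta[ok], se[ok], p[ok] = beta_ok, se_ok, np.clip(p_ok, 1e-300, 1.0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("score_markers: %d monomorphic/collinear markers set to p=1",
                    n_dropped)
    return GWASResult(marker_ids=ids, beta=beta, se=se, p=p)


def _score_exact(X: np.ndarray, ids: list[str], geno: GenotypeMatrix,
                 null_fit: RemlFit) -> GWASResult:
    """Exact per-marker REML refit (slow; small scans only)."""
    K = GRM(null_fit.eigvecs @ np.diag(null_fit.eigvals) @ null_fit.eigvecs.T,
            list(geno.sample_ids))
    y = null_fit.eigvecs @ null_fit.y_rot
    X0 = null_fit.eigvecs @ null_fit.x_rot
    beta = np.zeros(len(ids))
    se = np.zeros(len(ids))
    p = np.ones(len(ids))
    for j in range(len(ids)):
        col = X[:, j]
        if np.std(col) == 0:
            continue
        Xa = np.column_stack([X0, col])
        if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
            continue
        fit = reml_fit(y, K, Xa)
        w = fit.weights
        Xs = fit.x_rot * np.sqrt(w)[:, None]
        cov = np.linalg.inv(Xs.T @ Xs) * fit.vc.sigma_g2
        b = fit.beta[-1]
        s = float(np.sqrt(cov[-1, -1]))
        df = len(y) - Xa.shape[1]
        beta[j], se[j] = b, s
        p[j] = float(np.clip(2.0 * stats.t.sf(abs(b / s), df), 1e-300, 1.0))
    return GWASResult(marker_ids=ids, beta=beta, se=se, p=p)


def run_gwas(
    geno: GenotypeMatrix,
    y: np.ndarray,
    n_pcs: int = 3,
    kinship: GRM | None = None,
    marker_scope: Sequence[str] | None = None,
) -> GWASResult:
    """Convenience scan: kinship from all markers + intercept + ``n_pcs`` PCs.

    ``geno`` and ``y`` must already be restricted to the analysis samples
    (training samples only, in the selection pipeline).
    """
    from bingogs.kinship_gblup import build_grm

    K = kinship if kinship is not None else build_grm(geno)
    n = geno.n_samples
    X = np.ones((n, 1))
    if n_pcs > 0:
        X = np.column_stack([X, pca_covariates(geno, k=n_pcs)])
    null = fit_null_lmm(np.asarray(y, dtype=float), K, X)
    return score_markers(geno, null, marker_scope)


def gwas_to_frame(geno: GenotypeMatrix, res: GWASResult):
    """GEMMA-like association table: marker_id, chrom, pos, beta, se, p."""
    import pandas as pd

    info = {m.id: m for m in geno.markers}
    rows = [
        (mid, info[mid].chrom, info[mid].pos, b, s, pv)
        for mid, b, s, pv in zip(res.marker_ids, res.beta, res.se, res.p)
    ]
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "beta", "se", "p"])
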