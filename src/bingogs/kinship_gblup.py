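"""GRM construction, single-component REML heritability, and GBLUP prediction.

The variance-component fit is the classic spectral trick: eigendecompose the
GRM once, profile out the genetic variance, and optimize the restricted
likelihood over the single ratio delta = sigma_e^2 / sigma_g^2 with a coarse
log-grid followed by bounded refinement. Everything downstream (GBLUP, the
mixed-model GWAS) reuses this fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from bingogs.data_io import GenotypeMatrix

logger = logging.getLogger(__name__)

_DELTA_LOG_BOUNDS = (-8.0, 8.0)
_GRID_POINTS = 81


@dataclass
class GRM:
    """Genomic relationship matrix with its sample labels."""

    matrix: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, rows: Sequence[int], cols: Sequence[int] | None = None) -> np.ndarray:
        rows = np.asarray(rows, dtype=int)
        cols = rows if cols is None else np.asarray(cols, dtype=int)
        return self.matrix[np.ix_(rows, cols)]


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")

    @property
    def delta(self) -> float:
        """Residual-to-genetic variance ratio (inf when sigma_g2 = 0)."""
        return np.inf if self.sigma_g2 == 0 else self.sigma_e2 / self.sigma_g2


def build_grm(geno: GenotypeMatrix, method: str = "vanraden1") -> GRM:
    """VanRaden method-1 GRM: G = WW' / (2 sum p_j (1-p_j)), W centered by 2p.

    ``method='gcta'`` standardizes each column by sqrt(2 p (1-p)) and
    averages (the GCTA default). Missing dosages are mean-imputed per marker;
    monomorphic markers carry no weight in either estimator.
    """
    if geno.n_samples < 2:
        raise ValueError("need >= 2 samples for a GRM")
    X = geno.imputed()
    p = X.mean(axis=0) / 2.0
    het = 2.0 * p * (1.0 - p)
    poly = het > 0
    if not poly.any():
        raise ValueError("no polymorphic markers; GRM undefined")
    W = X[:, poly] - 2.0 * p[poly]
    if method == "vanraden1":
        G = (W @ W.T) / het[poly].sum()
    elif method == "gcta":
        Ws = W / np.sqrt(het[poly])
        G = (Ws @ Ws.T) / poly.sum()
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    G = (G + G.T) / 2.0
    return GRM(G, list(geno.sample_ids))


# ---------------------------------------------------------------------------
# restricted likelihood machinery
# ---------------------------------------------------------------------------

def _reml_loglik(log_delta: float, d: np.ndarray, ys: np.ndarray, Xs: np.ndarray,
                 logdet_xtx: float) -> float:
    """Restricted log-likelihood profiled over sigma_g2, at a fixed ratio."""
    delta = np.exp(log_delta)
    w = 1.0 / (d + delta)
    Xw = Xs * w[:, None]
    B = Xs.T @ Xw
    b = Xw.T @ ys
    try:
        beta = np.linalg.solve(B, b)
    except np.linalg.LinAlgError:
        return -np.inf
    resid = ys - Xs @ beta
    rss = float(np.sum(w * resid * resid))
    if rss <= 0:
        return -np.inf
    n, q = Xs.shape
    sign, logdet_b = np.linalg.slogdet(B)
    if sign <= 0:
        return -np.inf
    nq = n - q
    return 0.5 * (
        nq * np.log(nq / (2.0 * np.pi))
        - nq
        - nq * np.log(rss)
        - float(np.sum(np.log(d + delta)))
        - logdet_b
        + logdet_xtx
    )


def _fit_delta(d: np.ndarray, ys: np.ndarray, Xs: np.ndarray, logdet_xtx: float
               ) -> tuple[float, float]:
    """Grid + bounded refinement of the REML criterion; returns (delta, loglik)."""
    lo, hi = _DELTA_LOG_BOUNDS
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = np.array([_reml_loglik(g, d, ys, Xs, logdet_xtx) for g in grid])
    k = int(np.argmax(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, d, ys, Xs, logdet_xtx),
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    if -res.fun >= vals[k]:
        return float(np.exp(res.x)), float(-res.fun)
    return float(np.exp(grid[k])), float(vals[k])


@dataclass
class RemlFit:
    """REML fit of y = X beta + g + e with cov(g) = G sigma_g2.

    ``delta`` is the raw fitted variance ratio from the bounded optimizer
    (always finite and positive); ``vc`` reports components clamped to the
    boundary interpretation when the optimum sits at the search edge.
    """

    vc: VarianceComponents
    delta: float             # raw sigma_e2 / sigma_g2 at the optimum
    eigvals: np.ndarray      # eigenvalues of G
    eigvecs: np.ndarray      # columns = eigenvectors
    y_rot: np.ndarray        # U'y
    x_rot: np.ndarray        # U'X
    beta: np.ndarray         # GLS fixed effects at the REML optimum

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / (self.eigvals + self.delta)


def reml_fit(y: np.ndarray, G: GRM, X: np.ndarray | None = None,
             psd_tol: float = 1e-6) -> RemlFit:
    """Spectral REML for the one-GRM mixed model; deterministic.

    ``X`` defaults to an intercept. Raises on non-PSD G (beyond tolerance)
    or zero phenotypic variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != G.n:
        raise ValueError("phenotype length does not match GRM")
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be complete for included samples")
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariate columns in X")

    d, U = np.linalg.eigh(G.matrix)
    if d.min() < -psd_tol * max(1.0, abs(d.max())):
        raise ValueError(
            f"GRM not PSD (min eigenvalue {d.min():.3g}); add jitter to the diagonal"
        )
    d = np.clip(d, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
    delta, loglik = _fit_delta(d, ys, Xs, logdet_xtx)

    w = 1.0 / (d + delta)
    Xw = Xs * w[:, None]
    B = Xs.T @ Xw
    beta = np.linalg.solve(B, Xw.T @ ys)
    resid = ys - Xs @ beta
    sigma_g2 = float(np.sum(w * resid * resid)) / (n - X.shape[1])
    sigma_e2 = float(delta * sigma_g2)
    # clamp ratio extremes to the boundary interpretation
    h2 = 1.0 / (1.0 + delta)
    if np.log(delta) >= _DELTA_LOG_BOUNDS[1] - 1e-6:
        h2 = 0.0
        sigma_e2, sigma_g2 = sigma_e2, 0.0
    elif np.log(delta) <= _DELTA_LOG_BOUNDS[0] + 1e-6:
        h2 = 1.0
        sigma_e2 = 0.0
    vc = VarianceComponents(sigma_g2=sigma_g2, sigma_e2=sigma_e2, h2=h2, loglik=loglik)
    return RemlFit(vc=vc, delta=float(delta), eigvals=d, eigvecs=U,
                   y_rot=ys, x_rot=Xs, beta=beta)


def reml_h2(y: np.ndarray, G: GRM) -> VarianceComponents:
    """Genomic heritability of one trait via intercept-only REML."""
    return reml_fit(y, G).vc


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

def gblup_fit_predict(
    y_train: np.ndarray,
    G: GRM,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    jitter: float = 1e-8,
) -> np.ndarray:
    """Predict test phenotypes by GBLUP with variance ratio re-fit on training data.

    ghat_test = G[test,train] (G[train,train] + lambda I)^-1 (y_train - mu),
    lambda = sigma_e2/sigma_g2 from REML on the training partition;
    returns mu + ghat_test. With sigma_g2 ~ 0 predictions collapse to mu.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    y_train = np.asarray(y_train, dtype=float).ravel()
    G_tt = G.submatrix(train_idx)
    sub_ids = [G.sample_ids[i] for i in train_idx]
    fit = reml_fit(y_train, GRM(G_tt, sub_ids))
    lam = fit.delta  # raw ratio: at the h2~0 edge this is huge and the
    # solution collapses to the GLS mean on its own

    n = train_idx.size
    H = G_tt + lam * np.eye(n)
    ones = np.ones(n)
    try:
        Hi_y = np.linalg.solve(H, y_train)
        Hi_1 = np.linalg.solve(H, ones)
    except np.linalg.LinAlgError:
        logger.warning("singular GBLUP system; applying ridge jitter %g", jitter)
        H = H + jitter * np.eye(n)
        Hi_y = np.linalg.solve(H, y_train)
        Hi_1 = np.linalg.solve(H, ones)
    mu = float(ones @ Hi_y / (ones @ Hi_1))
    alpha = np.linalg.solve(H, y_train - mu)
    g_test = G.submatrix(test_idx, train_idx) @ alpha
    return mu + g_test


def pca_covariates(geno: GenotypeMatrix, k: int = 3, standardize: bool = True) -> np.ndarray:
    """Top-k principal-component scores of the centered/standardized dosages.

    Sign convention: the largest-|loading| element of each component is
    positive. Compute on training samples only when feeding a GWAS.
    """
    n, m = geno.n_samples, geno.n_markers
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n_samples, n_markers)={min(n, m)}")
    X = geno.imputed()
    mu = X.mean(axis=0)
    Z = X - mu
    if standardize:
        sd = Z.std(axis=0)
        keep = sd > 0
        Z = Z[:, keep] / sd[keep]
    else:
        Z = Z[:, Z.std(axis=0) > 0]
    if Z.shape[1] == 0:
        raise ValueError("all markers constant; no principal components")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the centered dosage matrix")
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores
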