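"""Marker quality control: MAF filter, Hardy-Weinberg test, windowed LD pruning.

The pruning rule is deliberately simple and deterministic: within each
sliding window (SNP-count based), while any surviving pair exceeds the r2
threshold the member with the lower MAF is dropped (tie -> later position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from bingogs.data_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not self.ld_window > self.ld_step >= 1:
            raise ValueError("need ld_window > ld_step >= 1")
        if not 0 < self.ld_r2_max <= 1:
            raise ValueError("ld_r2_max must be in (0, 1]")


def compute_maf(geno: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor allele frequency over non-missing calls.

    All-missing markers get ``NaN`` (flagged, excluded downstream).
    """
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(geno.dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def hwe_test(geno_counts: tuple[int, int, int]) -> float:
    """1-df chi-square goodness-of-fit p-value against HWE proportions.

    Monomorphic markers return p = 1 by convention.
    """
    n_aa, n_ab, n_bb = geno_counts
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Vector of HWE p-values, one per marker (missing calls ignored)."""
    X = geno.dosages
    out = np.empty(geno.n_markers)
    for j in range(geno.n_markers):
        col = X[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        out[j] = hwe_test(counts)
    return out


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete entries; constant vectors yield 0
    (logged) so pruning treats them as unlinked.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete entries")
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        logger.debug("ld_r2: constant vector, returning 0")
        return 0.0
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r * r


def _window_r2(Z: np.ndarray) -> np.ndarray:
    """Pairwise r2 for standardized columns Z (constant cols are all-zero)."""
    n = Z.shape[0]
    C = Z.T @ Z / n
    return C * C


def ld_prune(geno: GenotypeMatrix, cfg: QCConfig, protected: set[str] | None = None) -> list[str]:
    """Greedy windowed LD pruning; returns surviving marker ids in genomic order.

    Windows of ``cfg.ld_window`` SNPs advance by ``cfg.ld_step`` within each
    chromosome. While a surviving within-window pair has r2 > ``cfg.ld_r2_max``,
    the lower-MAF member is removed (tie -> later position). Ids in
    ``protected`` are never removed unless both members of a violating pair
    are protected (then the MAF rule applies to them as well).
    """
    protected = protected or set()
    maf = compute_maf(geno)
    X = geno.imputed()
    n = geno.n_samples
    # standardize once; constant columns become zero (r2 = 0 with anything)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, sd == 0] = 0.0

    alive = np.isfinite(maf)  # all-missing markers are dropped outright
    chroms = np.asarray([m.chrom for m in geno.markers])
    is_prot = np.asarray([m.id in protected for m in geno.markers])

    for chrom in dict.fromkeys(chroms):  # preserves genomic order
        idx = np.flatnonzero(chroms == chrom)
        m = idx.size
        starts = range(0, m, cfg.ld_step) if m > cfg.ld_window else [0]
        for s in starts:
            win = idx[s : s + cfg.ld_window]
            _prune_window(win, alive, is_prot, maf, Z, cfg.ld_r2_max)
    return [geno.markers[j].id for j in np.flatnonzero(alive)]


def _prune_window(
    win: np.ndarray,
    alive: np.ndarray,
    is_prot: np.ndarray,
    maf: np.ndarray,
    Z: np.ndarray,
    r2_max: float,
) -> None:
    cur = win[alive[win]]
    if cur.size < 2:
        return
    R2 = _window_r2(Z[:, cur])
    np.fill_diagonal(R2, 0.0)
    live = np.ones(cur.size, dtype=bool)
    while True:
        sub = np.flatnonzero(live)
        if sub.size < 2:
            return
        viol = None
        for a_i in range(len(sub)):
            row = R2[sub[a_i], sub[a_i + 1 :]]
            hit = np.flatnonzero(row > r2_max)
            if hit.size:
                viol = (sub[a_i], sub[a_i + 1 + hit[0]])
                break
        if viol is None:
            return
        a, b = viol
        ja, jb = cur[a], cur[b]
        pa, pb = is_prot[ja], is_prot[jb]
        if pa != pb:
            victim = a if pb else b
        elif maf[ja] < maf[jb]:
            victim = a
        elif maf[jb] < maf[ja]:
            victim = b
        else:  # tie -> later genomic position (larger column index)
            victim = b if jb > ja else a
        live[victim] = False
        alive[cur[victim]] = False


def run_qc(geno: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, dict]:
    """MAF -> HWE -> LD pruning chain; returns filtered matrix + summary counts."""
    cfg = cfg or QCConfig()
    summary: dict[str, int] = {"input": geno.n_markers}

    maf = compute_maf(geno)
    keep = np.isfinite(maf) & (maf >= cfg.maf_min)
    summary["removed_maf"] = int((~keep).sum())
    geno = geno.subset_markers([m.id for m, k in zip(geno.markers, keep) if k])

    hwe = hwe_pvalues(geno)
    keep = ~(hwe < cfg.hwe_p_min)
    summary["removed_hwe"] = int((~keep).sum())
    geno = geno.subset_markers([m.id for m, k in zip(geno.markers, keep) if k])

    survivors = ld_prune(geno, cfg)
    summary["removed_ld"] = geno.n_markers - len(survivors)
    geno = geno.subset_markers(survivors)
    summary["output"] = geno.n_markers
    return geno, summary
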