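"""Monte Carlo choice of the marker-budget upper limit.

Random subsets of increasing size are scored by cross-validated GBLUP
accuracy; the size-vs-accuracy curve is smoothed with a trailing moving
average, differenced, and the budget is the grid size at the first point
where the slope stays near zero for a run of intervals or drops sharply
against its prior average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from bingogs.data_io import GenotypeMatrix
from bingogs.kinship_gblup import build_grm, gblup_fit_predict

logger = logging.getLogger(__name__)


@dataclass
class AccuracyCurve:
    sizes: list[int]
    mean_acc: np.ndarray
    sd_acc: np.ndarray
    n_reps: int = 50

    def __post_init__(self) -> None:
        if list(self.sizes) != sorted(set(self.sizes)):
            raise ValueError("sizes must be strictly increasing")
        if len(self.mean_acc) != len(self.sizes) or len(self.sd_acc) != len(self.sizes):
            raise ValueError("accuracy arrays must match the size grid")


@dataclass
class PlateauConfig:
    ma_window: int = 3
    near_zero_eps: float = 0.1
    run_length: int = 3
    drop_frac: float = 0.2
    drop_baseline: str = "running"  # or "window": mean of last ma_window slopes

    def __post_init__(self) -> None:
        if self.ma_window % 2 == 0 or self.ma_window < 1:
            raise ValueError("ma_window must be odd and positive")
        if not 0 < self.drop_frac < 1:
            raise ValueError("drop_frac must be in (0, 1)")


def moving_average(y: Sequence[float], window: int) -> np.ndarray:
    """Trailing moving average: MA_t = mean(y_{t-window+1} .. y_t).

    Defined from index window-1 onward; the returned array has
    ``len(y) - window + 1`` entries.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    y = np.asarray(y, dtype=float)
    if y.size < window:
        raise ValueError(f"series of length {y.size} shorter than window {window}")
    return np.convolve(y, np.ones(window) / window, mode="valid")


def slope(ma: Sequence[float]) -> np.ndarray:
    """First difference of the smoothed series: Slope_t = MA_t - MA_{t-1}."""
    ma = np.asarray(ma, dtype=float)
    if ma.size < 2:
        raise ValueError("need at least two smoothed points")
    return np.diff(ma)


def detect_plateau(curve: AccuracyCurve, cfg: PlateauConfig | None = None) -> int:
    """Return the grid size at the first point of the stable region.

    Stability at slope index t (grid index window + t) holds when either
    (a) |Slope| stays below ``near_zero_eps * max(Slope)`` for
    ``run_length`` consecutive intervals starting at t, or (b) Slope_t has
    dropped by more than ``drop_frac`` relative to the mean of the earlier
    slopes. If no plateau is found the last grid size is returned with a
    warning.
    """
    cfg = cfg or PlateauConfig()
    sizes = list(curve.sizes)
    ma = moving_average(curve.mean_acc, cfg.ma_window)
    sl = slope(ma)
    if sl.size < max(cfg.run_length, 2):
        raise ValueError("curve too short for plateau detection")
    thresh = cfg.near_zero_eps * float(np.max(sl))
    # slope index t corresponds to grid index cfg.ma_window + t
    offset = cfg.ma_window

    near_zero = np.abs(sl) < thresh
    for t in range(sl.size):
        # (a) a run of near-zero slopes beginning here
        if t + cfg.run_length <= sl.size and near_zero[t : t + cfg.run_length].all():
            return sizes[offset + t]
        # (b) sharp drop against the prior average slope
        if t >= 1:
            if cfg.drop_baseline == "running":
                base = float(np.mean(sl[:t]))
            else:
                base = float(np.mean(sl[max(0, t - cfg.ma_window) : t]))
            if base > 0 and sl[t] < (1.0 - cfg.drop_frac) * base:
                return sizes[offset + t]
    warnings.warn("no plateau detected; returning the largest grid size",
                  stacklevel=2)
    return sizes[-1]


def default_grid(pool_size: int, coarse_from_frac: float = 0.125,
                 n_points: int = 30) -> list[int]:
    """Size grid proportional to the pool: fine steps early, doubled after
    ~1/8 of the pool (mirrors step-1000-then-2000 on an 80k cap)."""
    cap = max(2, pool_size)
    fine_end = max(2, int(cap * coarse_from_frac))
    fine_step = max(1, fine_end // (n_points // 3))
    sizes = list(range(fine_step, fine_end + 1, fine_step))
    coarse_step = 2 * fine_step
    s = sizes[-1] + coarse_step
    while s <= cap and len(sizes) < n_points:
        sizes.append(s)
        s += coarse_step
    return sizes


def _cv_accuracy(geno_sub: GenotypeMatrix, y: np.ndarray, folds: np.ndarray) -> float:
    """Mean per-fold GBLUP r2 with a GRM built from the given marker subset."""
    from bingogs.pipeline_eval import accuracy_r2

    G = build_grm(geno_sub)
    accs = []
    for f in np.unique(folds):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        pred = gblup_fit_predict(y[train], G, train, test)
        accs.append(accuracy_r2(y[test], pred))
    return float(np.mean(accs))


def cv_fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.arange(n) % n_folds
    rng.shuffle(folds)
    return folds


def sample_accuracy_curve(
    pool: Sequence[str],
    geno: GenotypeMatrix,
    y_train: np.ndarray,
    grid: Sequence[int],
    n_reps: int = 50,
    seed: int = 0,
    cv_folds: int = 5,
) -> AccuracyCurve:
    """Mean cross-validated GBLUP r2 of random subsets at each grid size.

    ``geno``/``y_train`` must already be restricted to training samples;
    draws are uniform without replacement from ``pool``. Reproducible
    given ``seed``.
    """
    pool = list(pool)
    grid = list(grid)
    if any(s > len(pool) for s in grid):
        raise ValueError("grid size exceeds pool size")
    rng = np.random.default_rng(seed)
    y = np.asarray(y_train, dtype=float).ravel()
    folds = cv_fold_assignment(len(y), cv_folds, rng)
    mean_acc, sd_acc = [], []
    for size in grid:
        accs = []
        for _ in range(n_reps):
            ids = rng.choice(len(pool), size=size, replace=False)
            sub = geno.subset_markers([pool[i] for i in ids])
            accs.append(_cv_accuracy(sub, y, folds))
        mean_acc.append(float(np.mean(accs)))
        sd_acc.append(float(np.std(accs)))
    return AccuracyCurve(sizes=grid, mean_acc=np.asarray(mean_acc),
                         sd_acc=np.asarray(sd_acc), n_reps=n_reps)


def choose_budget(
    pool: Sequence[str],
    geno: GenotypeMatrix,
    y_train: np.ndarray,
    grid: Sequence[int] | None = None,
    n_reps: int = 50,
    seed: int = 0,
    plateau: PlateauConfig | None = None,
) -> tuple[int, AccuracyCurve]:
    """Sample the curve and apply plateau detection; returns (budget, curve)."""
    grid = list(grid) if grid is not None else default_grid(len(pool))
    curve = sample_accuracy_curve(pool, geno, y_train, grid, n_reps=n_reps, seed=seed)
    return detect_plateau(curve, plateau), curve
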