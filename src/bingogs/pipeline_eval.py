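"""End-to-end pipeline orchestration and the evaluation harness.

Reproduces the evaluation design around the selector: 75/25 train/test
splits over independent replicates, identical partitions for every compared
marker set, squared-correlation accuracy, equal-size random-subset
baselines, and one-tailed paired t-tests (method > baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bingogs.bin_optimizer import (
    OptimizerConfig,
    SelectionReport,
    build_subset1,
    partition_bins,
    run_optimization,
)
from bingogs.data_io import GenotypeMatrix, PhenotypeTable
from bingogs.kinship_gblup import build_grm, gblup_fit_predict
from bingogs.lmm_gwas import run_gwas
from bingogs.marker_qc import QCConfig, run_qc
from bingogs.subset_size import PlateauConfig, choose_budget, default_grid

logger = logging.getLogger(__name__)


@dataclass
class EvalConfig:
    train_frac: float = 0.75
    n_replicates: int = 15
    n_random_subsets: int = 500
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


def make_splits(
    sample_ids: Sequence[str], cfg: EvalConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint exhaustive train/test index splits, one per replicate.

    The same split list must be reused for every compared marker set.
    """
    n = len(sample_ids)
    n_train = int(round(cfg.train_frac * n))
    if n < 8 or n_train == 0 or n_train == n:
        raise ValueError(f"cannot split {n} samples at fraction {cfg.train_frac}")
    rng = np.random.default_rng(cfg.seed)
    splits = []
    for _ in range(cfg.n_replicates):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def accuracy_r2(observed: np.ndarray, predicted: np.ndarray,
                method: str = "pearson2") -> float:
    """Squared Pearson correlation between observed and predicted values.

    Constant predictions yield 0 (logged), not an exception.
    ``method='sse'`` gives 1 - SSE/SST instead.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size or obs.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.std(obs) == 0:
        raise ValueError("observed values are constant")
    if method == "sse":
        return float(1.0 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2))
    if np.std(pred) == 0:
        logger.info("accuracy_r2: constant prediction, returning 0")
        return 0.0
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r * r


def gblup_test_accuracy(
    marker_ids: Sequence[str],
    geno: GenotypeMatrix,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
) -> float:
    """Fit GBLUP on the training partition and score test r2."""
    if not len(marker_ids):
        return 0.0
    G = build_grm(geno.subset_markers(list(marker_ids)))
    pred = gblup_fit_predict(y[train], G, train, test)
    return accuracy_r2(y[test], pred)


def random_subset_baseline(
    pool: Sequence[str],
    size: int,
    n_subsets: int,
    geno: GenotypeMatrix,
    y: np.ndarray,
    split: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
) -> float:
    """Mean GBLUP test r2 over uniform random subsets of the given size."""
    pool = list(pool)
    if size > len(pool):
        raise ValueError("subset size exceeds pool")
    rng = np.random.default_rng(seed)
    train, test = split
    accs = []
    for _ in range(n_subsets):
        pick = rng.choice(len(pool), size=size, replace=False)
        accs.append(
            gblup_test_accuracy([pool[i] for i in pick], geno, y, train, test)
        )
    return float(np.mean(accs))


def paired_onetailed_t(x: Sequence[float], y: Sequence[float]) -> float:
    """One-tailed paired t-test p-value for H1: mean(x - y) > 0.

    Zero-variance differences use the degenerate convention:
    p = 0 if the mean difference is positive, 1 if negative, 0.5 if zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    d = x - y
    if np.std(d) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        m = float(d.mean())
        return 0.0 if m > 0 else (1.0 if m < 0 else 0.5)
    t, p = stats.ttest_rel(x, y, alternative="greater")
    return float(p)


# ---------------------------------------------------------------------------
# one replicate of selection + evaluation
# ---------------------------------------------------------------------------

@dataclass
class ReplicateResult:
    report: SelectionReport
    accuracies: dict[str, float]  # marker-set label -> test r2
    budget: int


def select_and_evaluate(
    geno: GenotypeMatrix,
    y: np.ndarray,
    pool: Sequence[str],
    split: tuple[np.ndarray, np.ndarray],
    opt_cfg: OptimizerConfig,
    qc_cfg: QCConfig | None = None,
    n_pcs: int = 3,
    budget: int | None = None,
    budget_kwargs: dict | None = None,
    n_random_subsets: int = 0,
    random_seed: int = 0,
) -> ReplicateResult:
    """Run selection inside the training partition and score all subsets.

    Selection (GWAS, Subset I, bins, rolling optimization) sees training
    samples only; test phenotypes are touched exclusively at scoring time.
    When ``budget`` is None it is chosen per-replicate by the Monte Carlo
    plateau rule (``budget_kwargs`` forwarded).
    """
    qc_cfg = qc_cfg or QCConfig()
    train, test = split
    y = np.asarray(y, dtype=float).ravel()
    geno_train = geno.subset_samples(train)
    y_train = y[train]

    gwas = run_gwas(geno_train, y_train, n_pcs=n_pcs, marker_scope=list(pool))

    subset1 = build_subset1(gwas, geno_train, opt_cfg, qc_cfg)
    if budget is None:
        budget, _ = choose_budget(pool, geno_train, y_train,
                                  **(budget_kwargs or {}))
    opt_cfg = OptimizerConfig(
        p_strong=opt_cfg.p_strong, n_bins=opt_cfg.n_bins,
        n_groups=opt_cfg.n_groups, cv_folds=opt_cfg.cv_folds,
        budget=budget, seed=opt_cfg.seed,
    )
    part = partition_bins(gwas, subset1, opt_cfg)
    report = run_optimization(part, subset1, geno_train, y_train, opt_cfg, qc_cfg)

    accs: dict[str, float] = {}
    accs["full"] = gblup_test_accuracy(geno.marker_ids, geno, y, train, test)
    accs["pool"] = gblup_test_accuracy(list(pool), geno, y, train, test)
    accs["subset1"] = gblup_test_accuracy(report.subset1, geno, y, train, test)
    accs["subset2"] = gblup_test_accuracy(report.subset2, geno, y, train, test)
    accs["final"] = gblup_test_accuracy(report.final, geno, y, train, test)
    if n_random_subsets > 0:
        accs["random"] = random_subset_baseline(
            pool, max(1, len(report.final)), n_random_subsets,
            geno, y, split, seed=random_seed,
        )
    return ReplicateResult(report=report, accuracies=accs, budget=budget)


@dataclass
class PipelineResult:
    comparison: pd.DataFrame          # replicate x marker-set accuracies
    ttests: pd.DataFrame              # method-vs-baseline one-tailed p-values
    replicates: list[ReplicateResult] = field(default_factory=list)
    qc_summary: dict = field(default_factory=dict)
    pool: list[str] = field(default_factory=list)


def evaluate_pipeline(
    geno: GenotypeMatrix,
    y: np.ndarray,
    pool: Sequence[str],
    eval_cfg: EvalConfig,
    opt_cfg: OptimizerConfig,
    qc_cfg: QCConfig | None = None,
    budget: int | None = None,
    budget_kwargs: dict | None = None,
    n_pcs: int = 3,
) -> PipelineResult:
    """Replicated selection + evaluation over identical splits per marker set."""
    splits = make_splits(list(range(geno.n_samples)), eval_cfg)
    rows = []
    reps: list[ReplicateResult] = []
    for r, split in enumerate(splits):
        rep = select_and_evaluate(
            geno, y, pool, split, opt_cfg, qc_cfg, n_pcs=n_pcs,
            budget=budget, budget_kwargs=budget_kwargs,
            n_random_subsets=eval_cfg.n_random_subsets,
            random_seed=eval_cfg.seed + 7919 * r,
        )
        reps.append(rep)
        rows.append({"replicate": r, **rep.accuracies})
        logger.info("replicate %d: %s", r,
                    {k: round(v, 4) for k, v in rep.accuracies.items()})
    comparison = pd.DataFrame(rows)

    tt_rows = []
    for baseline in ("full", "random", "subset1", "subset2"):
        if baseline not in comparison:
            continue
        p = paired_onetailed_t(comparison["final"], comparison[baseline])
        tt_rows.append({"comparison": f"final>{baseline}", "p_value": p})
    ttests = pd.DataFrame(tt_rows)
    return PipelineResult(comparison=comparison, ttests=ttests, replicates=reps,
                          pool=list(pool))


# ---------------------------------------------------------------------------
# config-file front end
# ---------------------------------------------------------------------------

def run_full_pipeline(config_file: str | Path, outdir: str | Path | None = None
                      ) -> PipelineResult:
    """Execute QC -> GO pool -> replicated selection/evaluation from a YAML config.

    The config names the input files (genotypes, phenotypes, genes, go_map),
    the trait, and optional qc/optimizer/eval/budget sections. Outputs
    (comparison TSV, t-test TSV, subset lists, audit TSV) land in ``outdir``.
    """
    import yaml

    from bingogs import data_io
    from bingogs.go_prior import (build_go_pool, map_terms_to_markers,
                                  select_effective_terms)

    with open(config_file) as fh:
        cfg = yaml.safe_load(fh)

    def _stage(name: str):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("read inputs")
        geno = data_io.read_genotypes(cfg["genotypes"],
                                      cfg.get("genotype_format", "vcf"))
        pheno = data_io.read_phenotypes(cfg["phenotypes"])
        genes = data_io.read_gene_models(cfg["genes"],
                                         cfg.get("gene_format", "gff3"))
        go = data_io.read_go_map(cfg["go_map"])
        trait = cfg["trait"]
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage 'read inputs': {exc}") from exc

    qc_cfg = QCConfig(**cfg.get("qc", {}))
    opt_cfg = OptimizerConfig(**{"budget": 1, **cfg.get("optimizer", {})})
    eval_cfg = EvalConfig(**cfg.get("eval", {}))

    try:
        _stage("marker QC")
        # restrict genotypes to phenotyped samples for the chosen trait
        ids, yvals = pheno.complete_cases(trait)
        row_of = {s: i for i, s in enumerate(geno.sample_ids)}
        rows = [row_of[s] for s in ids if s in row_of]
        yvals = np.asarray([v for s, v in zip(ids, yvals) if s in row_of])
        geno = geno.subset_samples(rows)
        geno, qc_summary = run_qc(geno, qc_cfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage 'marker QC': {exc}") from exc

    try:
        _stage("GO pool")
        idx = map_terms_to_markers(go, genes, geno,
                                   flank_bp=cfg.get("flank_bp", 0))
        idx = select_effective_terms(idx, min_snps=cfg.get("min_snps", 200))
        pool = build_go_pool(idx, geno)
        if not pool:
            raise ValueError("GO pool is empty")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage 'GO pool': {exc}") from exc

    try:
        _stage("selection + evaluation")
        result = evaluate_pipeline(
            geno, yvals, pool, eval_cfg, opt_cfg, qc_cfg,
            budget=cfg.get("budget"),
            budget_kwargs=cfg.get("budget_kwargs"),
            n_pcs=cfg.get("n_pcs", 3),
        )
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage 'selection + evaluation': {exc}") from exc

    result.qc_summary = qc_summary
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.comparison.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        result.ttests.to_csv(outdir / "ttests.tsv", sep="\t", index=False)
        last = result.replicates[-1].report
        data_io.write_marker_subset(last.subset1, outdir / "subset1.txt")
        data_io.write_marker_subset(last.subset2, outdir / "subset2.txt")
        data_io.write_marker_subset(last.final, outdir / "final.txt")
        pd.DataFrame([r.__dict__ for r in last.rounds]).to_csv(
            outdir / "rounds.tsv", sep="\t", index=False)
    return result
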