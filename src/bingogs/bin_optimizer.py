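"""Bin-based combinatorial marker-subset optimization.

Markers with strong GWAS signal (p < ``p_strong``) are LD-pruned into
Subset I. The remaining markers are stratified into B p-value bins, each
split into G ascending sub-interval groups. Round 1 enumerates exactly
B x G candidate combinations by chain-wise rolling: start with every bin
at its first group, then repeatedly move the leading bin to the tail while
advancing its group (wrapping G -> 1). Each combination is scored by
cross-validated GBLUP accuracy of (accumulated set + combination markers)
after LD pruning; the winner's markers are retained, its leading group is
retired, and the surviving combinations roll into the next round until the
accumulated subset reaches the budget. Round-1 scoring therefore costs
O(B x G x F) model fits for F CV folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from bingogs.data_io import GenotypeMatrix
from bingogs.kinship_gblup import build_grm, gblup_fit_predict
from bingogs.lmm_gwas import GWASResult
from bingogs.marker_qc import QCConfig, ld_prune
from bingogs.subset_size import cv_fold_assignment

logger = logging.getLogger(__name__)


@dataclass
class OptimizerConfig:
    p_strong: float = 0.01
    n_bins: int = 10
    n_groups: int = 10
    cv_folds: int = 5
    budget: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_strong < 1:
            raise ValueError("p_strong must be in (0, 1)")
        if min(self.n_bins, self.n_groups, self.cv_folds) < 1:
            raise ValueError("n_bins, n_groups, cv_folds must be >= 1")
        if self.budget < 1:
            raise ValueError("budget must be positive")


@dataclass
class Group:
    """One p-value sub-interval inside a bin, with its markers."""

    lo: float
    hi: float
    marker_ids: list[str] = field(default_factory=list)


@dataclass
class Bin:
    lo: float
    hi: float
    groups: list[Group] = field(default_factory=list)


@dataclass
class BinPartition:
    """B ascending p-value bins, each tiled by G ascending groups."""

    bins: list[Bin]

    def group(self, bin_index: int, group_index: int) -> Group:
        return self.bins[bin_index].groups[group_index]

    def all_marker_ids(self) -> list[str]:
        out: list[str] = []
        for b in self.bins:
            for g in b.groups:
                out.extend(g.marker_ids)
        return out


@dataclass
class Combination:
    """One group per participating bin; the head of ``order`` leads."""

    leading: tuple[int, int]              # (bin_index, group_index)
    members: dict[int, int]               # bin_index -> group_index
    order: list[int] = field(default_factory=list)  # bin order, head first

    def __post_init__(self) -> None:
        b, g = self.leading
        if self.members.get(b) != g:
            raise ValueError("leading group must be one of the members")

    def label(self, bin_names: str = "ABCDEFGHIJKLMNOPQRSTUVWXYZ") -> str:
        order = self.order or sorted(self.members)
        return "-".join(f"{bin_names[b]}{self.members[b] + 1}" for b in order)


@dataclass
class RoundRecord:
    round: int
    winner_label: str
    winner_leading: tuple[int, int]
    cv_accuracy: float
    n_added: int
    cumulative: int


@dataclass
class SelectionReport:
    subset1: list[str]
    subset2: list[str]
    final: list[str]
    rounds: list[RoundRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.subset1) & set(self.subset2):
            raise ValueError("Subsets I and II must be disjoint")


# ---------------------------------------------------------------------------
# Subset I and the bin partition
# ---------------------------------------------------------------------------

def build_subset1(
    gwas: GWASResult,
    geno: GenotypeMatrix,
    cfg: OptimizerConfig,
    qc: QCConfig | None = None,
) -> list[str]:
    """LD-pruned markers with p strictly below ``p_strong``, in genomic order."""
    qc = qc or QCConfig()
    strong = [m for m, p in zip(gwas.marker_ids, gwas.p) if p < cfg.p_strong]
    if not strong:
        warnings.warn("no markers below the strong-effect threshold; "
                      "Subset I is empty", stacklevel=2)
        return []
    sub = geno.subset_markers(strong)
    return ld_prune(sub, qc)


def bin_edges(n_bins: int, p_strong: float) -> np.ndarray:
    """Bin boundaries: [p_strong, 1/B), then equal 1/B-wide bins up to 1.0.

    For B = 10 and p_strong = 0.01 this reproduces the intervals
    [0.01-0.1), [0.1-0.2), ..., [0.9-1.0]; the first bin is narrower than
    the rest by p_strong.
    """
    edges = np.arange(n_bins + 1) / n_bins
    edges[0] = p_strong
    if edges[0] >= edges[1]:
        raise ValueError("p_strong must be below the first interior bin edge")
    return edges


def partition_bins(
    gwas: GWASResult,
    subset1: Sequence[str],
    cfg: OptimizerConfig,
) -> BinPartition:
    """Assign every marker with p >= p_strong (and not in Subset I) to the
    bin/group whose p-interval contains it; the upper end 1.0 is closed.

    Within each bin, groups are G equal-width ascending sub-intervals;
    empty groups are permitted.
    """
    edges = bin_edges(cfg.n_bins, cfg.p_strong)
    exclude = set(subset1)
    bins: list[Bin] = []
    for b in range(cfg.n_bins):
        lo, hi = float(edges[b]), float(edges[b + 1])
        g_edges = np.linspace(lo, hi, cfg.n_groups + 1)
        bins.append(Bin(lo=lo, hi=hi,
                        groups=[Group(float(g_edges[g]), float(g_edges[g + 1]))
                                for g in range(cfg.n_groups)]))
    B, G = cfg.n_bins, cfg.n_groups
    for mid, p in zip(gwas.marker_ids, gwas.p):
        if p < cfg.p_strong or mid in exclude:
            continue
        b = min(int(p * B), B - 1)  # interior edges sit at k/B; 1.0 closes last bin
        if p < edges[b]:  # p in [p_strong, 1/B) lands in bin 0
            b -= 1
        binobj = bins[b]
        frac = (p - binobj.lo) / (binobj.hi - binobj.lo)
        # snap values sitting a rounding error below a group edge upward
        g = min(int(frac * G + 1e-9), G - 1)
        binobj.groups[g].marker_ids.append(mid)
    return BinPartition(bins=bins)


# ---------------------------------------------------------------------------
# chain-wise rolling enumeration
# ---------------------------------------------------------------------------

def enumerate_round1(cfg: OptimizerConfig) -> list[Combination]:
    """Exactly B x G combinations via cyclic rotation.

    Start with all bins at group 0 in bin order. Each emitted combination
    is the current chain (head = leading group); the head bin then moves to
    the tail with its group index advanced (wrapping G -> 1). Every
    (bin, group) pair leads exactly once.
    """
    B, G = cfg.n_bins, cfg.n_groups
    order = list(range(B))
    group_of = {b: 0 for b in order}
    combos: list[Combination] = []
    for _ in range(B * G):
        head = order[0]
        combos.append(
            Combination(
                leading=(head, group_of[head]),
                members=dict(group_of),
                order=list(order),
            )
        )
        order = order[1:] + [head]
        group_of[head] = (group_of[head] + 1) % G
    return combos


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def merge_and_prune(
    base: Sequence[str],
    new_ids: Sequence[str],
    geno: GenotypeMatrix,
    qc: QCConfig,
) -> list[str]:
    """LD-prune base + new markers; base markers are protected from removal."""
    base = list(base)
    add = [m for m in new_ids if m not in set(base)]
    if not add:
        return list(base)
    merged = geno.in_genomic_order(set(base) | set(add))
    sub = geno.subset_markers(merged)
    return ld_prune(sub, qc, protected=set(base))


def cv_gblup_accuracy(
    marker_ids: Sequence[str],
    geno: GenotypeMatrix,
    y: np.ndarray,
    folds: np.ndarray,
) -> float:
    """Mean per-fold GBLUP test r2 using a GRM from the given markers."""
    from bingogs.pipeline_eval import accuracy_r2

    if not len(marker_ids):
        return 0.0
    G = build_grm(geno.subset_markers(list(marker_ids)))
    accs = []
    for f in np.unique(folds):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        pred = gblup_fit_predict(y[train], G, train, test)
        accs.append(accuracy_r2(y[test], pred))
    return float(np.mean(accs))


def combination_markers(
    comb: Combination,
    part: BinPartition,
    excluded: set[tuple[int, int]] | None = None,
) -> list[str]:
    """Markers contributed by a combination, skipping excluded groups."""
    excluded = excluded or set()
    out: list[str] = []
    for b, g in comb.members.items():
        if (b, g) in excluded:
            continue
        out.extend(part.group(b, g).marker_ids)
    return out


def score_combination(
    comb: Combination,
    part: BinPartition,
    base: Sequence[str],
    geno: GenotypeMatrix,
    y_train: np.ndarray,
    cfg: OptimizerConfig,
    qc: QCConfig | None = None,
    folds: np.ndarray | None = None,
    excluded: set[tuple[int, int]] | None = None,
) -> tuple[float, list[str]]:
    """Accuracy and merged marker list for one combination.

    merged = ld_prune(base U combination markers); accuracy = mean F-fold
    CV r2 of GBLUP on the training samples. The fold assignment should be
    shared by every combination scored in the same round.
    """
    qc = qc or QCConfig()
    y = np.asarray(y_train, dtype=float).ravel()
    if folds is None:
        folds = cv_fold_assignment(y.size, cfg.cv_folds,
                                   np.random.default_rng(cfg.seed))
    merged = merge_and_prune(base, combination_markers(comb, part, excluded),
                             geno, qc)
    if not merged:
        logger.warning("empty merged marker set; accuracy set to 0")
        return 0.0, []
    return cv_gblup_accuracy(merged, geno, y, folds), merged


# ---------------------------------------------------------------------------
# the rolling optimization loop
# ---------------------------------------------------------------------------

def run_optimization(
    part: BinPartition,
    subset1: Sequence[str],
    geno: GenotypeMatrix,
    y_train: np.ndarray,
    cfg: OptimizerConfig,
    qc: QCConfig | None = None,
) -> SelectionReport:
    """Iterate chain-wise rolling rounds until the budget is reached.

    Round 1 scores the full B x G enumeration; each later round re-scores
    the surviving combinations against the grown accumulated set. The
    winner's leading group is retired from every candidate. Ties break to
    the earliest combination in enumeration order. Deterministic given
    (cfg.seed, input order).
    """
    qc = qc or QCConfig()
    y = np.asarray(y_train, dtype=float).ravel()
    subset1 = list(subset1)
    accumulated = list(subset1)
    report = SelectionReport(subset1=subset1, subset2=[], final=list(subset1))

    if len(accumulated) >= cfg.budget:
        warnings.warn("budget already satisfied by Subset I; no rounds run",
                      stacklevel=2)
        report.final = list(accumulated)
        report.subset2 = []
        return report

    candidates = enumerate_round1(cfg)
    excluded: set[tuple[int, int]] = set()
    rng = np.random.default_rng(cfg.seed)
    round_no = 0
    while candidates and len(accumulated) < cfg.budget:
        round_no += 1
        folds = cv_fold_assignment(y.size, cfg.cv_folds, rng)
        best: tuple[float, int] | None = None  # (acc, candidate position)
        best_merged: list[str] = []
        # combinations whose surviving groups coincide produce identical
        # merged sets; score each distinct merged set once per round
        seen: dict[tuple[str, ...], tuple[float, list[str]]] = {}
        for k, comb in enumerate(candidates):
            ids = combination_markers(comb, part, excluded)
            key = tuple(sorted(set(ids)))
            if key in seen:
                acc, merged = seen[key]
            else:
                merged = merge_and_prune(accumulated, ids, geno, qc)
                acc = cv_gblup_accuracy(merged, geno, y, folds) if merged else 0.0
                seen[key] = (acc, merged)
            if best is None or acc > best[0]:
                best = (acc, k)
                best_merged = merged
        assert best is not None
        acc, k = best
        winner = candidates.pop(k)
        excluded.add(winner.leading)
        n_added = len(best_merged) - len(accumulated)
        accumulated = best_merged
        report.rounds.append(
            RoundRecord(
                round=round_no,
                winner_label=winner.label(),
                winner_leading=winner.leading,
                cv_accuracy=acc,
                n_added=n_added,
                cumulative=len(accumulated),
            )
        )
        logger.info("round %d: winner %s acc=%.4f added=%d total=%d",
                    round_no, winner.label(), acc, n_added, len(accumulated))

    report.final = geno.in_genomic_order(accumulated)
    report.subset2 = [m for m in report.final if m not in set(subset1)]
    return report


def split_subset2(report: SelectionReport) -> tuple[list[str], list[str]]:
    """(Subset I, Subset II = final markers outside Subset I); disjoint."""
    s1 = set(report.subset1)
    subset2 = [m for m in report.final if m not in s1]
    assert not (s1 & set(subset2))
    return list(report.subset1), subset2
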