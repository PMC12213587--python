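import numpy as np
import pytest

from bingogs.bin_optimizer import (
    BinPartition,
    Combination,
    OptimizerConfig,
    bin_edges,
    build_subset1,
    combination_markers,
    enumerate_round1,
    merge_and_prune,
    partition_bins,
    run_optimization,
    score_combination,
    split_subset2,
)
from bingogs.lmm_gwas import GWASResult, run_gwas
from bingogs.marker_qc import QCConfig, ld_r2
from bingogs.subset_size import cv_fold_assignment
from bingogs.synthetic_fixtures import SimConfig, simulate_dataset


def _gwas(marker_ids, pvals):
    k = len(marker_ids)
    return GWASResult(marker_ids=list(marker_ids), beta=np.zeros(k),
                      se=np.ones(k), p=np.asarray(pvals, dtype=float))


def brute_force_rotation(B, G):
    """Independent simulation of the chain-wise rolling process."""
    chain = [(b, 0) for b in range(B)]
    out = []
    for _ in range(B * G):
        out.append(list(chain))
        (b, g), rest = chain[0], chain[1:]
        chain = rest + [(b, (g + 1) % G)]
    return out


class TestEnumerateRound1:
    def test_worked_example_5_bins_4_groups(self):
        combos = enumerate_round1(OptimizerConfig(n_bins=5, n_groups=4, budget=1))
        assert len(combos) == 20
        assert combos[0].label() == "A1-B1-C1-D1-E1"
        assert combos[1].label() == "B1-C1-D1-E1-A2"
        assert combos[-1].label() == "E4-A1-B1-C1-D1"

    def test_single_bin_single_group(self):
        combos = enumerate_round1(OptimizerConfig(n_bins=1, n_groups=1, budget=1))
        assert len(combos) == 1
        assert combos[0].leading == (0, 0)

    @pytest.mark.parametrize("B", range(1, 7))
    @pytest.mark.parametrize("G", range(1, 7))
    def test_matches_brute_force_rotation_oracle(self, B, G):
        combos = enumerate_round1(OptimizerConfig(n_bins=B, n_groups=G, budget=1))
        expected = brute_force_rotation(B, G)
        assert len(combos) == B * G
        for comb, chain in zip(combos, expected):
            assert comb.leading == chain[0]
            assert [(b, comb.members[b]) for b in comb.order] == chain
        # every (bin, group) pair leads exactly once
        leaders = {c.leading for c in combos}
        assert leaders == {(b, g) for b in range(B) for g in range(G)}

    def test_default_config_100_combinations(self):
        combos = enumerate_round1(OptimizerConfig(budget=1))
        assert len(combos) == 100

    def test_leading_must_be_member(self):
        with pytest.raises(ValueError, match="leading"):
            Combination(leading=(0, 1), members={0: 0})


class TestBinEdges:
    def test_decile_intervals_for_ten_bins(self):
        edges = bin_edges(10, 0.01)
        np.testing.assert_allclose(
            edges, [0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])

    def test_p_strong_above_first_edge_rejected(self):
        with pytest.raises(ValueError):
            bin_edges(10, 0.15)


class TestPartitionBins:
    def test_interval_membership(self):
        gwas = _gwas(["a"], [0.15])
        part = partition_bins(gwas, [], OptimizerConfig(budget=1))
        assert part.bins[1].groups[5].marker_ids == ["a"]  # [0.1-0.2), 0.15 -> g5

    def test_p_one_lands_in_last_bin(self):
        gwas = _gwas(["a"], [1.0])
        part = partition_bins(gwas, [], OptimizerConfig(budget=1))
        assert part.bins[-1].groups[-1].marker_ids == ["a"]

    def test_strong_markers_and_subset1_excluded(self):
        gwas = _gwas(["a", "b", "c"], [0.005, 0.5, 0.7])
        part = partition_bins(gwas, ["b"], OptimizerConfig(budget=1))
        assert part.all_marker_ids() == ["c"]

    def test_groups_tile_bins_disjointly(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.011, 1.0, 500)
        gwas = _gwas([f"m{i}" for i in range(500)], p)
        part = partition_bins(gwas, [], OptimizerConfig(budget=1))
        ids = part.all_marker_ids()
        assert len(ids) == len(set(ids)) == 500
        for b in part.bins:
            assert b.groups[0].lo == pytest.approx(b.lo)
            assert b.groups[-1].hi == pytest.approx(b.hi)
            for g0, g1 in zip(b.groups, b.groups[1:]):
                assert g0.hi == pytest.approx(g1.lo)

    def test_uniform_p_multinomial_occupancy(self):
        rng = np.random.default_rng(11)
        n = 10_000
        p = rng.uniform(0.0, 1.0, n)
        keep = p >= 0.01
        gwas = _gwas([f"m{i}" for i in range(n)], p)
        part = partition_bins(gwas, [], OptimizerConfig(budget=1))
        n_assigned = keep.sum()
        for b, binobj in enumerate(part.bins):
            width = binobj.hi - binobj.lo
            exp = n_assigned * width / 0.99
            sd = np.sqrt(exp * (1 - width / 0.99))
            count = sum(len(g.marker_ids) for g in binobj.groups)
            assert abs(count - exp) < 3 * sd


@pytest.fixture(scope="module")
def opt_fixture():
    data = simulate_dataset(
        SimConfig(n_samples=150, n_markers=1000, n_chrom=2, qtn_count=15,
                  h2=0.7, seed=3))
    geno = data["geno"]
    y = data["pheno"].values[:, 0]
    gwas = run_gwas(geno, y)
    return data, geno, y, gwas


class TestBuildSubset1:
    def test_all_p_above_threshold_gives_empty(self, mini_geno):
        gwas = _gwas(mini_geno.marker_ids[:5], [0.5, 0.2, 0.9, 0.011, 0.01])
        with pytest.warns(UserWarning, match="Subset I is empty"):
            out = build_subset1(gwas, mini_geno, OptimizerConfig(budget=1))
        assert out == []

    def test_p_exactly_at_threshold_excluded(self, mini_geno):
        gwas = _gwas(mini_geno.marker_ids[:2], [0.01, 0.009])
        out = build_subset1(gwas, mini_geno, OptimizerConfig(budget=1))
        assert out == [mini_geno.marker_ids[1]]

    def test_qtn_tagging_enrichment(self):
        # mean fraction of QTNs tagged (r2 > 0.5) by Subset I across seeds;
        # the kinship-corrected scan absorbs part of the signal, so the
        # detectable rate at this scale is well below 1 but far above chance
        rates = []
        for seed in range(4):
            data = simulate_dataset(
                SimConfig(n_samples=200, n_markers=1000, n_chrom=2,
                          qtn_count=8, h2=0.8, seed=seed))
            geno = data["geno"]
            y = data["pheno"].values[:, 0]
            gwas = run_gwas(geno, y)
            cfg = OptimizerConfig(budget=1)
            strong = [m for m, p in zip(gwas.marker_ids, gwas.p)
                      if p < cfg.p_strong]
            s1 = build_subset1(gwas, geno, cfg) if strong else []
            X = geno.imputed()
            qtns = data["truth"]["qtn_id"].tolist()
            tagged = sum(
                any(ld_r2(X[:, geno.index_of([q])[0]],
                          X[:, geno.index_of([m])[0]]) > 0.5 for m in s1)
                for q in qtns)
            rates.append(tagged / len(qtns))
        assert np.mean(rates) >= 0.3


class TestScoreCombination:
    def test_noop_merge_keeps_base_accuracy(self, opt_fixture):
        _, geno, y, gwas = opt_fixture
        cfg = OptimizerConfig(n_bins=5, n_groups=5, budget=500, seed=1)
        s1 = build_subset1(gwas, geno, cfg)
        part = partition_bins(gwas, s1, cfg)
        comb = enumerate_round1(cfg)[0]
        folds = cv_fold_assignment(len(y), 5, np.random.default_rng(0))
        excluded = {(b, comb.members[b]) for b in comb.members}
        acc, merged = score_combination(comb, part, s1, geno, y, cfg,
                                        folds=folds, excluded=excluded)
        assert merged == list(s1)
        from bingogs.bin_optimizer import cv_gblup_accuracy
        assert acc == pytest.approx(cv_gblup_accuracy(s1, geno, y, folds))

    def test_merge_prune_idempotent_on_duplicates(self, opt_fixture):
        _, geno, _, gwas = opt_fixture
        base = geno.marker_ids[:50]
        merged = merge_and_prune(base, base, geno, QCConfig())
        assert merged == list(base)

    def test_adding_qtn_group_raises_accuracy(self, opt_fixture):
        data, geno, y, gwas = opt_fixture
        qtns = data["truth"]["qtn_id"].tolist()
        from bingogs.bin_optimizer import cv_gblup_accuracy
        wins = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            folds = cv_fold_assignment(len(y), 5, rng)
            base = [m for m in rng.choice(geno.marker_ids, 60, replace=False)
                    if m not in qtns]
            with_q = geno.in_genomic_order(set(base) | set(qtns))
            if cv_gblup_accuracy(with_q, geno, y, folds) > \
               cv_gblup_accuracy(base, geno, y, folds):
                wins += 1
        assert wins >= 8


class TestRunOptimization:
    def test_budget_saturated_by_subset1(self, opt_fixture):
        _, geno, y, gwas = opt_fixture
        cfg = OptimizerConfig(n_bins=3, n_groups=3, budget=1, seed=0)
        s1 = build_subset1(gwas, geno, cfg)
        part = partition_bins(gwas, s1, cfg)
        with pytest.warns(UserWarning, match="budget"):
            rep = run_optimization(part, s1, geno, y, cfg)
        assert rep.final == list(s1)
        assert rep.rounds == []

    def test_winner_removal_leaves_99_default(self):
        cfg = OptimizerConfig(budget=10)
        combos = enumerate_round1(cfg)
        combos.pop(37)  # designate any winner
        assert len(combos) == 99

    def test_rolling_run_audit_and_disjointness(self, opt_fixture):
        _, geno, y, gwas = opt_fixture
        cfg = OptimizerConfig(n_bins=4, n_groups=4, cv_folds=3, budget=250, seed=5)
        s1 = build_subset1(gwas, geno, cfg)
        part = partition_bins(gwas, s1, cfg)
        rep = run_optimization(part, s1, geno, y, cfg)
        assert len(rep.final) >= cfg.budget
        assert set(rep.subset1) & set(rep.subset2) == set()
        assert set(rep.final) == set(rep.subset1) | set(rep.subset2)
        # monotone accumulation + winning rounds recorded
        sizes = [r.cumulative for r in rep.rounds]
        assert sizes == sorted(sizes)
        leads = [r.winner_leading for r in rep.rounds]
        assert len(set(leads)) == len(leads)  # each leading group retired once

    def test_deterministic(self, opt_fixture):
        _, geno, y, gwas = opt_fixture
        cfg = OptimizerConfig(n_bins=3, n_groups=3, cv_folds=3, budget=150, seed=7)
        s1 = build_subset1(gwas, geno, cfg)
        part = partition_bins(gwas, s1, cfg)
        a = run_optimization(part, s1, geno, y, cfg)
        b = run_optimization(part, s1, geno, y, cfg)
        assert a.final == b.final
        assert [r.winner_label for r in a.rounds] == [r.winner_label for r in b.rounds]

    def test_subset1_protected_through_merges(self, opt_fixture):
        _, geno, y, gwas = opt_fixture
        cfg = OptimizerConfig(n_bins=3, n_groups=3, cv_folds=3, budget=200, seed=2)
        s1 = build_subset1(gwas, geno, cfg)
        part = partition_bins(gwas, s1, cfg)
        rep = run_optimization(part, s1, geno, y, cfg)
        assert set(s1) <= set(rep.final)


class TestSplitSubset2:
    def test_final_equals_subset1_gives_empty(self):
        from bingogs.bin_optimizer import SelectionReport

        rep = SelectionReport(subset1=["a", "b"], subset2=[], final=["a", "b"])
        s1, s2 = split_subset2(rep)
        assert s2 == []

    def test_partition_identity(self, opt_fixture):
        _, geno, y, gwas = opt_fixture
        cfg = OptimizerConfig(n_bins=3, n_groups=3, cv_folds=3, budget=150, seed=4)
        s1 = build_subset1(gwas, geno, cfg)
        part = partition_bins(gwas, s1, cfg)
        rep = run_optimization(part, s1, geno, y, cfg)
        s1b, s2 = split_subset2(rep)
        assert len(rep.final) == len(s1b) + len(s2)
        assert set(s2) == set(rep.final) - set(s1b)  # set-difference oracle
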