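import math

import numpy as np
import pytest

from cats2d.benchmark import (
    BenchmarkConfig,
    alpha_for_contribution,
    bedroc,
    compare_descriptors,
    random_bedroc_expectation,
    run_benchmark,
    scaffold_diversity,
    summarize,
)
from cats2d.chemio import murcko_scaffold
from cats2d.simsearch import DescriptorSpec, Entry, RankedRetrieval


def ranking_from_active_ranks(n_total: int, active_ranks: set[int]) -> RankedRetrieval:
    entries = [
        Entry(f"c{r:05d}", float(r), r in active_ranks) for r in range(1, n_total + 1)
    ]
    return RankedRetrieval("q", entries, "euclidean_distance")


def bedroc_closed_form(n_total: int, ranks: list[int], alpha: float) -> float:
    """Independent plain-math coding of the exponentially weighted ROC score."""
    n = len(ranks)
    ra = n / n_total
    s = sum(math.exp(-alpha * r / n_total) for r in ranks)
    rie = (s / n) * n_total * (math.exp(alpha / n_total) - 1) / (1 - math.exp(-alpha))
    num = ra * math.sinh(alpha / 2)
    den = math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra)
    return rie * num / den + 1 / (1 - math.exp(alpha * (1 - ra)))


class TestBedroc:
    def test_perfect_ranking_saturates(self):
        ranked = ranking_from_active_ranks(1000, set(range(1, 11)))
        assert bedroc(ranked, 160.9) >= 0.99

    def test_worst_ranking_vanishes(self):
        ranked = ranking_from_active_ranks(1000, set(range(991, 1001)))
        assert bedroc(ranked, 160.9) <= 0.01

    def test_agrees_with_independent_closed_form(self):
        cases = [
            (200, [3, 17, 50, 120, 180]),
            (1000, [1, 2, 999]),
            (50, [10, 11, 12, 13]),
        ]
        for n_total, ranks in cases:
            for alpha in (5.0, 20.0, 160.9):
                ranked = ranking_from_active_ranks(n_total, set(ranks))
                assert bedroc(ranked, alpha) == pytest.approx(
                    bedroc_closed_form(n_total, ranks, alpha), abs=1e-9
                )

    def test_bounded_and_monotone_under_rank_improvement(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n_total = int(rng.integers(20, 200))
            n_act = int(rng.integers(1, n_total // 2))
            ranks = set(rng.choice(np.arange(1, n_total + 1), n_act, replace=False).tolist())
            score = bedroc(ranking_from_active_ranks(n_total, ranks), 160.9)
            assert 0.0 <= score <= 1.0
            movable = sorted(r for r in ranks if r > 1 and r - 1 not in ranks)
            if not movable:
                continue
            improved = (ranks - {movable[0]}) | {movable[0] - 1}
            better = bedroc(ranking_from_active_ranks(n_total, improved), 160.9)
            assert better >= score

    def test_small_alpha_limit_matches_linear_weighting(self):
        """As alpha -> 0 the exponential weights become linear in rank, so the
        score approaches the min-max-normalized linear-weight sum."""
        n_total, ranks = 200, [3, 17, 50, 120, 180]
        n = len(ranks)
        s = sum(n_total - r for r in ranks)
        s_best = sum(n_total - r for r in range(1, n + 1))
        s_worst = sum(n_total - r for r in range(n_total - n + 1, n_total + 1))
        linear = (s - s_worst) / (s_best - s_worst)
        got = bedroc(ranking_from_active_ranks(n_total, set(ranks)), alpha=0.001)
        assert got == pytest.approx(linear, rel=0.01)

    def test_random_permutations_match_expectation_formula(self):
        """Mean over 1000 random label placements stays within 3 standard
        errors of the closed-form random expectation."""
        rng = np.random.default_rng(8)
        n_total, n_act, alpha = 200, 10, 160.9
        scores = []
        for _ in range(1000):
            ranks = set(rng.choice(np.arange(1, n_total + 1), n_act, replace=False).tolist())
            scores.append(bedroc(ranking_from_active_ranks(n_total, ranks), alpha))
        scores = np.asarray(scores)
        expect = random_bedroc_expectation(n_total, n_act, alpha)
        se = scores.std(ddof=1) / math.sqrt(len(scores))
        assert abs(scores.mean() - expect) <= 3 * se

    def test_all_active_or_all_inactive_rejected(self):
        with pytest.raises(ValueError):
            bedroc(ranking_from_active_ranks(10, set(range(1, 11))), 160.9)
        with pytest.raises(ValueError):
            bedroc(ranking_from_active_ranks(10, set()), 160.9)


class TestAlphaForContribution:
    def test_top_one_percent_eighty_percent_contribution(self):
        assert alpha_for_contribution(0.01, 0.8) == pytest.approx(160.9, abs=0.05)

    def test_round_trip(self):
        alpha = alpha_for_contribution(0.05, 0.8)
        achieved = (1 - math.exp(-alpha * 0.05)) / (1 - math.exp(-alpha))
        assert achieved == pytest.approx(0.8, abs=1e-6)

    def test_uniform_weight_limit(self):
        # contribution barely above the fraction itself forces alpha -> 0+
        assert alpha_for_contribution(0.5, 0.5 + 1e-5) < 0.01

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            alpha_for_contribution(0.0, 0.8)
        with pytest.raises(ValueError):
            alpha_for_contribution(0.01, 1.0)


class TestScaffoldDiversity:
    def test_direct_count(self):
        entries = [Entry(f"a{i}", float(i), True) for i in range(5)]
        entries += [Entry(f"z{i}", 10.0 + i, False) for i in range(95)]
        ranked = RankedRetrieval("q", entries, "euclidean_distance")
        scaffolds = {"a0": "A", "a1": "A", "a2": "B", "a3": "C", "a4": "C"}
        n, s, r = scaffold_diversity(ranked, 0.05, scaffolds)
        assert (n, s, r) == (5, 3, 0.6)

    def test_single_scaffold_lower_bound(self):
        entries = [Entry(f"a{i}", float(i), True) for i in range(4)]
        entries += [Entry(f"z{i}", 10.0 + i, False) for i in range(96)]
        ranked = RankedRetrieval("q", entries, "euclidean_distance")
        n, s, r = scaffold_diversity(ranked, 0.04, {f"a{i}": "S" for i in range(4)})
        assert (n, s, r) == (4, 1, 0.25)

    def test_no_actives_in_cut(self):
        entries = [Entry(f"z{i}", float(i), False) for i in range(99)]
        entries.append(Entry("a0", 100.0, True))
        ranked = RankedRetrieval("q", entries, "euclidean_distance")
        assert scaffold_diversity(ranked, 0.01, {"a0": "S"}) == (0, 0, None)

    def test_matches_recount_oracle_on_fixture(self, benchmark_collection):
        results = run_benchmark(
            benchmark_collection, ["cats2"], BenchmarkConfig(top_fraction=0.05)
        )["cats2"]
        scaffolds = {c.id: murcko_scaffold(c) for c in benchmark_collection}
        by_target = {}
        for c in benchmark_collection:
            for t in c.targets:
                by_target.setdefault(t, set()).add(c.id)
        for q in results:
            assert 0 <= q.s <= q.n
            if q.n:
                keys = {scaffolds[cid] for cid in by_target[q.target_id]}
                assert q.r == pytest.approx(q.s / q.n)
                assert q.s <= len(keys)
                assert 0 < q.r <= 1


class TestRunBenchmark:
    def test_query_count_contract(self, benchmark_collection):
        results = run_benchmark(benchmark_collection, ["cats2"], BenchmarkConfig())
        assert len(results["cats2"]) == 75  # 3 targets x 25 ligands

    def test_identical_representation_listed_twice(self, benchmark_collection):
        from cats2d.cats import cats_matrix

        spec = DescriptorSpec(
            "cats2-bis", "euclidean_distance", lambda cs: cats_matrix(cs)
        )
        results = run_benchmark(benchmark_collection, ["cats2", spec], BenchmarkConfig())
        a = [(q.query_id, q.bedroc, q.n, q.s) for q in results["cats2"]]
        b = [(q.query_id, q.bedroc, q.n, q.s) for q in results["cats2-bis"]]
        assert a == b

    def test_below_threshold_targets_skipped(self, benchmark_collection):
        with pytest.raises(ValueError):
            run_benchmark(
                benchmark_collection, ["cats2"], BenchmarkConfig(min_actives_per_target=26)
            )

    def test_constant_descriptor_behaves_like_random_ranking(self, benchmark_collection):
        """A constant descriptor ranks by the id tie-break; with ids shuffled
        to random hex strings this is one random permutation, whose BEDROC
        must sit inside the permutation-null distribution."""
        from cats2d.chemio import Compound

        rng = np.random.default_rng(4)
        relabeled = []
        for c in benchmark_collection:
            new_id = f"{rng.integers(0, 16**8):08x}"
            cc = Compound(new_id, c.mol, set(c.targets))
            relabeled.append(cc)
        const = DescriptorSpec(
            "const", "euclidean_distance", lambda cs: np.zeros((len(cs), 4))
        )
        results = run_benchmark(relabeled, [const], BenchmarkConfig())["const"]
        observed = np.mean([q.bedroc for q in results])

        null = []
        for _ in range(1000):
            ranks = set(rng.choice(np.arange(1, 175), 24, replace=False).tolist())
            null.append(bedroc(ranking_from_active_ranks(174, ranks), 160.9))
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= observed <= hi

    def test_summary_has_quartiles(self, benchmark_collection):
        results = run_benchmark(benchmark_collection, ["cats2"], BenchmarkConfig())
        table = summarize(results, "bedroc")
        assert list(table.columns) == ["q25", "median", "q75"]
        assert (table["q25"] <= table["median"]).all()


class TestCompareDescriptors:
    @staticmethod
    def _results_from_values(**named_values):
        from cats2d.benchmark import QueryResult

        return {
            name: [QueryResult(f"q{i}", "T", v, 1, 1, 1.0) for i, v in enumerate(vals)]
            for name, vals in named_values.items()
        }

    def test_self_comparison_is_indistinguishable(self):
        vals = np.random.default_rng(1).uniform(0, 1, 50).tolist()
        results = self._results_from_values(a=vals, b=list(vals))
        comp = compare_descriptors(results, "bedroc")
        assert comp.p_matrix.loc["a", "b"] == pytest.approx(0.5, abs=0.05)
        d = 1 - 2 * min(comp.p_matrix.loc["a", "b"], comp.p_matrix.loc["b", "a"])
        assert d == pytest.approx(0.0, abs=0.1)

    def test_shifted_distribution_separates(self):
        rng = np.random.default_rng(3)
        lo = rng.normal(0.3, 0.05, 100).tolist()
        hi = rng.normal(0.7, 0.05, 100).tolist()
        comp = compare_descriptors(self._results_from_values(hi=hi, lo=lo), "bedroc")
        assert comp.p_matrix.loc["hi", "lo"] < 1e-6
        assert comp.p_matrix.loc["lo", "hi"] > 1 - 1e-6
        d = 1 - 2 * min(comp.p_matrix.loc["hi", "lo"], comp.p_matrix.loc["lo", "hi"])
        assert d > 0.99

    def test_ward_merges_identical_pair_first(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0.5, 0.1, 60).tolist()
        shifted = rng.normal(0.9, 0.1, 60).tolist()
        comp = compare_descriptors(
            self._results_from_values(a=base, b=list(base), c=shifted), "bedroc"
        )
        first_merge = set(comp.linkage_matrix[0, :2].astype(int))
        assert first_merge == {0, 1}  # a and b
        assert comp.linkage_matrix.shape[0] == 2

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(10)
        results = self._results_from_values(
            x=rng.uniform(size=30).tolist(),
            y=rng.uniform(size=30).tolist(),
            z=(rng.uniform(size=30) + 0.5).tolist(),
        )
        nwk = compare_descriptors(results).to_newick()
        assert nwk.endswith(";")
        for leaf in ("x", "y", "z"):
            assert leaf in nwk
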