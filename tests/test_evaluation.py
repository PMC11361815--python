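"""Cross-validation protocol, ranking metrics, MRR comparison, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qwprio import (
    CVConfig,
    InputFormatError,
    PPINetwork,
    ScoreVector,
    SeedSet,
    average_precision,
    hypergeometric_enrichment,
    mrr_across_methods,
    qa_scores,
    rank_candidates,
    recall_at,
    run_cv,
    split_seeds,
)
from qwprio.evaluation import RankedList
from qwprio.methods import make_scorer


def seed_set(indices, n, name="d"):
    return SeedSet(name, frozenset(indices), n)


class TestSplitSeeds:
    def test_even_split(self):
        tr, ho = split_seeds(seed_set(range(10), 20), 0.5, rng_seed=0)
        assert len(tr) == 5 and len(ho) == 5

    def test_odd_split_rounds_half_up(self):
        tr, ho = split_seeds(seed_set(range(15), 20), 0.5, rng_seed=0)
        assert len(ho) == 8 and len(tr) == 7

    def test_partition_is_disjoint_union(self):
        s = seed_set(range(0, 20, 2), 30)
        tr, ho = split_seeds(s, 0.5, rng_seed=3)
        assert tr.seed_indices | ho.seed_indices == s.seed_indices
        assert not (tr.seed_indices & ho.seed_indices)

    def test_reproducible(self):
        s = seed_set(range(11), 15)
        a = split_seeds(s, 0.5, rng_seed=42)
        b = split_seeds(s, 0.5, rng_seed=42)
        assert a[0].seed_indices == b[0].seed_indices

    def test_too_few_seeds(self):
        with pytest.raises(InputFormatError):
            split_seeds(seed_set([0], 5), 0.5, rng_seed=0)


class TestRankCandidates:
    @pytest.fixture
    def net3(self):
        return PPINetwork.from_edges([("a", "b"), ("b", "c")])

    def test_descending_order_excluding_train(self, net3):
        sv = ScoreVector("m", np.array([3.0, 2.0, 1.0]))
        ranked = rank_candidates(net3, sv, seed_set({0}, 3), seed_set({2}, 3))
        assert [net3.node_ids[i] for i in ranked.ordered_nodes] == ["b", "c"]
        assert ranked.holdout_mask.tolist() == [False, True]

    def test_ties_broken_by_ascending_identifier(self, net3):
        sv = ScoreVector("m", np.array([3.0, 1.0, 1.0]))
        ranked = rank_candidates(net3, sv, seed_set({0}, 3), seed_set({2}, 3))
        assert [net3.node_ids[i] for i in ranked.ordered_nodes] == ["b", "c"]

    def test_train_holdout_overlap_rejected(self, net3):
        sv = ScoreVector("m", np.zeros(3))
        with pytest.raises(InputFormatError):
            rank_candidates(net3, sv, seed_set({0}, 3), seed_set({0, 2}, 3))


class TestMetrics:
    def test_recall_at(self):
        mask = np.zeros(30, dtype=bool)
        mask[[2, 10, 27, 29]] = True
        ranked = RankedList(np.arange(30), mask)
        assert recall_at(ranked, 25) == 0.5
        assert recall_at(ranked, 30) == 1.0
        assert recall_at(ranked, 2) == 0.0

    def test_average_precision_worked_example(self):
        """Hits at ranks 1 and 3 of two holdouts: AP = (1 + 2/3)/2 = 5/6."""
        mask = np.array([True, False, True, False])
        assert average_precision(RankedList(np.arange(4), mask)) == pytest.approx(5 / 6)

    def test_average_precision_perfect_and_single(self):
        assert average_precision(
            RankedList(np.arange(5), np.array([1, 1, 0, 0, 0], bool))
        ) == 1.0
        k = 4
        mask = np.zeros(6, bool)
        mask[k - 1] = True
        assert average_precision(RankedList(np.arange(6), mask)) == pytest.approx(1 / k)

    def test_empty_holdout_rejected(self):
        ranked = RankedList(np.arange(3), np.zeros(3, bool))
        with pytest.raises(InputFormatError):
            recall_at(ranked, 2)
        with pytest.raises(InputFormatError):
            average_precision(ranked)


class TestMRR:
    def test_clear_winner(self):
        recs = mrr_across_methods(
            {"d1": {"X": 0.9, "Y": 0.1}, "d2": {"X": 0.8, "Y": 0.2}}
        )
        by = {r.method: r.mrr for r in recs}
        assert by == {"X": 1.0, "Y": 0.5}

    def test_exact_tie_uses_fractional_ranks(self):
        recs = mrr_across_methods({"d1": {"X": 0.5, "Y": 0.5}})
        for r in recs:
            assert r.per_disease_rr == pytest.approx((1 / 1.5,))

    def test_three_distinct_methods(self):
        recs = mrr_across_methods({"d": {"a": 0.9, "b": 0.5, "c": 0.1}})
        by = {r.method: r.mrr for r in recs}
        assert by == {"a": 1.0, "b": 0.5, "c": pytest.approx(1 / 3)}

    def test_three_by_three_with_ties_hand_enumerated(self):
        """Fractional ranks per disease, averaged across three diseases."""
        table = {
            "d1": {"a": 0.9, "b": 0.5, "c": 0.1},  # ranks 1, 2, 3
            "d2": {"a": 0.4, "b": 0.4, "c": 0.4},  # all tied -> rank 2 each
            "d3": {"a": 0.1, "b": 0.7, "c": 0.7},  # b,c tied at 1.5; a rank 3
        }
        by = {r.method: r.mrr for r in mrr_across_methods(table)}
        assert by["a"] == pytest.approx((1 + 1 / 2 + 1 / 3) / 3)
        assert by["b"] == pytest.approx((1 / 2 + 1 / 2 + 1 / 1.5) / 3)
        assert by["c"] == pytest.approx((1 / 3 + 1 / 2 + 1 / 1.5) / 3)

    def test_missing_method_rejected(self):
        with pytest.raises(InputFormatError):
            mrr_across_methods({"d1": {"X": 0.5, "Y": 0.1}, "d2": {"X": 0.5}})

    def test_reciprocal_rank_bounds(self):
        """RR in (0,1]; per-disease RR sum <= harmonic number, equal w/o ties."""
        rng = np.random.default_rng(4)
        table = {
            f"d{i}": {m: float(rng.random()) for m in "abcd"} for i in range(6)
        }
        recs = mrr_across_methods(table)
        h4 = sum(1 / r for r in range(1, 5))
        for d in range(6):
            total = sum(r.per_disease_rr[d] for r in recs)
            assert total == pytest.approx(h4)
        for r in recs:
            assert 0 < r.mrr <= 1


class TestRunCV:
    def test_degenerate_single_cell(self, small_bench):
        net, diseases = small_bench
        cfg = CVConfig(repetitions=1, top_n_grid=(5, 25, net.n), rng_seed=0)
        res = run_cv(net, diseases[:1], {"qa": make_scorer("qa")}, cfg)
        assert len(res.recall) == 3 and not res.failures
        curve = res.recall.sort_values("cutoff")["recall"].tolist()
        assert curve == sorted(curve)  # monotone
        assert curve[-1] == 1.0  # terminal cutoff covers all candidates

    def test_duplicated_scorer_gives_identical_curves(self, small_bench):
        net, diseases = small_bench
        cfg = CVConfig(repetitions=2, top_n_grid=(25,), rng_seed=5)
        res = run_cv(
            net, diseases[:2], {"m1": make_scorer("nbr"), "m2": make_scorer("nbr")}, cfg
        )
        wide = res.recall.pivot_table(
            index=["disease", "repetition"], columns="method", values="recall"
        )
        assert np.allclose(wide["m1"], wide["m2"])
        mrr = res.mrr_summary()
        assert np.allclose(mrr["mrr"], 1 / 1.5)  # permanently tied methods

    def test_disease_order_invariance(self, small_bench):
        net, diseases = small_bench
        cfg = CVConfig(repetitions=2, top_n_grid=(25,), rng_seed=9)
        methods = {"nbr": make_scorer("nbr"), "rwr": make_scorer("rwr")}
        a = run_cv(net, diseases[:3], methods, cfg).recall
        b = run_cv(net, diseases[:3][::-1], methods, cfg).recall
        pd.testing.assert_frame_equal(
            a.sort_values(list(a.columns)).reset_index(drop=True),
            b.sort_values(list(b.columns)).reset_index(drop=True),
        )

    def test_scores_blind_to_holdout_labels(self, small_bench):
        """Scorers see only the training seeds: re-scoring the same train set
        with a different holdout labelling is bit-identical."""
        net, diseases = small_bench
        train, holdout = split_seeds(diseases[0], 0.5, rng_seed=1)
        sv1 = qa_scores(net, train)
        other_holdout = SeedSet("d", frozenset(list(holdout.seed_indices)[:3]), net.n)
        sv2 = qa_scores(net, train)
        assert np.array_equal(sv1.scores, sv2.scores)
        r1 = rank_candidates(net, sv1, train, holdout)
        r2 = rank_candidates(net, sv2, train, other_holdout)
        assert np.array_equal(r1.ordered_nodes, r2.ordered_nodes)

    def test_failing_scorer_recorded_not_fatal(self, small_bench):
        net, diseases = small_bench

        def broken(net_, seeds_):
            raise RuntimeError("boom")

        cfg = CVConfig(repetitions=1, top_n_grid=(25,), rng_seed=0)
        res = run_cv(net, diseases[:1], {"ok": make_scorer("nbr"), "bad": broken}, cfg)
        assert len(res.failures) == 1 and res.failures[0][1] == "bad"
        assert set(res.recall["method"]) == {"ok"}


class TestEnrichment:
    def brute_force(self, k, list_size, reference_size, universe):
        """Exhaustive enumeration over all subsets of the universe."""
        genes = range(universe)
        ref = set(range(reference_size))
        hits = total = 0
        for subset in itertools.combinations(genes, list_size):
            total += 1
            if len(ref & set(subset)) >= k:
                hits += 1
        return hits / total

    def test_worked_example(self):
        res = hypergeometric_enrichment(3, 5, 4, 10)
        assert res.p_value == pytest.approx(66 / 252, abs=1e-12)

    def test_zero_overlap_and_forced_overlap(self):
        assert hypergeometric_enrichment(0, 5, 4, 10).p_value == 1.0
        assert hypergeometric_enrichment(3, 3, 3, 3).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "k,ls,rs,u",
        [(1, 3, 4, 10), (2, 5, 5, 12), (4, 6, 4, 11), (0, 2, 2, 8), (3, 4, 6, 9)],
    )
    def test_matches_exhaustive_enumeration(self, k, ls, rs, u):
        res = hypergeometric_enrichment(k, ls, rs, u)
        assert res.p_value == pytest.approx(self.brute_force(k, ls, rs, u), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InputFormatError):
            hypergeometric_enrichment(5, 3, 4, 10)
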