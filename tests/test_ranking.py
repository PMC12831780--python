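"""Unit and property tests for the pairwise fold-change Borda ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spheroid_ith import (
    OverlapPartition,
    aggregate_ranking,
    candidate_set,
    compare_lines,
    pairwise_log2fc,
    rank_proteins,
    top_k_per_pair,
    top_n_heatmap_matrix,
)
from spheroid_ith.ranking import PairwiseFCTable, TopKList
from conftest import make_matrix


def borda_oracle(values: pd.DataFrame, k: int):
    """Independent brute-force transcription of the ranking procedure:
    all pairwise |log2 FC|, top-k per pair with points k..1, summed."""
    points: dict[str, int] = {}
    n_lists: dict[str, int] = {}
    samples = list(values.columns)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            fc = (values[samples[i]] - values[samples[j]]).abs()
            ordered = sorted(values.index, key=lambda p: (-fc[p], p))[:k]
            for pos, pid in enumerate(ordered):
                points[pid] = points.get(pid, 0) + (k - pos)
                n_lists[pid] = n_lists.get(pid, 0) + 1
    order = sorted(points, key=lambda p: (-points[p], -n_lists[p], p))
    return [(p, points[p], n_lists[p]) for p in order]


class TestPairwiseLog2FC:
    def test_two_samples_single_difference(self):
        m = make_matrix([[10.0, 12.0]], scale="log2")
        fc = pairwise_log2fc(m)
        assert fc.pairs == [("S1", "S2")]
        assert fc.fc[0, 0] == -2.0

    def test_pair_count_is_n_choose_2(self):
        m = make_matrix(np.zeros((2, 16)), scale="log2")
        assert pairwise_log2fc(m).n_pairs == 120

    def test_antisymmetry_under_sample_reversal(self, tiny_log2_matrix):
        fwd = pairwise_log2fc(tiny_log2_matrix)
        rev = pairwise_log2fc(tiny_log2_matrix, tiny_log2_matrix.sample_ids[::-1])
        rev_map = {frozenset(p): rev.fc[:, c] for c, p in enumerate(rev.pairs)}
        for c, pair in enumerate(fwd.pairs):
            assert np.allclose(fwd.fc[:, c], -rev_map[frozenset(pair)])

    def test_fewer_than_two_samples_rejected(self):
        m = make_matrix([[1.0]], scale="log2")
        with pytest.raises(ValueError):
            pairwise_log2fc(m)

    def test_missing_values_rejected(self):
        m = make_matrix([[1.0, np.nan]], scale="log2")
        with pytest.raises(Exception, match="missing"):
            pairwise_log2fc(m)


class TestTopKPerPair:
    def _table(self, abs_fcs: dict[str, float]):
        pids = sorted(abs_fcs)
        fc = np.array([[abs_fcs[p]] for p in pids])
        return PairwiseFCTable(pids, [("S1", "S2")], fc)

    def test_hand_enumeration(self):
        fc = self._table({"P1": 5.0, "P2": 3.0, "P3": 1.0, "P4": 0.5})
        (lst,) = top_k_per_pair(fc, k=3)
        assert lst.entries == [("P1", 5.0, 3), ("P2", 3.0, 2), ("P3", 1.0, 1)]

    def test_tie_broken_by_protein_id(self):
        fc = self._table({"P9": 2.0, "P2": 2.0, "P5": 1.0})
        (lst,) = top_k_per_pair(fc, k=2)
        assert lst.protein_ids() == ["P2", "P9"]

    def test_k_at_least_population_lists_everything(self):
        fc = self._table({"P1": 3.0, "P2": 2.0, "P3": 1.0})
        (lst,) = top_k_per_pair(fc, k=10)
        assert len(lst.entries) == 3
        assert lst.entries[0][2] == 10  # best still gets k points
        assert lst.entries[-1][2] == 8

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            top_k_per_pair(self._table({"P1": 1.0}), k=0)


class TestAggregateRanking:
    def test_hand_summation(self):
        lists = [
            TopKList(("a", "b"), 3, [("P1", 9.0, 3), ("P2", 5.0, 2), ("P3", 1.0, 1)]),
            TopKList(("a", "c"), 3, [("P3", 8.0, 3), ("P1", 6.0, 2), ("P2", 2.0, 1)]),
        ]
        ranking = aggregate_ranking(lists)
        assert [(e.protein_id, e.total_points) for e in ranking] == [
            ("P1", 5), ("P3", 4), ("P2", 3),
        ]

    def test_single_list_is_identity(self):
        lst = TopKList(("a", "b"), 2, [("P1", 4.0, 2), ("P2", 1.0, 1)])
        ranking = aggregate_ranking([lst])
        assert [(e.protein_id, e.total_points, e.n_lists, e.rank) for e in ranking] == [
            ("P1", 2, 1, 1), ("P2", 1, 1, 2),
        ]

    def test_full_lists_sum_to_arithmetic_series(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(20, 2, (80, 6)), scale="log2")
        lists = top_k_per_pair(pairwise_log2fc(m), k=50)
        ranking = aggregate_ranking(lists)
        total = sum(e.total_points for e in ranking)
        assert total == 15 * 50 * 51 // 2  # C(6,2) pairs x k(k+1)/2


class TestCandidateSetAndOverlap:
    def test_single_pair_candidate_size_is_k(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(20, 2, (60, 2)), scale="log2")
        ranking = rank_proteins(m, k=50)
        assert len(candidate_set(ranking)) == 50

    def test_union_bound(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(20, 2, (30, 5)), scale="log2")
        ranking = rank_proteins(m, k=4)
        assert len(candidate_set(ranking)) <= min(30, 10 * 4)

    def test_published_overlap_arithmetic(self):
        shared = {f"C{i}" for i in range(186)}
        a = shared | {f"A{i}" for i in range(294 - 186)}
        b = shared | {f"B{i}" for i in range(308 - 186)}
        part = compare_lines(a, b)
        assert part.sizes == (108, 186, 122)

    def test_disjoint_and_identical_sets(self):
        assert compare_lines({"x"}, {"y"}).shared == frozenset()
        part = compare_lines({"x", "y"}, {"x", "y"})
        assert part.only_a == part.only_b == frozenset()


class TestHeatmapMatrix:
    def test_rank_order_and_zscore(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(20, 2, (40, 5)), scale="log2")
        ranking = rank_proteins(m, k=10)
        heat = top_n_heatmap_matrix(m, ranking, n=10)
        assert heat.shape == (10, 5)
        assert heat.protein_ids == [e.protein_id for e in ranking.top(10)]
        assert np.allclose(heat.values.to_numpy().mean(axis=1), 0.0, atol=1e-12)

    def test_n_exceeding_ranking_truncates(self, caplog):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(20, 2, (5, 3)), scale="log2")
        ranking = rank_proteins(m, k=5)
        with caplog.at_level("WARNING"):
            heat = top_n_heatmap_matrix(m, ranking, n=99)
        assert heat.shape[0] == len(ranking)


class TestOracleAndInvariance:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n_prot = rng.integers(5, 31)
        n_samp = rng.integers(2, 7)
        k = int(rng.integers(1, n_prot + 1))
        m = make_matrix(rng.normal(20, 2, (n_prot, n_samp)), scale="log2")
        ranking = rank_proteins(m, k=k)
        oracle = borda_oracle(m.values, k)
        assert [(e.protein_id, e.total_points, e.n_lists) for e in ranking] == oracle

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.permutations(list(range(5))))
    def test_sample_order_invariance(self, seed, perm):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(20, 1, (12, 5)), scale="log2")
        base = rank_proteins(m, k=5)
        shuffled = rank_proteins(m, [m.sample_ids[i] for i in perm], k=5)
        assert base == shuffled

    def test_driver_monotonicity(self):
        """Raising one protein's bimodal shift never lowers its points."""
        rng = np.random.default_rng(7)
        base = rng.normal(20, 0.3, (30, 8))
        prev_points = -1
        for shift in (0.5, 1.5, 3.0):
            vals = base.copy()
            vals[0, :4] += shift
            ranking = rank_proteins(make_matrix(vals, scale="log2"), k=5)
            pts = {e.protein_id: e.total_points for e in ranking}.get("P0001", 0)
            assert pts >= prev_points
            prev_points = pts
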