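"""Pairwise fold-change Borda ranking of heterogeneously expressed proteins.

This is the pipeline's central statistic. Within one cell line, log2 fold
changes are computed for every unordered pair of spheroid proteomes. For
each pair, the k proteins with the largest absolute fold change form a
"top-k list" and receive Borda points: k for the largest |FC| down to 1
for the k-th. Points are summed across all C(n, 2) lists; sorting by
total points yields the final ranking, and the union of all top-k lists
is the "candidate ITH-driver" set. Proteins whose abundance differs
strongly between spheroid subclones dominate many pairwise lists and
accumulate points, whereas homogeneously expressed proteins rarely enter
any list.

Ties (equal |FC| at the list boundary, equal total points) are broken by
ascending protein id so results are deterministic and invariant to the
sample order of the input matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ProteinMatrix, RankedEntry, RankedProteinList, ValidationError
from .preprocess import zscore_rows

__all__ = [
    "PairwiseFCTable",
    "TopKList",
    "OverlapPartition",
    "pairwise_log2fc",
    "top_k_per_pair",
    "aggregate_ranking",
    "rank_proteins",
    "candidate_set",
    "compare_lines",
    "top_n_heatmap_matrix",
    "DEFAULT_K",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 50


@dataclass
class PairwiseFCTable:
    """Log2 fold changes for every unordered sample pair.

    ``fc`` has one row per protein and one column per pair; only the
    (i, j) orientation with i before j in matrix order is stored, since
    FC(j, i) = -FC(i, j) and the ranking uses |FC| only.
    """

    protein_ids: list[str]
    pairs: list[tuple[str, str]]
    fc: np.ndarray

    def __post_init__(self):
        if self.fc.shape != (len(self.protein_ids), len(self.pairs)):
            raise ValidationError(
                f"fc shape {self.fc.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.pairs)} pairs"
            )
        if not np.all(np.isfinite(self.fc)):
            raise ValidationError("fold changes must be finite")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_dataframe(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.pairs, names=["sample_i", "sample_j"])
        return pd.DataFrame(self.fc, index=self.protein_ids, columns=cols)


@dataclass
class TopKList:
    """One pair's top-k absolute-fold-change list with Borda points.

    ``entries`` are (protein_id, abs_fc, points) ordered by descending
    |FC|; points run from k (best) downward, so a full-length list ends
    at 1 point.
    """

    pair: tuple[str, str]
    k: int
    entries: list[tuple[str, float, int]]

    def __post_init__(self):
        abs_fcs = [e[1] for e in self.entries]
        if any(b > a for a, b in zip(abs_fcs, abs_fcs[1:])):
            raise ValidationError("abs_fc must be non-increasing")
        expected = list(range(self.k, self.k - len(self.entries), -1))
        if [e[2] for e in self.entries] != expected:
            raise ValidationError("points must decrease stepwise from k")

    def protein_ids(self) -> list[str]:
        return [e[0] for e in self.entries]


@dataclass(frozen=True)
class OverlapPartition:
    """Venn partition of two candidate sets: shared and line-specific."""

    shared: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.only_a), len(self.shared), len(self.only_b)


def pairwise_log2fc(
    matrix: ProteinMatrix, sample_ids: Sequence[str] | None = None
) -> PairwiseFCTable:
    """Log2 fold change for every unordered sample pair and every protein.

    The matrix must be log2-scaled and complete over the selected samples
    (run the preprocessing filters first); the fold change is simply the
    difference of log2 intensities.
    """
    if matrix.scale != "log2":
        raise ValidationError("pairwise_log2fc expects a log2-scaled matrix")
    if sample_ids is not None:
        matrix = matrix.subset_samples(sample_ids)
    samples = matrix.sample_ids
    if len(samples) < 2:
        raise ValueError(f"need at least 2 samples, got {len(samples)}")
    arr = matrix.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("missing values encountered; filter the matrix first")
    idx_pairs = list(combinations(range(len(samples)), 2))
    fc = np.empty((arr.shape[0], len(idx_pairs)), dtype=float)
    for col, (i, j) in enumerate(idx_pairs):
        fc[:, col] = arr[:, i] - arr[:, j]
    pairs = [(samples[i], samples[j]) for i, j in idx_pairs]
    return PairwiseFCTable(matrix.protein_ids, pairs, fc)


def top_k_per_pair(fc_table: PairwiseFCTable, k: int = DEFAULT_K) -> list[TopKList]:
    """Per pair, the k proteins with the largest |FC|, with Borda points.

    Proteins are sorted by descending absolute fold change, ties broken by
    ascending protein id; the best protein receives k points, decreasing
    stepwise. When fewer than k proteins exist the points still start at k
    (cross-pair comparability), ending above 1.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if fc_table.n_pairs == 0:
        raise ValueError("fold-change table has no pairs")
    pids = np.array(fc_table.protein_ids)
    abs_fc = np.abs(fc_table.fc)
    lists: list[TopKList] = []
    for col, pair in enumerate(fc_table.pairs):
        # lexsort: primary key last -> descending |FC|, then ascending id
        order = np.lexsort((pids, -abs_fc[:, col]))[: min(k, len(pids))]
        entries = [
            (str(pids[row]), float(abs_fc[row, col]), k - pos)
            for pos, row in enumerate(order)
        ]
        lists.append(TopKList(pair=pair, k=k, entries=entries))
    return lists


def aggregate_ranking(lists: Sequence[TopKList]) -> RankedProteinList:
    """Sum Borda points across all top-k lists into a final ranking.

    total_points is the sum of points over every list a protein appears
    in; n_lists counts those appearances. Sorting is by descending total
    points, then descending n_lists, then ascending protein id, with
    ranks 1..N.
    """
    if not lists:
        raise ValueError("need at least one top-k list")
    points: dict[str, int] = {}
    n_lists: dict[str, int] = {}
    for tkl in lists:
        for pid, _, pts in tkl.entries:
            points[pid] = points.get(pid, 0) + pts
            n_lists[pid] = n_lists.get(pid, 0) + 1
    order = sorted(points, key=lambda p: (-points[p], -n_lists[p], p))
    entries = [
        RankedEntry(protein_id=p, total_points=points[p], n_lists=n_lists[p], rank=r)
        for r, p in enumerate(order, start=1)
    ]
    return RankedProteinList(entries, n_pairs=len(lists))


def rank_proteins(
    matrix: ProteinMatrix,
    sample_ids: Sequence[str] | None = None,
    k: int = DEFAULT_K,
) -> RankedProteinList:
    """Convenience composite: pairwise FCs -> top-k lists -> Borda ranking."""
    return aggregate_ranking(top_k_per_pair(pairwise_log2fc(matrix, sample_ids), k))


def candidate_set(ranking: RankedProteinList, min_points: int = 1) -> frozenset[str]:
    """Candidate ITH-driver proteins: everything that entered any top-k list.

    By default no further cutoff is applied (the union of all per-pair
    lists); ``min_points`` optionally requires a higher total.
    """
    return frozenset(e.protein_id for e in ranking if e.total_points >= min_points)


def compare_lines(candidates_a: set[str], candidates_b: set[str]) -> OverlapPartition:
    """Partition two candidate sets into shared and line-specific proteins."""
    a, b = frozenset(candidates_a), frozenset(candidates_b)
    return OverlapPartition(shared=a & b, only_a=a - b, only_b=b - a)


def top_n_heatmap_matrix(
    matrix: ProteinMatrix, ranking: RankedProteinList, n: int = 10
) -> ProteinMatrix:
    """Row-wise Z-scored submatrix of the top-n ranked proteins, rank order."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n > len(ranking):
        logger.warning("n=%d exceeds ranking length %d; truncating", n, len(ranking))
        n = len(ranking)
    top_ids = [e.protein_id for e in ranking.top(n)]
    return zscore_rows(matrix.subset_proteins(top_ids))
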