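"""PCA clustering of spheroid proteomes and single-sample GSEA scoring.

The ssGSEA score of one sample for one gene set is the sum, over the
gene ranking of that sample (descending expression), of the difference
between the weighted empirical cumulative distribution function of the
in-set genes and the unweighted ECDF of all remaining genes. In-set
steps are weighted by the ranked value raised to a configurable exponent
(0.25 by default, the literature convention; 0 gives a purely rank-based
score). Positive scores indicate the set's genes concentrate at the top
of the sample's expression ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .datatypes import GeneSetCollection, ProteinMatrix, ValidationError

__all__ = [
    "PCAResult",
    "SsgseaScores",
    "pca",
    "rank_normalize",
    "ssgsea_score",
    "ssgsea_score_matrix",
    "top_pathways",
    "DEFAULT_WEIGHT_EXPONENT",
]

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_EXPONENT = 0.25


@dataclass
class PCAResult:
    """Sample scores, explained-variance fractions and protein loadings."""

    scores: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame  # proteins x components

    def __post_init__(self):
        frac = self.explained_variance_fraction
        if np.any(np.diff(frac) > 1e-12):
            raise ValidationError("explained fractions must be non-increasing")
        if frac.sum() > 1 + 1e-9:
            raise ValidationError("explained fractions sum above 1")


@dataclass
class SsgseaScores:
    """Per-(sample, gene set) enrichment scores with scoring parameters."""

    scores: pd.DataFrame  # sets x samples
    weight_exponent: float
    rank_normalized: bool
    minmax_normalized: bool = False


def pca(matrix: ProteinMatrix, n_components: int) -> PCAResult:
    """Project samples onto the principal axes of protein space.

    Proteins are mean-centred; the matrix must be complete and
    log2-scaled. The sign of each component is fixed so that its
    largest-magnitude protein loading is positive, making results
    deterministic.
    """
    if matrix.values.isna().any().any():
        raise ValidationError("PCA expects a complete matrix")
    n_samples, n_proteins = matrix.shape[1], matrix.shape[0]
    if n_components > min(n_samples, n_proteins):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, proteins)="
            f"{min(n_samples, n_proteins)}"
        )
    X = matrix.values.to_numpy(dtype=float).T  # samples x proteins
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # proteins x components
    for c in range(loadings.shape[1]):
        peak = np.argmax(np.abs(loadings[:, c]))
        if loadings[peak, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings, index=matrix.protein_ids, columns=comp_names),
    )


def rank_normalize(profile: pd.Series) -> pd.Series:
    """Replace values by average ranks scaled to (0, 1]."""
    values = profile.to_numpy(dtype=float)
    ranks = stats.rankdata(values) / len(values)
    return pd.Series(ranks, index=profile.index, name=profile.name)


def ssgsea_score(
    profile: pd.Series,
    gene_set: Iterable[str],
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> float:
    """Weighted-ECDF enrichment score of one gene set in one sample.

    Genes are ranked by descending value (ties broken by gene name for
    determinism). The running in-set ECDF weights each in-set gene by
    |value|^weight_exponent (normalised to 1 in total); the out-set ECDF
    steps uniformly. The score is the sum of the pointwise differences.
    """
    if weight_exponent < 0:
        raise ValueError("weight exponent must be >= 0")
    genes = profile.index
    in_set = genes.isin(set(gene_set))
    n_in = int(in_set.sum())
    n_out = len(genes) - n_in
    if n_in == 0:
        raise ValidationError("gene set does not intersect the profile")
    if n_out == 0:
        raise ValidationError("gene set covers every profiled gene; "
                              "out-set ECDF undefined")
    order = np.lexsort((np.asarray(genes), -profile.to_numpy(dtype=float)))
    values = profile.to_numpy(dtype=float)[order]
    hits = np.asarray(in_set)[order]

    weights = np.where(hits, np.abs(values) ** weight_exponent, 0.0)
    total_w = weights.sum()
    if total_w == 0:  # all in-set values are 0; fall back to uniform steps
        weights = hits.astype(float)
        total_w = weights.sum()
    in_cdf = np.cumsum(weights) / total_w
    out_cdf = np.cumsum(~hits) / n_out
    return float(np.sum(in_cdf - out_cdf))


def ssgsea_score_matrix(
    expression: pd.DataFrame,
    collection: GeneSetCollection,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    rank_norm: bool = True,
    minmax: bool = False,
) -> SsgseaScores:
    """Score every gene set in every sample of a gene x sample table.

    Expression values are rank-normalised per sample by default (ranks
    scaled to (0, 1], matching absolute-expression rank normalisation)
    before the weighted-ECDF score is computed. Sets with no profiled
    gene are skipped with a warning. ``minmax`` optionally rescales each
    set's scores to [0, 1] across samples.
    """
    rows = {}
    for name, genes in collection.items():
        if not expression.index.isin(genes).any():
            logger.warning("gene set %r has no gene in the profile; skipped", name)
            continue
        row = {}
        for sample in expression.columns:
            profile = expression[sample]
            if rank_norm:
                profile = rank_normalize(profile)
            row[sample] = ssgsea_score(profile, genes, weight_exponent)
        rows[name] = row
    scores = pd.DataFrame.from_dict(rows, orient="index")
    if not scores.empty:
        scores = scores.loc[:, list(expression.columns)]
    if minmax and not scores.empty:
        rng = scores.max(axis=1) - scores.min(axis=1)
        rng = rng.replace(0, 1.0)
        scores = scores.sub(scores.min(axis=1), axis=0).div(rng, axis=0)
    return SsgseaScores(
        scores=scores,
        weight_exponent=weight_exponent,
        rank_normalized=rank_norm,
        minmax_normalized=minmax,
    )


def top_pathways(
    scores: SsgseaScores,
    n: int = 30,
    groups: Mapping[str, Sequence[str]] | None = None,
    collection: GeneSetCollection | None = None,
    redundancy_overlap: float = 0.9,
) -> pd.DataFrame:
    """The n most differentially represented gene sets.

    With ``groups`` = {name: sample ids} for two groups, sets are ordered
    by the absolute difference of group-mean scores; otherwise by the
    absolute score spread (max - min) across samples. When a
    :class:`GeneSetCollection` is supplied, redundant sets (gene-content
    overlap coefficient >= ``redundancy_overlap`` with a higher-ranked
    set) are collapsed, keeping the higher-scoring one.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = scores.scores
    if df.empty:
        return pd.DataFrame(columns=["pathway", "criterion"])
    if groups is not None:
        if len(groups) != 2:
            raise ValueError("groups must name exactly two sample groups")
        (ga, sa), (gb, sb) = groups.items()
        crit = (df[list(sa)].mean(axis=1) - df[list(sb)].mean(axis=1)).abs()
    else:
        crit = df.max(axis=1) - df.min(axis=1)
    ordered = crit.sort_values(ascending=False, kind="stable")
    ordered = ordered.loc[sorted(ordered.index, key=lambda s: (-ordered[s], s))]

    kept: list[str] = []
    if collection is not None:
        members = {name: set(collection[name]) for name in ordered.index
                   if name in collection.sets}
        for name in ordered.index:
            genes = members.get(name, set())
            redundant = any(
                genes and members.get(k)
                and len(genes & members[k]) / min(len(genes), len(members[k]))
                >= redundancy_overlap
                for k in kept
            )
            if not redundant:
                kept.append(name)
            if len(kept) == n:
                break
    else:
        kept = list(ordered.index[:n])
    return pd.DataFrame(
        {"pathway": kept, "criterion": [float(ordered[k]) for k in kept]}
    )
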