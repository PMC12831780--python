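"""Matrix preprocessing: log2 transform, depth and complete-case filters,
row-wise Z-scoring.

The filtering strategy mirrors the study workflow for label-free DIA
protein-group matrices: samples with too few quantified proteins are
excluded first (default threshold 2500, chosen to guarantee sufficient
proteome depth), then proteins with any remaining missing intensity are
removed so that downstream fold-change statistics operate on a
complete-case matrix. No value is ever imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ProteinMatrix, ValidationError

__all__ = [
    "PreprocessReport",
    "log2_transform",
    "count_quantified",
    "filter_low_depth_samples",
    "filter_incomplete_proteins",
    "zscore_rows",
    "preprocess_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_PROTEINS = 2500


@dataclass
class PreprocessReport:
    """Bookkeeping for one filtering step (or a composite of steps)."""

    n_proteins_in: int
    n_proteins_out: int
    n_samples_in: int
    n_samples_out: int
    excluded_samples: dict[str, int] = field(default_factory=dict)
    depth_threshold: int | None = None

    def __post_init__(self):
        if self.n_proteins_out > self.n_proteins_in:
            raise ValidationError("protein out-count exceeds in-count")
        if self.n_samples_out > self.n_samples_in:
            raise ValidationError("sample out-count exceeds in-count")
        if self.depth_threshold is not None:
            for sid, count in self.excluded_samples.items():
                if count >= self.depth_threshold:
                    raise ValidationError(
                        f"excluded sample {sid!r} has count {count} >= "
                        f"threshold {self.depth_threshold}"
                    )


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """Base-2 logarithm of every present intensity; missing mask unchanged."""
    if matrix.scale == "log2":
        logger.warning("matrix already log2-scaled; returning unchanged")
        return matrix
    arr = matrix.values.to_numpy(dtype=float)
    bad = np.isfinite(arr) & (arr <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-positive intensity at protein {matrix.protein_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}"
        )
    values = pd.DataFrame(
        np.log2(arr), index=matrix.values.index, columns=matrix.values.columns
    )
    return ProteinMatrix(values, scale="log2", gene_names=matrix.gene_names)


def count_quantified(matrix: ProteinMatrix) -> pd.Series:
    """Number of non-missing protein quantifications per sample."""
    return matrix.values.notna().sum(axis=0).astype(int)


def filter_low_depth_samples(
    matrix: ProteinMatrix, min_proteins: int = DEFAULT_MIN_PROTEINS
) -> tuple[ProteinMatrix, PreprocessReport]:
    """Drop samples quantifying fewer than ``min_proteins`` proteins."""
    counts = count_quantified(matrix)
    keep = [s for s in matrix.sample_ids if counts[s] >= min_proteins]
    excluded = {s: int(counts[s]) for s in matrix.sample_ids if counts[s] < min_proteins}
    if not keep:
        raise ValidationError(
            f"all {len(matrix.sample_ids)} samples fall below the depth "
            f"threshold {min_proteins}; review the threshold"
        )
    out = matrix.subset_samples(keep)
    report = PreprocessReport(
        n_proteins_in=matrix.shape[0],
        n_proteins_out=out.shape[0],
        n_samples_in=matrix.shape[1],
        n_samples_out=out.shape[1],
        excluded_samples=excluded,
        depth_threshold=min_proteins,
    )
    if excluded:
        logger.info(
            "excluded %d sample(s) below depth threshold %d: %s",
            len(excluded), min_proteins, excluded,
        )
    return out, report


def filter_incomplete_proteins(
    matrix: ProteinMatrix,
) -> tuple[ProteinMatrix, PreprocessReport]:
    """Keep only proteins quantified in every retained sample."""
    complete = matrix.values.notna().all(axis=1)
    keep = [p for p, ok in zip(matrix.protein_ids, complete) if ok]
    if not keep:
        logger.warning("no protein is complete across all samples; empty result")
    genes = matrix.gene_names.loc[keep] if matrix.gene_names is not None else None
    out = ProteinMatrix(matrix.values.loc[keep], matrix.scale, genes)
    report = PreprocessReport(
        n_proteins_in=matrix.shape[0],
        n_proteins_out=out.shape[0],
        n_samples_in=matrix.shape[1],
        n_samples_out=out.shape[1],
    )
    return out, report


def zscore_rows(matrix: ProteinMatrix) -> ProteinMatrix:
    """Row-wise Z-score (sample SD, ddof=1) of a complete log2 matrix.

    Constant rows map to all-zero with a warning — the heatmap convention.
    """
    if matrix.scale != "log2":
        raise ValidationError("zscore_rows expects a log2-scaled matrix")
    if matrix.values.isna().any().any():
        raise ValidationError("zscore_rows expects a complete matrix (no missing values)")
    arr = matrix.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True) if arr.shape[1] > 1 else np.zeros_like(mean)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("%d constant row(s) mapped to zeros", int(constant.sum()))
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (arr - mean) / safe_sd
    z[constant, :] = 0.0
    values = pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)
    return ProteinMatrix(values, scale="log2", gene_names=matrix.gene_names)


def preprocess_matrix(
    matrix: ProteinMatrix,
    min_proteins: int = DEFAULT_MIN_PROTEINS,
    samples_first: bool = True,
) -> tuple[ProteinMatrix, PreprocessReport]:
    """Composite pipeline: log2 transform, depth filter, complete-case filter.

    Samples are filtered before proteins by default so that a protein
    missing only in low-depth samples is rescued; the order is
    configurable. The composite is idempotent.
    """
    if matrix.scale == "raw":
        matrix = log2_transform(matrix)
    n_proteins_in, n_samples_in = matrix.shape
    if samples_first:
        matrix, depth_report = filter_low_depth_samples(matrix, min_proteins)
        out, _ = filter_incomplete_proteins(matrix)
    else:
        matrix, _ = filter_incomplete_proteins(matrix)
        out, depth_report = filter_low_depth_samples(matrix, min_proteins)
    report = PreprocessReport(
        n_proteins_in=n_proteins_in,
        n_proteins_out=out.shape[0],
        n_samples_in=n_samples_in,
        n_samples_out=out.shape[1],
        excluded_samples=depth_report.excluded_samples,
        depth_threshold=min_proteins,
    )
    return out, report
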