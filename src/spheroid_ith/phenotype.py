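"""Phenotype statistics for spheroid cohorts.

Covers the diameter-related metabolic activity (DMA = viability / diameter,
RLU/µm — a per-size-unit ATP readout separating metabolic heterogeneity
from sheer cell number), morphology contingency analysis between two cell
lines (Fisher's exact test per attribute), distribution comparisons
(Shapiro normality check followed by a two-sample Kolmogorov-Smirnov
test), coefficient of variation, and ordinary least-squares
diameter-viability regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import (
    ContingencyTable2x2,
    MORPHOLOGY_LEVELS,
    SpheroidCohort,
    ValidationError,
)

__all__ = [
    "TestResult",
    "RegressionResult",
    "AttributeComparison",
    "dma",
    "fisher_exact_2x2",
    "compare_distributions",
    "linear_fit",
    "coefficient_of_variation",
    "table1_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self):
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValidationError(f"R^2 out of [0, 1]: {self.r_squared}")
        if self.n < 2:
            raise ValidationError("regression needs n >= 2")


@dataclass(frozen=True)
class AttributeComparison:
    """One morphology attribute's 2x2 table, per-line percentages and test."""

    attribute: str
    levels: tuple[str, str]
    table: ContingencyTable2x2
    percent_a: float  # frequency of the first level in line A, percent
    percent_b: float
    test: TestResult


def dma(viability_rlu: float, diameter_um: float) -> float:
    """Diameter-related metabolic activity: viability / diameter (RLU/µm)."""
    if not (diameter_um > 0):
        raise ValidationError(f"diameter must be > 0, got {diameter_um}")
    if viability_rlu < 0:
        raise ValidationError(f"viability must be >= 0, got {viability_rlu}")
    return viability_rlu / diameter_um


def fisher_exact_2x2(
    table: ContingencyTable2x2, alternative: str = "two-sided"
) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Uses the conventional point-probability definition: the p-value sums
    hypergeometric probabilities of all tables (with the observed margins)
    no more probable than the observed one. A zero row or column margin
    makes the table degenerate; p = 1 is returned with a warning.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table (zero margin); p = 1")
        odds = float("nan")
        return TestResult(
            statistic=odds,
            p_value=1.0,
            method="fisher_exact",
            n_per_group=(int(arr[:, 0].sum()), int(arr[:, 1].sum())),
        )
    res = stats.fisher_exact(arr, alternative=alternative)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="fisher_exact",
        n_per_group=(int(arr[:, 0].sum()), int(arr[:, 1].sum())),
    )


def compare_distributions(x, y) -> TestResult:
    """Shapiro normality per sample, then a two-sample KS test.

    The Shapiro p-values are reported in ``details`` but do not gate the
    KS comparison, which is run regardless of the normality outcome.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    shapiro_x = stats.shapiro(x)
    shapiro_y = stats.shapiro(y)
    ks = stats.ks_2samp(x, y, method="auto")
    return TestResult(
        statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        method="ks_2samp",
        n_per_group=(len(x), len(y)),
        details={
            "shapiro_p_x": float(shapiro_x.pvalue),
            "shapiro_p_y": float(shapiro_y.pvalue),
        },
    )


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x; R^2 = squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("regression needs n >= 2")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; regression is degenerate")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n=len(x),
    )


def coefficient_of_variation(x) -> float:
    """Sample coefficient of variation: SD (ddof=1) / mean."""
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValidationError("coefficient of variation undefined for zero mean")
    if len(x) < 2:
        return 0.0
    return float(x.std(ddof=1) / mean)


def table1_report(
    cohort: SpheroidCohort, line_a: str | None = None, line_b: str | None = None
) -> list[AttributeComparison]:
    """Morphology comparison between two cell lines, one row per attribute.

    For each attribute (shape, clustering, budding, margin) a 2x2 table is
    built with rows = attribute levels and columns = cell lines, the
    first-level frequency per line is reported as a percentage (one
    decimal is the display convention), and a two-sided Fisher's exact
    test is run. Records with a missing attribute are excluded from that
    attribute only; attributes absent from the cohort are skipped with a
    warning.
    """
    lines = cohort.cell_lines
    if line_a is None or line_b is None:
        if len(lines) != 2:
            raise ValueError(
                f"cohort has {len(lines)} cell line(s); specify line_a and line_b"
            )
        line_a, line_b = lines
    out: list[AttributeComparison] = []
    for attr, levels in MORPHOLOGY_LEVELS.items():
        counts = {(lv, ln): 0 for lv in levels for ln in (line_a, line_b)}
        n_scored = 0
        for rec in cohort:
            val = getattr(rec, attr)
            if val is None or rec.cell_line not in (line_a, line_b):
                continue
            counts[(val, rec.cell_line)] += 1
            n_scored += 1
        if n_scored == 0:
            logger.warning("attribute %r not scored in cohort; skipped", attr)
            continue
        table = ContingencyTable2x2(
            a=counts[(levels[0], line_a)],
            b=counts[(levels[0], line_b)],
            c=counts[(levels[1], line_a)],
            d=counts[(levels[1], line_b)],
        )
        pct_a, pct_b = table.column_percentages()
        out.append(
            AttributeComparison(
                attribute=attr,
                levels=levels,
                table=table,
                percent_a=pct_a,
                percent_b=pct_b,
                test=fisher_exact_2x2(table),
            )
        )
    return out
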