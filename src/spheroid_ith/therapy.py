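"""5-FU therapy-response analysis.

Four-parameter logistic (4PL) dose-response fitting for IC50
determination, percent viability reduction of treated vs control
spheroids, an exact Wilcoxon matched-pairs signed-rank test (full
sign-flip enumeration at small n), and the size-resistance regression of
post-treatment viability on spheroid diameter.

The 4PL model is

    viability(dose) = bottom + (top - bottom) / (1 + (dose / IC50)^hill)

with dose on the natural concentration scale; a zero dose contributes
exactly the top asymptote (no log transform is applied to doses), and
IC50 is constrained positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datatypes import DoseResponseTable, SpheroidCohort, ValidationError
from .phenotype import RegressionResult, TestResult, linear_fit

__all__ = [
    "FourPLFit",
    "four_pl",
    "fit_ic50",
    "fit_ic50_per_spheroid",
    "percent_reduction",
    "signed_rank_exact",
    "resistance_size_regression",
    "EXACT_ENUMERATION_MAX_N",
]

logger = logging.getLogger(__name__)

#: Largest sample size for which the signed-rank null distribution is
#: enumerated exactly; the normal approximation with continuity
#: correction is used above this.
EXACT_ENUMERATION_MAX_N = 25


@dataclass(frozen=True)
class FourPLFit:
    top: float
    bottom: float
    ic50_uM: float
    hill_slope: float
    rss: float
    n_points: int

    def __post_init__(self):
        if not (self.ic50_uM > 0):
            raise ValidationError(f"fitted IC50 must be > 0, got {self.ic50_uM}")

    def predict(self, dose_uM) -> np.ndarray:
        return four_pl(np.asarray(dose_uM, dtype=float),
                       self.top, self.bottom, self.ic50_uM, self.hill_slope)


def four_pl(dose, top, bottom, ic50, hill) -> np.ndarray:
    """Four-parameter logistic response; dose 0 returns the top asymptote."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_ic50(data: DoseResponseTable, weighting: str = "relative") -> FourPLFit:
    """Least-squares 4PL fit of viability against dose.

    Initial values come from the data: the mean viability at the lowest
    and highest dose seed the top and bottom asymptotes, the geometric
    mid-range of the positive doses seeds the IC50, and the Hill slope
    starts at 1. IC50 and the Hill slope are bounded positive.

    ``weighting='relative'`` (default) weights residuals by 1/viability,
    matching the multiplicative error of luminescence viability assays
    and avoiding the IC50 bias an unweighted fit shows under such noise;
    ``weighting='none'`` gives the ordinary unweighted fit.
    """
    if weighting not in ("relative", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    df = data.to_dataframe()
    doses = np.sort(df["dose_uM"].unique())
    if len(doses) < 4:
        raise ValueError(f"need >= 4 distinct doses for a 4PL fit, got {len(doses)}")
    d = df["dose_uM"].to_numpy(dtype=float)
    v = df["viability_rlu"].to_numpy(dtype=float)

    means = df.groupby("dose_uM")["viability_rlu"].mean()
    if means.reindex(doses).is_monotonic_increasing:
        logger.warning("mean viability increases with dose: no inhibition apparent")

    top0 = float(means.loc[doses[0]])
    bottom0 = float(means.loc[doses[-1]])
    positive = doses[doses > 0]
    ic50_0 = float(np.exp(np.mean(np.log(positive))))
    p0 = [max(top0, 1e-9), max(bottom0, 0.0), ic50_0, 1.0]
    bounds = ([0.0, 0.0, 1e-9, 0.05], [np.inf, np.inf, np.inf, 20.0])
    sigma = None
    if weighting == "relative" and np.max(v) > 0:
        sigma = np.clip(v, np.max(v) * 1e-3, None)
    try:
        popt, _ = optimize.curve_fit(
            four_pl, d, v, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"4PL fit failed to converge (p0={p0}, {len(d)} points): {exc}"
        ) from exc
    top, bottom, ic50, hill = (float(x) for x in popt)
    rss = float(np.sum((v - four_pl(d, *popt)) ** 2))
    return FourPLFit(top=top, bottom=bottom, ic50_uM=ic50, hill_slope=hill,
                     rss=rss, n_points=len(d))


def fit_ic50_per_spheroid(
    data: DoseResponseTable, weighting: str = "relative"
) -> dict[str, FourPLFit]:
    """Independent 4PL fit for each spheroid's own dose curve."""
    out: dict[str, FourPLFit] = {}
    for sid, sub in data.to_dataframe().groupby("spheroid_id", sort=True):
        out[str(sid)] = fit_ic50(DoseResponseTable.from_dataframe(sub), weighting)
    return out


def percent_reduction(treated_mean: float, control_mean: float) -> float:
    """Percent viability reduction of treated relative to control.

    100 * (control - treated) / control; negative when treated exceeds
    control.
    """
    if not (control_mean > 0):
        raise ValidationError(f"control mean must be > 0, got {control_mean}")
    return 100.0 * (control_mean - treated_mean) / control_mean


def signed_rank_exact(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (their count is reported). For n up to
    ``EXACT_ENUMERATION_MAX_N`` the null distribution of the
    positive-rank sum W+ is enumerated exactly over all 2^n sign
    assignments (ties handled with average ranks); beyond that, a normal
    approximation with continuity and tie corrections is used. The
    two-sided p is twice the smaller tail, capped at 1.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one difference")
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    if d.size == 0:
        logger.warning("all differences are zero; p = 1")
        return TestResult(statistic=0.0, p_value=1.0, method="wilcoxon_signed_rank",
                          n_per_group=(0,), details={"n_zero_dropped": n_zero})
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_ENUMERATION_MAX_N:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "wilcoxon_signed_rank_exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        # continuity correction toward the mean
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "wilcoxon_signed_rank_normal"
    return TestResult(statistic=w_plus, p_value=p, method=method,
                      n_per_group=(n,), details={"n_zero_dropped": n_zero})


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by dynamic programming over the 2^n sign flips.

    Ranks are doubled so that average ranks from ties become integers;
    the distribution of 2*W+ is then the convolution of (1 + x^(2r)).
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_assign = counts.sum()  # 2^n
    w2 = int(np.rint(2 * w_plus))
    cdf_le = counts[: w2 + 1].sum() / n_assign
    cdf_ge = counts[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(cdf_le, cdf_ge)))


def resistance_size_regression(
    cohort: SpheroidCohort, cell_line: str | None = None
) -> RegressionResult:
    """OLS of post-treatment viability on diameter among treated spheroids.

    A positive slope with appreciable R^2 indicates size-dependent
    therapy resistance (larger spheroids retaining more viability under
    treatment).
    """
    records = [
        r for r in cohort
        if r.arm == "treated" and r.viability_rlu is not None
        and (cell_line is None or r.cell_line == cell_line)
    ]
    lines = {r.cell_line for r in records}
    if cell_line is None and len(lines) > 1:
        raise ValueError(
            f"treated spheroids span {len(lines)} cell lines; pass cell_line"
        )
    if len(records) < 3:
        raise ValueError(f"need >= 3 treated spheroids, got {len(records)}")
    x = [r.diameter_um for r in records]
    y = [r.viability_rlu for r in records]
    return linear_fit(x, y)
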