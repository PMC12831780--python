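import numpy as np
import pandas as pd
import pytest

from spheroid_ith import (
    ProteinMatrix,
    SpheroidCohort,
    SpheroidRecord,
)


def make_matrix(values, proteins=None, samples=None, scale="raw", genes=None):
    """Build a ProteinMatrix from a nested list / array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i + 1:04d}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    gene_series = (
        pd.Series(genes, index=proteins, name="gene_name") if genes else None
    )
    return ProteinMatrix(
        pd.DataFrame(arr, index=proteins, columns=samples),
        scale=scale,
        gene_names=gene_series,
    )


def table1_cohort():
    """Cohort whose morphology counts equal the published two-line table:
    shape round 15/28 vs 4/45, clustering compact 23/28 vs 20/45,
    budding yes 18/28 vs 23/45, margin sharp 19/28 vs 17/45."""
    counts = {
        "LINE_A": {"n": 28, "shape": 15, "clustering": 23, "budding": 18, "margin": 19},
        "LINE_B": {"n": 45, "shape": 4, "clustering": 20, "budding": 23, "margin": 17},
    }
    levels = {
        "shape": ("round", "diffuse"),
        "clustering": ("compact", "loose"),
        "budding": ("yes", "no"),
        "margin": ("sharp", "blurred"),
    }
    records = []
    for line, c in counts.items():
        for i in range(c["n"]):
            attrs = {
                attr: levels[attr][0] if i < c[attr] else levels[attr][1]
                for attr in levels
            }
            records.append(
                SpheroidRecord(
                    spheroid_id=f"{line}-{i:02d}",
                    cell_line=line,
                    diameter_um=100.0 + i,
                    **attrs,
                )
            )
    return SpheroidCohort(records)


@pytest.fixture
def tiny_log2_matrix():
    return make_matrix(
        [[10.0, 12.0, 11.0], [8.0, 8.5, 7.5], [14.0, 14.0, 14.1]],
        scale="log2",
    )


@pytest.fixture
def cohort_two_lines():
    return table1_cohort()
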