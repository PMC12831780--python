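"""Core domain types for the spheroid ITH pipeline.

The in-memory containers mirror the artefacts of a single-cell-derived
spheroid study: a phenotype cohort table (one row per spheroid), a
protein-group intensity matrix (proteins x samples, DIA label-free
quantification), gene-set collections for enrichment scoring, ranked
protein lists produced by the fold-change Borda aggregation, 2x2
contingency tables for morphology comparisons, and dose-response records
for chemotherapy testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SpheroidRecord",
    "SpheroidCohort",
    "ProteinMatrix",
    "GeneSetCollection",
    "RankedEntry",
    "RankedProteinList",
    "ContingencyTable2x2",
    "DoseResponseTable",
    "MORPHOLOGY_LEVELS",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


#: Allowed levels for each manually scored morphology attribute, the first
#: level being the one whose counts appear in contingency-table row one.
MORPHOLOGY_LEVELS: dict[str, tuple[str, str]] = {
    "shape": ("round", "diffuse"),
    "clustering": ("compact", "loose"),
    "budding": ("yes", "no"),
    "margin": ("sharp", "blurred"),
}

_ARM_LEVELS = ("control", "treated")


def _normalize_enum(value, levels: tuple[str, ...], name: str):
    if value is None:
        return None
    token = str(value).strip().lower()
    if token in ("", "na", "nan"):
        return None
    if token not in levels:
        raise ValidationError(
            f"invalid {name} value {value!r}; expected one of {levels}"
        )
    return token


@dataclass(frozen=True)
class SpheroidRecord:
    """Phenotype of one single-cell-derived spheroid.

    diameter_um is the maximum diameter for irregular spheroids;
    viability_rlu is the ATP-assay luminescence readout (relative light
    units). Morphology attributes are manual classifications; any of them
    may be absent.
    """

    spheroid_id: str
    cell_line: str
    diameter_um: float
    viability_rlu: float | None = None
    shape: str | None = None
    clustering: str | None = None
    budding: str | None = None
    margin: str | None = None
    arm: str | None = None
    dose_uM: float | None = None

    def __post_init__(self):
        if not self.spheroid_id:
            raise ValidationError("spheroid_id must be non-empty")
        if not (self.diameter_um > 0):
            raise ValidationError(
                f"spheroid {self.spheroid_id!r}: diameter_um must be > 0, "
                f"got {self.diameter_um}"
            )
        if self.viability_rlu is not None and not (self.viability_rlu >= 0):
            raise ValidationError(
                f"spheroid {self.spheroid_id!r}: viability_rlu must be >= 0"
            )
        if self.dose_uM is not None and not (self.dose_uM >= 0):
            raise ValidationError(
                f"spheroid {self.spheroid_id!r}: dose_uM must be >= 0"
            )
        for attr, levels in MORPHOLOGY_LEVELS.items():
            object.__setattr__(
                self, attr, _normalize_enum(getattr(self, attr), levels, attr)
            )
        object.__setattr__(self, "arm", _normalize_enum(self.arm, _ARM_LEVELS, "arm"))


class SpheroidCohort:
    """Ordered collection of :class:`SpheroidRecord` with unique ids."""

    def __init__(self, records: Iterable[SpheroidRecord]):
        self.records: list[SpheroidRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.spheroid_id in seen:
                raise ValidationError(f"duplicate spheroid_id {rec.spheroid_id!r}")
            seen.add(rec.spheroid_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpheroidRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, SpheroidCohort) and self.records == other.records

    @property
    def cell_lines(self) -> list[str]:
        """Cell-line labels in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.cell_line not in out:
                out.append(rec.cell_line)
        return out

    def subset(self, cell_line: str) -> "SpheroidCohort":
        return SpheroidCohort(r for r in self.records if r.cell_line == cell_line)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spheroid_id": [r.spheroid_id for r in self.records],
                "cell_line": [r.cell_line for r in self.records],
                "diameter_um": [r.diameter_um for r in self.records],
                "viability_rlu": [r.viability_rlu for r in self.records],
                "shape": [r.shape for r in self.records],
                "clustering": [r.clustering for r in self.records],
                "budding": [r.budding for r in self.records],
                "margin": [r.margin for r in self.records],
                "arm": [r.arm for r in self.records],
                "dose_uM": [r.dose_uM for r in self.records],
            }
        )


@dataclass
class ProteinMatrix:
    """Protein-group x sample intensity matrix with explicit missingness.

    ``values`` is a pandas DataFrame indexed by protein-group accession
    (rows) with one column per sample/run; missing quantifications are
    NaN. ``scale`` records whether intensities are raw (linear) or
    log2-transformed. ``gene_names`` is an optional annotation aligned
    with the protein index; the accession remains the identity key.
    """

    values: pd.DataFrame
    scale: str = "raw"
    gene_names: pd.Series | None = None

    def __post_init__(self):
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate protein id {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if self.scale == "raw" and np.any(arr[np.isfinite(arr)] <= 0):
            raise ValidationError("raw intensities must be > 0 where present")
        if self.gene_names is not None:
            self.gene_names = self.gene_names.reindex(idx)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ProteinMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample ids {missing}")
        return ProteinMatrix(
            self.values.loc[:, list(sample_ids)], self.scale, self.gene_names
        )

    def subset_proteins(self, protein_ids: Sequence[str]) -> "ProteinMatrix":
        missing = [p for p in protein_ids if p not in self.values.index]
        if missing:
            raise ValidationError(f"unknown protein ids {missing}")
        genes = (
            self.gene_names.loc[list(protein_ids)] if self.gene_names is not None else None
        )
        return ProteinMatrix(self.values.loc[list(protein_ids)], self.scale, genes)

    def equals(self, other: "ProteinMatrix") -> bool:
        if self.scale != other.scale:
            return False
        if not self.values.equals(other.values):
            return False
        if (self.gene_names is None) != (other.gene_names is None):
            return False
        if self.gene_names is not None and not self.gene_names.equals(other.gene_names):
            return False
        return True


class GeneSetCollection:
    """Named, non-empty gene sets (e.g. one pathway per set)."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ):
        self.sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            genes = list(dict.fromkeys(genes))  # de-duplicate, keep order
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if name in self.sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            self.sets[name] = genes
        self.descriptions: dict[str, str] = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class RankedEntry:
    protein_id: str
    total_points: int
    n_lists: int
    rank: int


class RankedProteinList:
    """Borda-aggregated protein ranking.

    Entries are sorted by descending total points; ties broken by
    descending number of contributing lists, then ascending protein id.
    Ranks run 1..N without gaps.
    """

    def __init__(self, entries: Sequence[RankedEntry], n_pairs: int | None = None):
        self.entries: list[RankedEntry] = list(entries)
        self.n_pairs = n_pairs
        for i, e in enumerate(self.entries):
            if e.rank != i + 1:
                raise ValidationError(
                    f"ranks must be 1..N without gaps; entry {i} has rank {e.rank}"
                )
            if e.total_points < 0 or e.n_lists < 0:
                raise ValidationError("points and list counts must be non-negative")
            if i and self.entries[i - 1].total_points < e.total_points:
                raise ValidationError("total_points must be non-increasing along rank")
            if n_pairs is not None and e.n_lists > n_pairs:
                raise ValidationError(
                    f"{e.protein_id}: n_lists {e.n_lists} exceeds pair count {n_pairs}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RankedEntry]:
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RankedProteinList) and self.entries == other.entries
        )

    def top(self, n: int) -> list[RankedEntry]:
        return self.entries[:n]

    def protein_ids(self) -> list[str]:
        return [e.protein_id for e in self.entries]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [e.rank for e in self.entries],
                "protein_id": [e.protein_id for e in self.entries],
                "total_points": [e.total_points for e in self.entries],
                "n_lists": [e.n_lists for e in self.entries],
            }
        )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows = outcome levels, columns = cell lines."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValidationError("contingency counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table total must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def column_percentages(self) -> tuple[float, float]:
        """Row-one frequency per column (percent), NaN for an empty column."""
        col1 = self.a + self.c
        col2 = self.b + self.d
        p1 = 100.0 * self.a / col1 if col1 else float("nan")
        p2 = 100.0 * self.b / col2 if col2 else float("nan")
        return p1, p2


class DoseResponseTable:
    """Per-spheroid viability at graded drug concentrations."""

    def __init__(self, rows: Iterable[tuple[str, float, float]]):
        self.rows: list[tuple[str, float, float]] = []
        seen: set[tuple[str, float]] = set()
        for sid, dose, via in rows:
            dose = float(dose)
            via = float(via)
            if not np.isfinite(dose) or dose < 0:
                raise ValidationError(f"{sid}: dose must be finite and >= 0")
            if via < 0:
                raise ValidationError(f"{sid}: viability must be >= 0")
            key = (sid, dose)
            if key in seen:
                raise ValidationError(f"duplicate (spheroid, dose) entry {key}")
            seen.add(key)
            self.rows.append((sid, dose, via))

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, DoseResponseTable) and self.rows == other.rows

    @property
    def doses(self) -> np.ndarray:
        return np.array(sorted({d for _, d, _ in self.rows}))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["spheroid_id", "dose_uM", "viability_rlu"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DoseResponseTable":
        return cls(
            (str(r.spheroid_id), float(r.dose_uM), float(r.viability_rlu))
            for r in df.itertuples()
        )
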