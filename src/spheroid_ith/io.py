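"""Readers and writers for the pipeline's file formats.

Supported formats: the DIA-NN ``pg_matrix`` tab-separated dialect
(annotation columns followed by one intensity column per run), a generic
protein x sample TSV, the spheroid cohort CSV, GMT gene-set files and
ranked-list TSVs. All files are UTF-8; matrices are tab-separated and
cohort tables comma-separated. Empty cells and the tokens ``NA``/``NaN``
are read as missing; a literal ``0`` is data, not missingness.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DoseResponseTable,
    FormatError,
    GeneSetCollection,
    ProteinMatrix,
    RankedEntry,
    RankedProteinList,
    SpheroidCohort,
    SpheroidRecord,
    ValidationError,
)

__all__ = [
    "read_protein_group_matrix",
    "write_protein_group_matrix",
    "read_cohort_table",
    "write_cohort_table",
    "read_gmt",
    "write_gmt",
    "read_ranked_list",
    "write_ranked_list",
    "read_dose_response",
    "write_dose_response",
]

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan"}

#: Annotation columns DIA-NN places ahead of the per-run intensity columns.
PG_ANNOTATION_COLUMNS = (
    "Protein.Group",
    "Protein.Ids",
    "Protein.Names",
    "Genes",
    "First.Protein.Description",
)


def _parse_cell(token: str) -> float:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        return math.nan  # non-numeric placeholder -> missing


def read_protein_group_matrix(path, dialect: str = "pg_matrix") -> ProteinMatrix:
    """Read a protein-group intensity matrix as raw-scale :class:`ProteinMatrix`.

    ``dialect='pg_matrix'`` expects a leading block of annotation columns
    (protein group accession, names, gene symbols ...) followed by one
    numeric column per run; the accession becomes the protein id and the
    ``Genes`` column, when present, the gene-name annotation.
    ``dialect='generic_tsv'`` expects the first column to hold protein ids
    and every remaining column to be a sample.
    """
    if dialect not in ("pg_matrix", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        if len(header) < 2 or any(h.strip() == "" for h in header):
            raise FormatError(f"{path}: malformed header {header!r}")
        rows = [row for row in reader if row]

    for row in rows:
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row with {len(row)} fields does not match header "
                f"width {len(header)}"
            )

    if dialect == "generic_tsv":
        n_annot = 1
        gene_col = None
    else:
        n_annot = _annotation_block_width(header, rows)
        gene_col = header.index("Genes") if "Genes" in header[:n_annot] else None

    sample_ids = header[n_annot:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ValidationError(f"{path}: duplicate sample column {dup!r}")
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns found")

    protein_ids = [row[0] for row in rows]
    if len(set(protein_ids)) != len(protein_ids):
        seen: set[str] = set()
        dup = next(p for p in protein_ids if p in seen or seen.add(p))
        raise ValidationError(f"{path}: duplicate protein id {dup!r}")

    data = np.array(
        [[_parse_cell(tok) for tok in row[n_annot:]] for row in rows], dtype=float
    )
    values = pd.DataFrame(data, index=protein_ids, columns=sample_ids)
    genes = (
        pd.Series([row[gene_col] for row in rows], index=protein_ids, name="gene_name")
        if gene_col is not None
        else None
    )
    return ProteinMatrix(values, scale="raw", gene_names=genes)


def _annotation_block_width(header: list[str], rows: list[list[str]]) -> int:
    """Width of the leading annotation block in a pg_matrix header.

    A column belongs to the block if it carries a known DIA-NN annotation
    name or if its content is non-numeric; the block ends at the first
    column that looks like run intensities.
    """
    n = 1  # first column is always the protein-group accession
    for j in range(1, len(header)):
        known = header[j] in PG_ANNOTATION_COLUMNS
        cells = [row[j].strip() for row in rows]
        numeric = all(
            c.lower() in _MISSING_TOKENS or _is_number(c) for c in cells
        ) and any(_is_number(c) for c in cells)
        if known or (rows and not numeric):
            n = j + 1
        else:
            break
    return n


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_protein_group_matrix(
    matrix: ProteinMatrix, path, dialect: str = "pg_matrix"
) -> None:
    """Write a matrix as TSV; missing values become empty cells."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if dialect == "pg_matrix":
            annot = ["Protein.Group"]
            if matrix.gene_names is not None:
                annot.append("Genes")
            writer.writerow(annot + matrix.sample_ids)
            for pid in matrix.protein_ids:
                row = [pid]
                if matrix.gene_names is not None:
                    g = matrix.gene_names.loc[pid]
                    row.append("" if pd.isna(g) else str(g))
                row += _format_values(matrix.values.loc[pid])
                writer.writerow(row)
        elif dialect == "generic_tsv":
            writer.writerow(["protein_id"] + matrix.sample_ids)
            for pid in matrix.protein_ids:
                writer.writerow([pid] + _format_values(matrix.values.loc[pid]))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def _format_values(row: pd.Series) -> list[str]:
    return ["" if pd.isna(v) else repr(float(v)) for v in row]


_COHORT_COLUMNS = [
    "spheroid_id",
    "cell_line",
    "diameter_um",
    "viability_rlu",
    "shape",
    "clustering",
    "budding",
    "margin",
    "arm",
    "dose_uM",
]


def read_cohort_table(path) -> SpheroidCohort:
    """Read a spheroid cohort CSV.

    Required columns: spheroid_id, cell_line, diameter_um. Optional:
    viability_rlu, the morphology attributes, arm, dose_uM. Enum tokens
    are case-insensitive; validation errors name the offending data row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"spheroid_id", "cell_line", "diameter_um"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        row = row._asdict()
        try:
            records.append(
                SpheroidRecord(
                    spheroid_id=row["spheroid_id"],
                    cell_line=row["cell_line"],
                    diameter_um=_required_float(row["diameter_um"], "diameter_um"),
                    viability_rlu=_optional_float(row.get("viability_rlu")),
                    shape=row.get("shape") or None,
                    clustering=row.get("clustering") or None,
                    budding=row.get("budding") or None,
                    margin=row.get("margin") or None,
                    arm=row.get("arm") or None,
                    dose_uM=_optional_float(row.get("dose_uM")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return SpheroidCohort(records)


def _required_float(token: str, name: str) -> float:
    try:
        return float(token)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} is not numeric: {token!r}")


def _optional_float(token) -> float | None:
    if token is None or str(token).strip().lower() in _MISSING_TOKENS:
        return None
    return float(token)


def write_cohort_table(cohort: SpheroidCohort, path) -> None:
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, na_rep="")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then gene symbols."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one gene (got {len(fields)} fields)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        logger.warning("%s: GMT file contains no gene sets", path)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


_RANKED_HEADER = ["rank", "protein_id", "gene_name", "total_points", "n_lists"]


def write_ranked_list(
    rlist: RankedProteinList, path, gene_names: pd.Series | None = None
) -> None:
    """Write a Borda ranking as TSV (rank, protein, gene, points, lists)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_RANKED_HEADER)
        for e in rlist:
            gene = ""
            if gene_names is not None and e.protein_id in gene_names.index:
                g = gene_names.loc[e.protein_id]
                gene = "" if pd.isna(g) else str(g)
            writer.writerow([e.rank, e.protein_id, gene, e.total_points, e.n_lists])


def read_ranked_list(path) -> RankedProteinList:
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _RANKED_HEADER:
            raise FormatError(f"{path}: unexpected header {header!r}")
        entries = [
            RankedEntry(
                protein_id=row[1],
                total_points=int(row[3]),
                n_lists=int(row[4]),
                rank=int(row[0]),
            )
            for row in reader
            if row
        ]
    return RankedProteinList(entries)


def read_dose_response(path) -> DoseResponseTable:
    df = pd.read_csv(path)
    required = {"spheroid_id", "dose_uM", "viability_rlu"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return DoseResponseTable.from_dataframe(df)


def write_dose_response(table: DoseResponseTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)
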