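"""Readers and writers for the external formats the pipeline touches.

Supported formats
-----------------
GCT 1.2 / 1.3
    Expression matrices (probes or genes x wells).  Version 1.3 metadata
    rows/columns beyond the id columns are ignored on read; files are always
    written as the dialect of the matrix being saved.
GMT
    Gene-set collections, one set per tab-separated line
    (``name<TAB>description<TAB>gene...``).
TSV schemas
    ``plate_annotation``  well_id, plate_id, phase_id, cell_line_id,
                          group_label, treatment, dose
    ``drug_annotation``   drug, class, feature
    ``variant_table``     variant_id, cohort, annotation, window_seq,
                          offset, ref, alt
    ``counts_matrix``     gene column followed by one column per cell line
FASTA
    Via Biopython.

Gene identifiers are opaque strings throughout; no symbol mapping is
performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("rzscreen")

GROUP_LABELS = ("CCL", "NPC_control", "NPC_SZ")
VEHICLE = "VEHICLE"
POSITIVE_CONTROL = "POSITIVE_CONTROL"
EMPTY = "EMPTY"

PLATE_ANNOTATION_COLUMNS = [
    "well_id", "plate_id", "phase_id", "cell_line_id",
    "group_label", "treatment", "dose",
]
DRUG_ANNOTATION_COLUMNS = ["drug", "class", "feature"]
VARIANT_TABLE_COLUMNS = [
    "variant_id", "cohort", "annotation", "window_seq", "offset", "ref", "alt",
]


class FormatError(ValueError):
    """A file violated its declared format; carries the offending line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# GCT
# ---------------------------------------------------------------------------

@dataclass
class GctMatrix:
    """A genes/probes x wells expression matrix (log2 scale, unitless).

    ``values`` is a float DataFrame indexed by unique row ids with unique
    column ids; ``version_tag`` records the GCT dialect it was read from or
    should be written as (``#1.2`` or ``#1.3``).
    """

    values: pd.DataFrame
    version_tag: str = "#1.2"

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate row ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate column ids: {list(dups[:5])}")
        if self.version_tag not in ("#1.2", "#1.3"):
            raise FormatError(f"unsupported GCT dialect {self.version_tag!r}")
        self.values = self.values.astype(float)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_gct(path) -> GctMatrix:
    """Parse a GCT 1.2 or 1.3 file into a :class:`GctMatrix`.

    Raises :class:`FormatError` (naming the line) on dimension mismatches,
    duplicate ids, or an unsupported dialect.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError("truncated GCT file", path, len(lines))
    version = lines[0].strip()
    if version not in ("#1.2", "#1.3"):
        raise FormatError(f"unsupported GCT dialect {version!r}", path, 1)
    dims = lines[1].split("\t")
    if version == "#1.2":
        if len(dims) < 2:
            raise FormatError("dimension line needs 2 fields", path, 2)
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_row_meta, n_col_meta = 0, 0
    else:
        if len(dims) < 4:
            raise FormatError("GCT 1.3 dimension line needs 4 fields", path, 2)
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_row_meta, n_col_meta = int(dims[2]), int(dims[3])

    header = lines[2].split("\t")
    expected_header = 1 + n_row_meta + n_cols
    # GCT 1.2 carries a fixed Description column between ids and data
    if version == "#1.2":
        n_row_meta = 1
        expected_header = 2 + n_cols
    if len(header) != expected_header:
        raise FormatError(
            f"header has {len(header)} fields, expected {expected_header}",
            path, 3)
    col_ids = header[1 + n_row_meta:]

    body_start = 3 + n_col_meta  # 1.3 column-metadata rows are skipped
    data_lines = [ln for ln in lines[body_start:] if ln.strip() != ""]
    if len(data_lines) != n_rows:
        raise FormatError(
            f"header declares {n_rows} rows, body has {len(data_lines)}",
            path, body_start + len(data_lines) + 1)

    row_ids, data = [], np.empty((n_rows, n_cols))
    for i, ln in enumerate(data_lines):
        fields = ln.split("\t")
        if len(fields) != expected_header:
            raise FormatError(
                f"row has {len(fields)} fields, expected {expected_header}",
                path, body_start + i + 1)
        row_ids.append(fields[0])
        row = fields[1 + n_row_meta:]
        try:
            data[i] = [float(x) if x not in ("", "NA", "NaN") else np.nan
                       for x in row]
        except ValueError as exc:
            raise FormatError(f"non-numeric value: {exc}", path,
                              body_start + i + 1)
    values = pd.DataFrame(data, index=row_ids, columns=col_ids)
    try:
        return GctMatrix(values, version_tag=version)
    except FormatError as exc:
        raise FormatError(str(exc), path) from exc


def write_gct(matrix: GctMatrix, path) -> None:
    """Write ``matrix`` in its own dialect; round-trips bit-exactly."""
    path = Path(path)
    n_rows, n_cols = matrix.shape
    with open(path, "w") as fh:
        fh.write(matrix.version_tag + "\n")
        if matrix.version_tag == "#1.2":
            fh.write(f"{n_rows}\t{n_cols}\n")
            fh.write("Name\tDescription\t" + "\t".join(matrix.col_ids) + "\n")
            for rid, row in zip(matrix.row_ids, matrix.values.to_numpy()):
                fh.write(rid + "\tna\t" + "\t".join(repr(float(v)) for v in row)
                         + "\n")
        else:
            fh.write(f"{n_rows}\t{n_cols}\t0\t0\n")
            fh.write("id\t" + "\t".join(matrix.col_ids) + "\n")
            for rid, row in zip(matrix.row_ids, matrix.values.to_numpy()):
                fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with a free-text category label (e.g. ``"SZ DE"``)."""

    sets: dict[str, frozenset[str]]
    category: str = ""

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"empty gene set {name!r}")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path, category: str = "") -> GeneSetCollection:
    """Parse a GMT file; duplicate genes within a line are deduplicated.

    Lines with no genes are skipped with a warning; a duplicate set name is
    an error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if not genes:
                logger.warning("%s:%d: set %r has no genes, skipped",
                               path, i, name)
                continue
            if name in sets:
                raise FormatError(f"duplicate set name {name!r}", path, i)
            sets[name] = frozenset(genes)
    return GeneSetCollection(sets, category=category)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write(name + "\t" + (collection.category or "na") + "\t"
                     + "\t".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# TSV schemas
# ---------------------------------------------------------------------------

_SCHEMAS: dict[str, list[str]] = {
    "plate_annotation": PLATE_ANNOTATION_COLUMNS,
    "drug_annotation": DRUG_ANNOTATION_COLUMNS,
    "variant_table": VARIANT_TABLE_COLUMNS,
}


def validate_plate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Enforce the plate-annotation invariants.

    Every non-EMPTY well maps to exactly one cell line; every
    (plate, cell line) stratum holding a treated well has at least one
    vehicle well; group_label is consistent per cell line.
    """
    missing = [c for c in PLATE_ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"plate_annotation missing columns {missing}")
    if ann["well_id"].duplicated().any():
        raise FormatError("duplicate well_id in plate annotation")
    non_empty = ann[ann["treatment"] != EMPTY]
    if non_empty["cell_line_id"].isna().any():
        raise FormatError("non-EMPTY well without a cell line")
    per_line = non_empty.groupby("cell_line_id")["group_label"].nunique()
    bad = per_line[per_line > 1]
    if len(bad):
        raise FormatError(
            f"inconsistent group_label for cell lines {list(bad.index)}")
    unknown = set(non_empty["group_label"].unique()) - set(GROUP_LABELS)
    if unknown:
        raise FormatError(f"unknown group labels {sorted(unknown)}")
    is_ctrl = non_empty["treatment"].isin([VEHICLE, POSITIVE_CONTROL])
    treated = non_empty[~is_ctrl]
    vehicles = non_empty[non_empty["treatment"] == VEHICLE]
    have_vehicle = set(map(tuple,
                           vehicles[["plate_id", "cell_line_id"]].to_numpy()))
    need = set(map(tuple, treated[["plate_id", "cell_line_id"]].to_numpy()))
    orphans = need - have_vehicle
    if orphans:
        raise FormatError(
            f"treated (plate, cell) strata without a vehicle well: "
            f"{sorted(orphans)[:5]}")
    return ann


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a TSV against a named schema; unknown columns are preserved.

    ``schema`` is one of ``plate_annotation``, ``drug_annotation``,
    ``variant_table``, ``counts_matrix``.
    """
    path = Path(path)
    if schema == "counts_matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if (df.to_numpy() < 0).any():
            raise FormatError("negative counts", path)
        return df
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise FormatError(f"{schema} missing required columns {missing}", path)
    if schema == "plate_annotation":
        df["dose"] = pd.to_numeric(df["dose"], errors="coerce")
        validate_plate_annotation(df)
    elif schema == "variant_table":
        df["offset"] = df["offset"].astype(int)
        bad = (df["offset"] < 0) | (df["offset"] >= df["window_seq"].str.len())
        if bad.any():
            raise FormatError(
                f"variant offset outside window for "
                f"{list(df.loc[bad, 'variant_id'][:5])}", path)
    elif schema == "drug_annotation":
        if df.duplicated(subset=DRUG_ANNOTATION_COLUMNS).any():
            raise FormatError("duplicate (drug, class, feature) rows", path)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` mapping (upper-cased)."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
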