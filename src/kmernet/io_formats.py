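"""Readers for interaction tables and genome FASTA; TSV output.

Three interaction-table dialects are supported:

``generic_tsv``
    The canonical, fully documented format (0-based, half-open):
    columns ``promoter_id, p_chrom, p_tss, p_strand, enhancer_id,
    e_chrom, e_start, e_end``.  ``p_tss`` is the 0-based position of the
    TSS; the enhancer anchor is the fragment midpoint.

``sahlen_xlsx``
    Thin adapter for an Excel supplementary table with 1-based
    coordinates.  The column layout is not standardized, so the caller
    must supply ``column_map`` mapping the generic roles to the actual
    column names (plus an optional ``"sheet"`` entry).

``rubin_bed``
    Thin adapter for a BED-style table (0-based, half-open, no header).
    ``column_map`` maps roles to 0-based column indices; ``p_strand``
    and ``enhancer_id`` are optional roles.

Exact duplicate promoter-enhancer pairs are collapsed by default (the
interaction count is a count of unique pairs); ``keep_duplicates=True``
preserves multiplicity for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .regions import GenomicRegion

logger = logging.getLogger(__name__)

GENERIC_COLUMNS = [
    "promoter_id", "p_chrom", "p_tss", "p_strand",
    "enhancer_id", "e_chrom", "e_start", "e_end",
]

#: roles that a rubin_bed column_map may omit
_OPTIONAL_ROLES = {"p_strand", "enhancer_id"}


@dataclass(frozen=True)
class InteractionRecord:
    """One promoter-enhancer interaction with both located regions."""

    promoter_id: str
    enhancer_id: str
    promoter_region: GenomicRegion
    enhancer_region: GenomicRegion

    def __post_init__(self) -> None:
        if not self.promoter_id or not self.enhancer_id:
            raise ValueError("promoter_id and enhancer_id must be nonempty")


class Genome(dict):
    """Mapping of chromosome name to an uppercase A/C/G/T/N sequence."""


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are case-normalized to upper; multi-line records are
    concatenated.  Duplicate headers and empty sequences are errors.
    """
    genome = Genome()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {record.id!r}")
        genome[record.id] = seq
    return genome


def write_genome(genome: Genome, path: str | Path, line_width: int = 60) -> None:
    """Write a :class:`Genome` as FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def _int_field(value, row_number: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"malformed row {row_number}: column {column!r} is not an integer "
            f"({value!r})"
        ) from None


def _records_from_generic(frame: pd.DataFrame, row_offset: int) -> list[InteractionRecord]:
    """Build records from a frame already in generic column layout.

    ``row_offset`` converts a frame index into the file's row number for
    error messages (2 for a TSV with a header line).
    """
    records = []
    for idx, row in frame.iterrows():
        rownum = idx + row_offset
        pid = str(row["promoter_id"]) if pd.notna(row["promoter_id"]) else ""
        eid = str(row["enhancer_id"]) if pd.notna(row["enhancer_id"]) else ""
        if not pid or not eid:
            raise ValueError(f"malformed row {rownum}: empty node identifier")
        tss = _int_field(row["p_tss"], rownum, "p_tss")
        e_start = _int_field(row["e_start"], rownum, "e_start")
        e_end = _int_field(row["e_end"], rownum, "e_end")
        strand = str(row["p_strand"]) if pd.notna(row["p_strand"]) else "unknown"
        if strand not in ("+", "-", "unknown"):
            raise ValueError(f"malformed row {rownum}: invalid strand {strand!r}")
        if e_end <= e_start:
            raise ValueError(
                f"malformed row {rownum}: enhancer end {e_end} <= start {e_start}"
            )
        promoter = GenomicRegion(
            chrom=str(row["p_chrom"]), start=tss, end=tss + 1,
            strand=strand, node_type="promoter", node_id=pid,
        )
        enhancer = GenomicRegion(
            chrom=str(row["e_chrom"]), start=e_start, end=e_end,
            node_type="enhancer", node_id=eid,
        )
        records.append(InteractionRecord(pid, eid, promoter, enhancer))
    return records


def _dedup(records: list[InteractionRecord]) -> list[InteractionRecord]:
    seen = set()
    unique = []
    for rec in records:
        key = (rec.promoter_id, rec.enhancer_id)
        if key in seen:
            continue
        seen.add(key)
        unique.append(rec)
    if len(unique) < len(records):
        logger.info(
            "collapsed %d duplicate promoter-enhancer pairs",
            len(records) - len(unique),
        )
    return unique


def read_interaction_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    column_map: dict | None = None,
    keep_duplicates: bool = False,
) -> list[InteractionRecord]:
    """Read an interaction table into :class:`InteractionRecord` objects.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``generic_tsv``, ``sahlen_xlsx`` or ``rubin_bed`` (see module
        docstring).
    column_map
        Role-to-column mapping, required for the xlsx and bed adapters.
    keep_duplicates
        Keep exact duplicate pairs instead of collapsing them.
    """
    if dialect == "generic_tsv":
        try:
            frame = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            raise ValueError(f"empty interaction table: {path}") from None
        missing = [c for c in GENERIC_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        frame = frame.reset_index(drop=True)
        records = _records_from_generic(frame, row_offset=2)
    elif dialect == "sahlen_xlsx":
        if column_map is None:
            raise ValueError(
                "sahlen_xlsx requires a column_map (the table layout is not "
                "standardized); map the roles "
                f"{GENERIC_COLUMNS} to column names"
            )
        sheet = column_map.get("sheet", 0)
        raw = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
        if raw.empty:
            raise ValueError(f"empty interaction table: {path}")
        frame = pd.DataFrame(
            {role: raw[column_map[role]] for role in GENERIC_COLUMNS}
        ).reset_index(drop=True)
        # 1-based inclusive coordinates -> 0-based half-open
        frame["p_tss"] = pd.to_numeric(frame["p_tss"], errors="coerce") - 1
        frame["e_start"] = pd.to_numeric(frame["e_start"], errors="coerce") - 1
        records = _records_from_generic(frame, row_offset=2)
    elif dialect == "rubin_bed":
        if column_map is None:
            raise ValueError(
                "rubin_bed requires a column_map of roles to 0-based column indices"
            )
        try:
            raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
        except pd.errors.EmptyDataError:
            raise ValueError(f"empty interaction table: {path}") from None
        data = {}
        for role in GENERIC_COLUMNS:
            if role in column_map:
                data[role] = raw[column_map[role]]
            elif role in _OPTIONAL_ROLES:
                data[role] = None
            else:
                raise ValueError(f"rubin_bed column_map missing role {role!r}")
        frame = pd.DataFrame(data).reset_index(drop=True)
        if frame["enhancer_id"].isna().all():
            frame["enhancer_id"] = (
                frame["e_chrom"].astype(str)
                + ":" + frame["e_start"].astype(str)
                + "-" + frame["e_end"].astype(str)
            )
        frame["p_strand"] = frame["p_strand"].fillna("unknown")
        records = _records_from_generic(frame, row_offset=1)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not records:
        raise ValueError(f"empty interaction table: {path}")
    if not keep_duplicates:
        records = _dedup(records)
    return records


def interactions_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    """Serialize records to the generic_tsv column layout."""
    rows = []
    for rec in records:
        rows.append({
            "promoter_id": rec.promoter_id,
            "p_chrom": rec.promoter_region.chrom,
            "p_tss": rec.promoter_region.start,
            "p_strand": rec.promoter_region.strand,
            "enhancer_id": rec.enhancer_id,
            "e_chrom": rec.enhancer_region.chrom,
            "e_start": rec.enhancer_region.start,
            "e_end": rec.enhancer_region.end,
        })
    return pd.DataFrame(rows, columns=GENERIC_COLUMNS)


def write_interaction_table(records: list[InteractionRecord], path: str | Path) -> None:
    """Write records in the canonical generic_tsv dialect."""
    write_tsv(interactions_to_frame(records), path)


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV; NaN serialized as ``NA``, 10 significant digits."""
    if table.columns.duplicated().any():
        raise ValueError("duplicate column names")
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (``NA`` means missing)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
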