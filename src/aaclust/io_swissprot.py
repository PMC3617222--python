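"""Readers for UniProtKB/Swiss-Prot FLAT files and FASTA, and composition-table I/O.

Only the ID line, the SQ header and the indented sequence block of a FLAT
record are interpreted; all other line types (AC is kept if present, DE, FT,
... are skipped).  Each record's declared residue count is checked against the
assembled sequence; a record failing any check is rejected and reported
without aborting the rest of the file, so one corrupt entry cannot kill a
large run.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .composition import CompositionTable
from .records import ALLOWED_RESIDUES, ProteinRecord, RecordError

__all__ = [
    "FlatFileRecordWarning",
    "read_flatfile",
    "read_fasta",
    "write_composition_table",
    "read_composition_table",
]


class FlatFileRecordWarning(UserWarning):
    """A single FLAT record was rejected; parsing of the file continued."""


_SQ_RE = re.compile(r"^SQ\s+SEQUENCE\s+(\d+)\s+AA")
_ID_RE = re.compile(r"^ID\s+(\S+)")
_AC_RE = re.compile(r"^AC\s+(\S+?);")


def _finish_record(
    entry_name: str | None,
    accession: str,
    declared_length: int | None,
    seq_parts: list[str],
    record_no: int,
) -> ProteinRecord:
    if entry_name is None:
        raise RecordError(f"record #{record_no}: missing or unparseable ID line")
    if declared_length is None:
        raise RecordError(f"{entry_name}: missing SQ line")
    sequence = "".join(seq_parts)
    if not sequence:
        raise RecordError(f"{entry_name}: empty sequence block")
    if not sequence.isascii():
        raise RecordError(f"{entry_name}: non-ASCII bytes in sequence block")
    bad = set(sequence) - ALLOWED_RESIDUES
    if bad:
        raise RecordError(f"{entry_name}: invalid residue(s) {sorted(bad)!r}")
    if declared_length != len(sequence):
        raise RecordError(
            f"{entry_name}: SQ header declares {declared_length} AA but the "
            f"sequence block contains {len(sequence)} residues"
        )
    return ProteinRecord(
        entry_name=entry_name,
        accession=accession,
        declared_length=declared_length,
        sequence=sequence,
    )


def read_flatfile(path: str | Path, strict: bool = False) -> list[ProteinRecord]:
    """Parse a Swiss-Prot FLAT file into :class:`ProteinRecord` objects.

    Records are delimited by ``//`` lines and returned in file order.  A
    record with a missing/unparseable ID or SQ line, invalid residues, or a
    declared length disagreeing with its sequence block is rejected with a
    :class:`FlatFileRecordWarning` (or a :class:`RecordError` if ``strict``).
    """
    path = Path(path)
    entry_name: str | None = None
    accession = ""
    declared_length: int | None = None
    seq_parts: list[str] = []
    in_record = False
    record_no = 0
    records: list[ProteinRecord] = []

    def flush() -> None:
        nonlocal entry_name, accession, declared_length, seq_parts, in_record
        try:
            records.append(
                _finish_record(entry_name, accession, declared_length, seq_parts, record_no)
            )
        except RecordError as exc:
            if strict:
                raise
            warnings.warn(
                f"{path.name}: rejected record — {exc}",
                FlatFileRecordWarning,
                stacklevel=3,
            )
        entry_name, accession, declared_length = None, "", None
        seq_parts, in_record = [], False

    with open(path, encoding="ascii", errors="surrogateescape") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("//"):
                record_no += 1
                flush()
                continue
            if line.startswith("ID"):
                in_record = True
                m = _ID_RE.match(line)
                entry_name = m.group(1) if m else None
            elif line.startswith("AC") and not accession:
                m = _AC_RE.match(line)
                accession = m.group(1) if m else ""
            elif line.startswith("SQ"):
                m = _SQ_RE.match(line)
                if m:
                    declared_length = int(m.group(1))
            elif line[:1] in (" ", "\t") and in_record:
                seq_parts.append("".join(line.split()))
    if in_record or entry_name is not None:
        # trailing record without a terminating "//"
        record_no += 1
        flush()
    return records


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header's first whitespace-delimited token becomes ``entry_name``;
    the declared length is set to the counted residue length.
    """
    records: list[ProteinRecord] = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        sequence = str(seq_rec.seq).upper()
        if not sequence:
            raise RecordError(f"{seq_rec.id or '<unnamed>'}: sequence-less FASTA header")
        bad = set(sequence) - ALLOWED_RESIDUES
        if bad:
            raise RecordError(f"{seq_rec.id}: invalid residue(s) {sorted(bad)!r}")
        records.append(
            ProteinRecord(
                entry_name=seq_rec.id,
                accession="",
                declared_length=len(sequence),
                sequence=sequence,
            )
        )
    if not records:
        raise RecordError(f"{path}: no FASTA records found")
    return records


# -- composition-table TSV ---------------------------------------------------

from .records import STANDARD_AA  # noqa: E402  (column order for the header)

_HEADER = ["id", "length", *STANDARD_AA]


def write_composition_table(table: CompositionTable, path: str | Path) -> None:
    """Write the table as TSV: header ``id  length  A C D ... Y``.

    Frequencies are printed with exactly 3 decimals in rounded mode and with
    full (round-trippable) precision otherwise.
    """
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for i, pid in enumerate(table.protein_ids):
            if table.rounded:
                cells = [f"{x:.3f}" for x in table.matrix[i]]
            else:
                cells = [repr(float(x)) for x in table.matrix[i]]
            fh.write("\t".join([pid, str(int(table.lengths[i])), *cells]) + "\n")


def read_composition_table(path: str | Path) -> CompositionTable:
    """Read a TSV composition table written by :func:`write_composition_table`."""
    path = Path(path)
    with open(path, encoding="ascii") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != _HEADER:
        raise ValueError(f"{path}:1: malformed composition-table header")
    ids: list[str] = []
    lengths: list[int] = []
    rows: list[list[float]] = []
    rounded = True
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(_HEADER):
            raise ValueError(
                f"{path}:{lineno}: expected {len(_HEADER)} columns, got {len(cells)}"
            )
        try:
            length = int(cells[1])
            freqs = [float(c) for c in cells[2:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        ids.append(cells[0])
        lengths.append(length)
        rows.append(freqs)
        if any(not re.fullmatch(r"-?\d+\.\d{3}", c) for c in cells[2:]):
            rounded = False
    if not rows:
        raise ValueError(f"{path}: table contains no data rows")
    return CompositionTable(
        protein_ids=ids,
        lengths=np.array(lengths, dtype=np.int64),
        matrix=np.array(rows, dtype=np.float64),
        rounded=rounded,
    )
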