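"""Amino-acid composition vectors — the clustering features.

Each protein is reduced to the relative frequency of each of the 20 standard
amino acids: ``freq[a] = count(a) / length``.  Residues outside the standard
alphabet (B, Z, X, U, O) are not assigned to any column; they accumulate in
``nonstandard_fraction``, so rows containing them sum to less than one.  The
denominator is always the full declared length, keeping every frequency
interpretable as "fraction of the protein".

A 3-decimal rounding mode (``round3``, half away from zero) reproduces the
fixed-precision composition tables this kind of tool historically stored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import AA_INDEX, STANDARD_AA, ProteinRecord, validate_record

__all__ = [
    "CompositionVector",
    "CompositionTable",
    "compute_composition",
    "round3",
    "build_table",
    "make_leaf_labels",
]


@dataclass(frozen=True)
class CompositionVector:
    """Relative amino-acid frequencies of one protein."""

    protein_id: str
    length: int
    freqs: np.ndarray  # shape (20,), indexed by STANDARD_AA order
    nonstandard_fraction: float


@dataclass
class CompositionTable:
    """Per-protein composition matrix: rows = proteins, columns = STANDARD_AA."""

    protein_ids: list[str]
    lengths: np.ndarray  # (n,) residue counts
    matrix: np.ndarray  # (n, 20) relative frequencies
    rounded: bool = field(default=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.protein_ids)
        if self.matrix.shape != (n, len(STANDARD_AA)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n} ids x {len(STANDARD_AA)} amino acids"
            )
        if self.lengths.shape != (n,):
            raise ValueError("lengths do not match number of proteins")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.protein_ids)


def compute_composition(
    record: ProteinRecord, protein_id: str | None = None
) -> CompositionVector:
    """Relative frequency of each standard amino acid in ``record``.

    ``freqs[a] = count(a) / declared_length``; occurrences of nonstandard
    letters contribute only to ``nonstandard_fraction``.
    """
    validate_record(record)
    length = record.declared_length
    if length == 0:
        raise ValueError(f"{record.entry_name}: zero-length sequence")
    freqs = np.zeros(len(STANDARD_AA), dtype=np.float64)
    standard_total = 0
    for aa, col in AA_INDEX.items():
        c = record.sequence.count(aa)
        freqs[col] = c / length
        standard_total += c
    nonstandard = (length - standard_total) / length
    return CompositionVector(
        protein_id=protein_id if protein_id is not None else record.entry_name,
        length=length,
        freqs=freqs,
        nonstandard_fraction=nonstandard,
    )


def _round3_array(a: np.ndarray) -> np.ndarray:
    # half away from zero, 3 decimals (np.round would round half to even)
    a = np.asarray(a, dtype=np.float64)
    return np.sign(a) * np.floor(np.abs(a) * 1000.0 + 0.5) / 1000.0


def round3(obj):
    """Round frequencies to exactly 3 decimals, half away from zero.

    Accepts a :class:`CompositionVector`, a :class:`CompositionTable` or a
    plain array; returns the same type.  Idempotent.
    """
    if isinstance(obj, CompositionVector):
        return CompositionVector(
            protein_id=obj.protein_id,
            length=obj.length,
            freqs=_round3_array(obj.freqs),
            nonstandard_fraction=float(_round3_array(obj.nonstandard_fraction)),
        )
    if isinstance(obj, CompositionTable):
        return CompositionTable(
            protein_ids=list(obj.protein_ids),
            lengths=obj.lengths.copy(),
            matrix=_round3_array(obj.matrix),
            rounded=True,
        )
    return _round3_array(obj)


def make_leaf_labels(records: Sequence[ProteinRecord]) -> list[str]:
    """Newick-safe leaf labels ``<ENTRY_NAME>_<length>``, deduplicated.

    A duplicate label gets a numeric suffix (``_2``, ``_3``, ...) in order of
    occurrence; the first occurrence keeps the bare label.
    """
    labels: list[str] = []
    seen: dict[str, int] = {}
    for rec in records:
        base = f"{rec.entry_name}_{rec.declared_length}"
        count = seen.get(base, 0) + 1
        seen[base] = count
        labels.append(base if count == 1 else f"{base}_{count}")
    return labels


def build_table(
    records: Sequence[ProteinRecord], rounded: bool = False
) -> CompositionTable:
    """Assemble the composition table for a list of records, in input order."""
    if len(records) < 2:
        raise ValueError(
            f"need at least 2 records to build a clusterable table, got {len(records)}"
        )
    labels = make_leaf_labels(records)
    vectors = [compute_composition(r, protein_id=lbl) for r, lbl in zip(records, labels)]
    n_nonstd = sum(1 for v in vectors if v.nonstandard_fraction > 0)
    if n_nonstd:
        warnings.warn(
            f"{n_nonstd} record(s) contain nonstandard residues; their "
            "frequency rows sum to less than 1",
            stacklevel=2,
        )
    table = CompositionTable(
        protein_ids=labels,
        lengths=np.array([v.length for v in vectors], dtype=np.int64),
        matrix=np.vstack([v.freqs for v in vectors]),
    )
    return round3(table) if rounded else table
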