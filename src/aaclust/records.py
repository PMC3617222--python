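"""Core protein record type and the amino-acid alphabet.

The 20 standard amino acids are kept in fixed alphabetical one-letter order;
this order defines the columns of every composition table in the package.
Sequences may additionally contain the IUPAC ambiguity/rare codes B, Z, X, U
and O (any uppercase letter except J is accepted).
"""

from __future__ import annotations

import string
from dataclasses import dataclass

#: The 20 standard amino acids, alphabetical one-letter order.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Column index of each standard amino acid.
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(STANDARD_AA)}

#: Every residue letter a sequence may contain (IUPAC one-letter codes; J is
#: not a valid amino-acid code).
ALLOWED_RESIDUES: frozenset[str] = frozenset(string.ascii_uppercase) - {"J"}


class RecordError(ValueError):
    """A protein record violates its invariants (bad residues, length mismatch)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: identifier, declared length and residue string."""

    entry_name: str
    accession: str
    declared_length: int
    sequence: str


def validate_record(record: ProteinRecord) -> None:
    """Raise :class:`RecordError` if ``record`` violates its invariants.

    Checks: non-empty sequence over the allowed uppercase alphabet, and
    agreement between the declared length and the actual residue count.
    """
    if not record.sequence:
        raise RecordError(f"{record.entry_name}: empty sequence")
    bad = set(record.sequence) - ALLOWED_RESIDUES
    if bad:
        raise RecordError(
            f"{record.entry_name}: invalid residue(s) {sorted(bad)!r}"
        )
    if record.declared_length != len(record.sequence):
        raise RecordError(
            f"{record.entry_name}: declared length {record.declared_length} "
            f"!= sequence length {len(record.sequence)}"
        )
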