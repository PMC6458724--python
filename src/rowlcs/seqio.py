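"""FASTA input/output, sequence sanitization and alphabet construction.

Sequences are plain Python strings of uppercase residues.  The joint
alphabet of a pair is the deduplicated, code-point-sorted union of the
characters of both sequences; ranks are 1-based so they can index rows
of an occurrence table directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from io import StringIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceRecord",
    "Alphabet",
    "FastaFormatError",
    "SequenceValidationError",
    "read_fasta",
    "write_fasta",
    "sanitize",
    "build_alphabet",
]

DNA_ALPHABET = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Raised when a residue fails strict validation."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based, after whitespace removal
        super().__init__(
            f"invalid residue {char!r} at position {position} "
            f"(strict policy allows only A, C, G, T)"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence; ``residues`` holds uppercase characters only."""

    id: str
    residues: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alphabet:
    """Deduplicated character string with 1-based ranks.

    ``symbols[c - 1]`` is the character of rank ``c`` and
    ``rank[ch]`` recovers that rank, for every character seen.
    """

    symbols: str
    rank: dict[str, int] = field(compare=False)

    def __len__(self) -> int:
        return len(self.symbols)


def build_alphabet(a: str, b: str) -> Alphabet:
    """Joint alphabet of two strings, sorted ascending by character code."""
    symbols = "".join(sorted(set(a) | set(b)))
    return Alphabet(symbols=symbols, rank={ch: c for c, ch in enumerate(symbols, start=1)})


def sanitize(raw: str, policy: str = "permissive") -> str:
    """Uppercase and strip whitespace; ``strict`` additionally enforces ACGT.

    Raises :class:`SequenceValidationError` naming the first offending
    character and its 1-based position (counted after whitespace removal).
    """
    if policy not in ("strict", "permissive"):
        raise ValueError(f"unknown sanitize policy {policy!r}")
    cleaned = "".join(raw.split()).upper()
    if policy == "strict":
        for pos, ch in enumerate(cleaned, start=1):
            if ch not in DNA_ALPHABET:
                raise SequenceValidationError(ch, pos)
    return cleaned


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read all records of a FASTA file, preserving order.

    Sequence lines are concatenated, whitespace-stripped and uppercased.
    Content before the first ``>`` header or a header with an empty id is
    a :class:`FastaFormatError`.
    """
    with open(path) as handle:
        text = handle.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaFormatError(f"{path}: content before first '>' header")
    records = []
    with StringIO(text) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            if not parts:
                raise FastaFormatError(f"{path}: record with empty id")
            desc = parts[1] if len(parts) > 1 else ""
            records.append(
                SequenceRecord(id=parts[0], residues="".join(seq.split()).upper(),
                               description=desc)
            )
    return records


def write_fasta(records, path: str | os.PathLike, width: int = 70) -> None:
    """Write records as multi-line FASTA with ``width`` residues per line."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for start in range(0, len(rec.residues), width):
                handle.write(rec.residues[start:start + width] + "\n")
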