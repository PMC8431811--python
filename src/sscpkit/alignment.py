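"""Nucleotide multiple-sequence-alignment container and FASTA ingest.

Sequences are normalized on ingest: uppercase, U -> T.  Gaps are ``-``.
IUPAC ambiguity codes are kept verbatim; downstream column statistics
decide how to treat them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

GAP = "-"
STATES = ("A", "T", "C", "G", GAP)
#: one-letter codes that denote an ambiguous base (anything not ACGT/-)
AMBIGUITY = frozenset("RYSWKMBDHVN")

_NORMALIZE = str.maketrans({"u": "T", "U": "T", ".": GAP})


def normalize_seq(seq: str) -> str:
    """Uppercase, map U/u to T and ``.`` to ``-``."""
    return seq.translate(_NORMALIZE).upper()


@dataclass
class Alignment:
    """An aligned set of nucleotide sequences (equal length, unique ids)."""

    records: list[tuple[str, str]]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment needs at least one sequence")
        self.records = [(rid, normalize_seq(s)) for rid, s in self.records]
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        self.length = lengths.pop()
        if self.length < 1:
            raise ValueError("alignment has zero columns")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def column(self, i: int) -> list[str]:
        """Residues of 1-based column ``i``."""
        if not 1 <= i <= self.length:
            raise IndexError(f"column {i} outside 1..{self.length}")
        return [s[i - 1] for _, s in self.records]

    def columns(self) -> Iterable[list[str]]:
        for i in range(1, self.length + 1):
            yield self.column(i)

    def slice(self, start: int, end: int) -> "Alignment":
        """Sub-alignment of 1-based inclusive columns ``start..end``."""
        if not (1 <= start <= end <= self.length):
            raise IndexError(f"slice {start}..{end} outside 1..{self.length}")
        return Alignment([(rid, s[start - 1 : end]) for rid, s in self.records])


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(records)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (possibly unaligned) FASTA sequences, normalized."""
    return [
        (rec.id, normalize_seq(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
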