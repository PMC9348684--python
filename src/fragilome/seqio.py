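"""FASTA input/output and sequence validation.

A :class:`Genome` is one strand of a DNA (or RNA, stored as DNA letters)
sequence together with its record identifier.  Multi-record files are read
as independent genomes; records are never concatenated.

Positions in user-facing reports are 1-based (internal coordinates are
0-based half-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .alphabet import encode

__all__ = ["Genome", "read_fasta", "write_fasta", "sanitize", "FastaParseError"]

POLICIES = ("reject", "mask", "tolerate")


class FastaParseError(ValueError):
    """Raised when a FASTA file is missing, empty, or malformed."""


@dataclass(frozen=True)
class Genome:
    """An identified DNA sequence.

    Parameters
    ----------
    id
        Record identifier; must be non-empty.
    sequence
        Upper-case character string over {A,C,G,T} plus tolerated
        ambiguity codes.
    """

    id: str
    sequence: str = field(repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Genome id must be non-empty")

    @property
    def length(self) -> int:
        """Number of bases, |G|."""
        return len(self.sequence)

    def codes(self):
        """The uint8 code-array view of the sequence (A,C,G,T -> 0..3)."""
        return encode(self.sequence)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[Genome]:
    """Read all records of a FASTA file as a list of :class:`Genome`.

    Sequences are upper-cased; line breaks and whitespace inside records
    are removed.  Record order is preserved.

    Raises
    ------
    FastaParseError
        If the file is missing, empty, malformed (first non-blank line is
        not a ``>`` header), or contains duplicate record ids.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"FASTA file not found: {path}")
    text_started = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: malformed FASTA header at line {lineno}: "
                        f"expected '>' record start"
                    )
                text_started = True
                break
    if not text_started:
        raise FastaParseError(f"{path}: empty FASTA file")

    genomes: list[Genome] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {record.id!r}")
        seen.add(record.id)
        genomes.append(Genome(id=record.id, sequence=str(record.seq).upper()))
    return genomes


def write_fasta(
    genomes: Iterable[Genome], path: str | Path, line_width: int = 70
) -> None:
    """Write genomes to ``path`` in FASTA, wrapping bodies at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    genomes = list(genomes)
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids; FASTA records must be unique")
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for start in range(0, g.length, line_width):
                fh.write(g.sequence[start : start + line_width] + "\n")


def sanitize(genome: Genome, policy: str = "tolerate") -> Genome:
    """Apply a non-ACGT character policy to a genome.

    ``reject``   -- raise on any non-ACGT character (position reported
    1-based); ``mask`` -- replace every non-ACGT character with ``N``;
    ``tolerate`` -- return the genome unchanged (downstream tuple counting
    skips windows containing non-ACGT characters).

    Idempotent under every policy.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    codes = genome.codes()
    bad = codes >= 4
    if not bad.any():
        return genome
    if policy == "reject":
        pos = int(bad.argmax()) + 1  # first offending position, 1-based
        raise ValueError(
            f"genome {genome.id!r}: non-ACGT character "
            f"{genome.sequence[pos - 1]!r} at position {pos}"
        )
    if policy == "mask":
        seq = bytearray(genome.sequence.encode("ascii"))
        for i in bad.nonzero()[0]:
            seq[i] = ord("N")
        return Genome(id=genome.id, sequence=seq.decode("ascii"))
    return genome


def check_unique_ids(genomes: Sequence[Genome]) -> None:
    """Raise if any two genomes in the collection share an id."""
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate genome ids: {dupes}")


def warn_if_empty(genomes: Sequence[Genome]) -> None:  # pragma: no cover
    if not genomes:
        warnings.warn("no genomes loaded", stacklevel=2)
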