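"""Core sequence plumbing: DNA strings, coordinates, FASTA/FASTQ I/O and the
synthetic-genome fixture.

Conventions used throughout the package:

* All coordinates are 0-based, half-open ``[start, end)`` in the *sense*
  frame of the owning sequence.
* Nick positions are *bond* coordinates ``b`` in ``1..L-1``: the backbone
  bond between sense positions ``b-1`` and ``b``.  Antisense nicks use the
  same sense-frame bond coordinate.
* Strands are the strings ``"sense"`` and ``"antisense"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SENSE = "sense"
ANTISENSE = "antisense"
STRANDS = (SENSE, ANTISENSE)


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T}."""


class ParseError(ValueError):
    """A sequence file is malformed; the message carries the line number."""


def validate_dna(seq: str) -> str:
    """Return *seq* upper-cased, or raise :class:`AlphabetError`."""
    s = seq.upper()
    if not s:
        raise AlphabetError("empty sequence")
    bad = set(s) - set(ALPHABET)
    if bad:
        raise AlphabetError(f"non-ACGT characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (involution)."""
    return validate_dna(seq).translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    s = validate_dna(seq)
    return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval, optionally stranded."""

    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand is not None and self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeFixture:
    """Synthetic stand-in for a bacterial genomic reference.

    The sequence is i.i.d. with P(G)+P(C) = ``gc_fraction`` and is fully
    determined by ``seed``; no repeat structure is injected, so 16-mers are
    overwhelmingly unique — the regime the register designer relies on.
    """

    sequence: str
    seed: int
    gc_fraction: float


def make_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> GenomeFixture:
    """Generate a seeded i.i.d. genome fixture.

    Degenerate GC fractions (0 or 1) are rejected: they make the guide GC
    constraint unsatisfiable by construction.
    """
    if length < 1000:
        raise ValueError("fixture genome must be at least 1000 nt")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(list(ALPHABET), size=length, p=[at, gc, gc, at])
    return GenomeFixture("".join(bases), seed=seed, gc_fraction=gc_fraction)


# ---------------------------------------------------------------------------
# FASTA / FASTQ (Sanger Phred+33)
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    records = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            records.append((title.split()[0], validate_dna(seq)))
    if not records:
        raise ParseError(f"{path}: no FASTA records found (line 1)")
    return records


def write_fasta(path, records, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read a 4-line-record FASTQ; qualities are preserved byte-exact."""
    records = []
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise ValueError("sequence and quality lengths differ")
                records.append((title.split()[0], validate_dna(seq), qual))
        except ValueError as exc:
            line = 4 * len(records) + 1
            raise ParseError(f"{path}: {exc} (record starting near line {line})") from exc
    return records


def write_fastq(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"{name}: sequence/quality length mismatch")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def constant_quality(length: int, phred: int = 30) -> str:
    """Quality string at a single constant Phred score (Sanger +33)."""
    return chr(phred + 33) * length
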