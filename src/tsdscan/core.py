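"""Sequence records, FASTA I/O, genome composition and coordinate primitives.

Conventions used throughout the package:

* DNA is uppercase over the alphabet ``{A, C, G, T, N}``; anything else is
  normalized to ``N`` on input (with a logged warning).
* Coordinates are 0-based half-open internally and in exported BED;
  human-readable reports are 1-based inclusive.
* Base order in all matrices is ``A, C, G, T``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: canonical base order for all count/frequency matrices
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised when a FASTA file is empty or malformed."""


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but carries no usable signal."""


@dataclass
class SequenceRecord:
    """A named sequence (DNA or protein) with an optional description."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Background:
    """Genome base composition q(b), the baseline for bias logos.

    ``freqs`` is a length-4 array in A, C, G, T order, non-negative and
    summing to 1 (within 1e-9).
    """

    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        q = np.asarray(self.freqs, dtype=float)
        if q.shape != (4,):
            raise ValueError("background needs exactly 4 frequencies (A,C,G,T)")
        if (q < 0).any():
            raise ValueError("background frequencies must be non-negative")
        if abs(q.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {q.sum()}, not 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    def __getitem__(self, base: str) -> float:
        return self.freqs[BASE_INDEX[base]]

    @classmethod
    def uniform(cls) -> "Background":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_freqs(cls, a: float, c: float, g: float, t: float) -> "Background":
        return cls((a, c, g, t))


def normalize_dna(seq: str) -> str:
    """Uppercase, map U to T and replace non-IUPAC-core characters by N."""
    seq = seq.upper().replace("U", "T")
    if set(seq) <= _DNA_ALPHABET:
        return seq
    bad = sorted(set(seq) - _DNA_ALPHABET)
    logger.warning("replacing %d non-ACGTN character kinds %s with N", len(bad), bad)
    return "".join(c if c in _DNA_ALPHABET else "N" for c in seq)


def read_fasta(path: str | Path, moltype: str = "dna") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into a list of :class:`SequenceRecord`.

    DNA sequences are normalized (uppercase, U->T, other letters -> N).
    Pass ``moltype="protein"`` for amino-acid input (kept verbatim apart
    from uppercasing; gap dashes survive for alignments).
    """
    path = Path(path)
    try:
        text_head = path.open().readline()
    except OSError as exc:
        raise FastaFormatError(f"cannot read {path}: {exc}") from exc
    if not text_head:
        raise FastaFormatError(f"{path}: empty file")
    if not text_head.startswith(">"):
        raise FastaFormatError(f"{path}: line 1 does not start with '>'")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if moltype == "dna":
            seq = normalize_dna(seq)
        else:
            seq = seq.upper()
        records.append(SequenceRecord(rec.id, seq, rec.description))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    if not set(seq) <= _DNA_ALPHABET:
        bad = sorted(set(seq) - _DNA_ALPHABET)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def genome_composition(records: Sequence[SequenceRecord]) -> Background:
    """Base composition q(b) over all records, N excluded from the counts."""
    if not records:
        raise DegenerateInputError("no sequence records supplied")
    counts = Counter()
    for rec in records:
        counts.update(rec.sequence)
    total = sum(counts[b] for b in BASES)
    if total == 0:
        raise DegenerateInputError("no non-N bases in input")
    return Background(tuple(counts[b] / total for b in BASES))


def parse_background(spec: str) -> Background:
    """Parse 'a,c,g,t' (e.g. '0.31,0.19,0.19,0.31') into a Background."""
    parts = [p.strip() for p in spec.split(",")]
    if len(parts) != 4:
        raise ValueError("background must be four comma-separated frequencies A,C,G,T")
    return Background(tuple(float(p) for p in parts))


def hamming(a: str, b: str) -> int:
    """Positionwise mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
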