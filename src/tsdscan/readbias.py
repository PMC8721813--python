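"""Tagmentation-read selection, end trimming and the 28-base bias profile.

Reads whose 5' end carries the transposon end oligo (the 20-bp "left
end" used to load the transposase) start, after trimming that adapter,
at the insertion point: the first 8 bases are the target site
duplication and the following 20 the flanking genomic DNA.  Pooling the
first 28 post-adapter bases over all matched reads and comparing the
position weight matrix against the genome composition quantifies the
transposase's insertion-site sequence bias.

Adapter matching is gapless and anchored near the read start (offset
<= ``max_offset``): indel-free matching keeps the 28-base frame register
exact, which the TSD analysis requires.  The mismatch budget is
floor(error_rate * adapter length), error_rate defaulting to 0.1.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .core import Background, DegenerateInputError, SequenceRecord, normalize_dna
from .logo import LogoProfile, build_count_matrix, make_profile, to_frequency

logger = logging.getLogger(__name__)


@dataclass
class ReadRecord:
    id: str
    bases: str
    qualities: list[int] | None = None


@dataclass(frozen=True)
class AdapterMatch:
    """Gapless occurrence of the adapter in a read: [start, end), mismatches."""

    read_id: str
    start: int
    end: int
    errors: int


def match_adapter(
    read: ReadRecord,
    adapter: str,
    error_rate: float = 0.1,
    max_offset: int = 5,
) -> AdapterMatch | None:
    """Leftmost gapless adapter occurrence within the mismatch budget.

    Scans offsets 0..max_offset; the first offset whose mismatch count is
    <= floor(error_rate * len(adapter)) wins (a given offset has exactly
    one mismatch count, so "fewest mismatches among equal starts" is
    automatic).  Returns None when no offset qualifies.
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be at least 10 bases")
    max_mm = int(error_rate * len(adapter))
    L = len(adapter)
    bases = read.bases
    for off in range(min(max_offset, len(bases) - L) + 1):
        mm = sum(a != b for a, b in zip(bases[off : off + L], adapter))
        if mm <= max_mm:
            return AdapterMatch(read_id=read.id, start=off, end=off + L, errors=mm)
    return None


def trim_and_take(read: ReadRecord, match: AdapterMatch, take: int = 28) -> str | None:
    """The ``take`` bases immediately after the adapter, or None.

    None when fewer than ``take`` bases remain or the window contains N
    (callers count these exclusions separately).
    """
    window = read.bases[match.end : match.end + take]
    if len(window) < take or "N" in window:
        return None
    return window


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate a (possibly gzipped) 4-line FASTQ file."""
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                id=rec.id,
                bases=normalize_dna(str(rec.seq)),
                qualities=rec.letter_annotations.get("phred_quality"),
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = (
                "".join(chr(q + 33) for q in r.qualities)
                if r.qualities is not None
                else "I" * len(r.bases)
            )
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def reads_to_profile(
    fastq_paths: str | Path | list[str | Path],
    adapter: str,
    background: Background,
    error_rate: float = 0.1,
    max_offset: int = 5,
    take: int = 28,
    pseudocount: float | None = None,
) -> tuple[LogoProfile, dict]:
    """End-to-end read-bias pipeline over one or two FASTQ files.

    Paired files are processed independently and pooled (mates are not
    merged or deduplicated).  Returns the composition-adjusted logo of
    the 28-base windows and a stats dict with total_reads, matched,
    matched_fraction, short_after_trim and n_excluded_N.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    adapter = normalize_dna(adapter)
    windows: list[str] = []
    total = matched = short = n_excl = 0
    for path in fastq_paths:
        for read in iter_fastq(path):
            total += 1
            m = match_adapter(read, adapter, error_rate=error_rate, max_offset=max_offset)
            if m is None:
                continue
            matched += 1
            window = read.bases[m.end : m.end + take]
            if len(window) < take:
                short += 1
            elif "N" in window:
                n_excl += 1
            else:
                windows.append(window)
    stats = {
        "total_reads": total,
        "matched": matched,
        "matched_fraction": matched / total if total else 0.0,
        "short_after_trim": short,
        "n_excluded_N": n_excl,
        "n_windows": len(windows),
    }
    if not windows:
        raise DegenerateInputError(f"no usable adapter-matched reads; stats: {stats}")
    counts = build_count_matrix(windows, take)
    profile = make_profile(to_frequency(counts, pseudocount=pseudocount), background)
    return profile, stats
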