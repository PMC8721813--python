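"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take the naive route (score every offset, enumerate
every case) so they share no code path with the package's seeded /
short-circuited implementations.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq

from tsdscan.core import SequenceRecord, reverse_complement


def brute_force_end_hits(
    genome: list[SequenceRecord],
    query: SequenceRecord,
    min_identity: float,
) -> set[tuple[str, int, str, float]]:
    """Gapless identity of the full query at every offset on both strands."""
    L = len(query.sequence)
    q_fwd = np.frombuffer(query.sequence.encode(), dtype=np.uint8)
    q_rev = np.frombuffer(reverse_complement(query.sequence).encode(), dtype=np.uint8)
    out: set[tuple[str, int, str, float]] = set()
    for rec in genome:
        arr = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        if arr.size < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand, q in (("+", q_fwd), ("-", q_rev)):
            mism = (windows != q).sum(axis=1)
            for off in np.nonzero(mism <= L - math.ceil(min_identity * L - 1e-9))[0]:
                ident = (L - int(mism[off])) / L
                if ident >= min_identity - 1e-12:
                    out.add((rec.id, int(off), strand, ident))
    return out


def brute_force_adapter(
    bases: str,
    adapter: str,
    error_rate: float = 0.1,
    max_offset: int = 5,
) -> tuple[int, int] | None:
    """Enumerate every (offset, mismatch) pair; pick min by (offset, mismatches)."""
    max_mm = math.floor(error_rate * len(adapter))
    qualifying = []
    for off in range(max_offset + 1):
        seg = bases[off : off + len(adapter)]
        if len(seg) < len(adapter):
            continue
        mm = sum(a != b for a, b in zip(seg, adapter))
        if mm <= max_mm:
            qualifying.append((off, mm))
    return min(qualifying) if qualifying else None


def brute_force_orfs(seq: str, min_aa: int) -> set[tuple[str, int, int, int]]:
    """(strand, frame, length_aa, nt_start) of every stop-free stretch >= min_aa.

    Walks stop-codon boundary positions explicitly instead of splitting
    the translated string.
    """
    out: set[tuple[str, int, int, int]] = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            ncod = (n - frame) // 3
            prot = str(Seq(s[frame : frame + 3 * ncod]).translate())
            stops = [i for i, c in enumerate(prot) if c == "*"]
            bounds = [-1] + stops + [len(prot)]
            for a, b in zip(bounds, bounds[1:]):
                length = b - a - 1
                if length >= min_aa:
                    nt_a = frame + 3 * (a + 1)
                    nt_b = frame + 3 * b
                    if strand == "-":
                        nt_a, nt_b = n - nt_b, n - nt_a
                    out.add((strand, frame, length, nt_a))
    return out
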