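"""TE end-hit search, insertion pairing and target-site-duplication extraction.

hAT-family DNA transposons carry terminal inverted repeats, so a single
end sequence finds both boundaries of a copy: a plus-strand hit marks the
left end and a minus-strand hit of the same query marks the right end.
Insertion of the element duplicates the 8-bp target site on both flanks;
a candidate is accepted as a genuine insertion when the two flanking
8-mers agree at >= 7 of 8 positions (Hamming distance <= 1).

The built-in matcher is gapless seed-and-extend.  The query is split into
m+1 non-overlapping seed segments (m = the mismatch budget implied by
``min_identity``), so by pigeonhole every genome locus within the budget
contains at least one exact seed; each seeded locus is then scored over
the full query length.  This makes the matcher exactly equivalent to a
brute-force scan at every offset on both strands.  Gapped or partial
alignments from an external aligner can be substituted via
:func:`load_hit_table`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .core import (
    BASES,
    GenomicInterval,
    SequenceRecord,
    genome_composition,
    hamming,
    reverse_complement,
)
from .logo import LogoProfile, build_count_matrix, make_profile, to_frequency

logger = logging.getLogger(__name__)

SEED_K = 12  # seed segment length cap


class HitTableFormatError(ValueError):
    """Raised for malformed external alignment tables."""


class FlankUnavailableError(ValueError):
    """Raised when a candidate sits too close to a contig edge for its TSD."""


@dataclass(frozen=True)
class EndHit:
    """One gapless match of a TE end query in the genome."""

    interval: GenomicInterval
    query_id: str
    identity: float
    matched_length: int

    @property
    def contig(self) -> str:
        return self.interval.contig

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class CandidateInsertion:
    """A putative element delimited by a plus/minus end-hit pair."""

    contig: str
    element_start: int
    element_end: int
    left_hit: EndHit
    right_hit: EndHit
    orientation: str = "+"


@dataclass
class TSDPair:
    """The two flanking 8-mers of a candidate and their agreement."""

    upstream: str
    downstream: str
    hamming: int
    valid: bool
    tsd_len: int = 8


@dataclass
class DiscoveryReport:
    """Everything the discovery pipeline produces for one genome/query run."""

    candidates: list[CandidateInsertion]
    tsd_pairs: list[TSDPair]
    elements: list[SequenceRecord]
    n_hits: int
    n_pairs: int
    n_tsd_valid: int
    n_flank_unavailable: int

    def valid_tsd_seqs(self) -> list[str]:
        """Upstream copy of each TSD-valid insertion (one per insertion)."""
        return [t.upstream for t in self.tsd_pairs if t.valid]

    def tsd_logo(self, background) -> LogoProfile:
        seqs = self.valid_tsd_seqs()
        tsd_len = self.tsd_pairs[0].tsd_len if self.tsd_pairs else 8
        counts = build_count_matrix(seqs, tsd_len)
        return make_profile(to_frequency(counts), background)


def _seed_plan(query_len: int, min_identity: float) -> tuple[int, int]:
    """Return (mismatch budget m, seed length k) for a pigeonhole-safe plan."""
    m = int((1.0 - min_identity) * query_len + 1e-9)
    k = min(SEED_K, query_len // (m + 1))
    return m, k


def _scan_one_strand(
    contig_seq: str,
    pattern: str,
    max_mismatches: int,
    seed_k: int,
) -> list[tuple[int, int]]:
    """Candidate (offset, mismatches) pairs for a gapless pattern search.

    Seeds are the first m+1 non-overlapping k-mers of the pattern; any
    occurrence with <= m mismatches must contain one exact seed.
    """
    L = len(pattern)
    n = len(contig_seq)
    candidates: set[int] = set()
    for seg in range(max_mismatches + 1):
        seg_off = seg * seed_k
        seed = pattern[seg_off : seg_off + seed_k]
        pos = contig_seq.find(seed)
        while pos != -1:
            off = pos - seg_off
            if 0 <= off <= n - L:
                candidates.add(off)
            pos = contig_seq.find(seed, pos + 1)
    hits = []
    for off in candidates:
        mm = hamming(contig_seq[off : off + L], pattern)
        if mm <= max_mismatches:
            hits.append((off, mm))
    return hits


def find_end_hits(
    genome: list[SequenceRecord],
    query: SequenceRecord,
    min_identity: float = 0.9,
    min_length: int | None = None,
) -> list[EndHit]:
    """All gapless full-length matches of the end query, both strands.

    A locus is reported once per (contig, offset, strand) when its
    identity over the full query length is >= ``min_identity``.  Hits are
    sorted by (contig, start, strand); the result is deterministic.
    """
    L = len(query.sequence)
    if min_length is None:
        min_length = L
    if not (12 <= min_length <= L):
        raise ValueError(f"need query length >= min_length >= 12, got {L} / {min_length}")
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")

    m, k = _seed_plan(L, min_identity)
    patterns = {"+": query.sequence, "-": reverse_complement(query.sequence)}
    hits: list[EndHit] = []
    for rec in genome:
        for strand, pattern in patterns.items():
            for off, mm in _scan_one_strand(rec.sequence, pattern, m, k):
                identity = (L - mm) / L
                hits.append(
                    EndHit(
                        interval=GenomicInterval(rec.id, off, off + L, strand),
                        query_id=query.id,
                        identity=identity,
                        matched_length=L,
                    )
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def load_hit_table(path: str | Path) -> list[EndHit]:
    """Load an external aligner's 12-column tabular output (outfmt-6 dialect).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Subject coordinates are 1-based
    inclusive; sstart > send encodes the minus strand.
    """
    hits: list[EndHit] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if len(row) != 12:
                raise HitTableFormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(row)}"
                )
            qseqid, sseqid, pident, length = row[0], row[1], float(row[2]), int(row[3])
            sstart, send = int(row[8]), int(row[9])
            if sstart <= send:
                start, end, strand = sstart - 1, send, "+"
            else:
                start, end, strand = send - 1, sstart, "-"
            hits.append(
                EndHit(
                    interval=GenomicInterval(sseqid, start, end, strand),
                    query_id=qseqid,
                    identity=pident / 100.0,
                    matched_length=length,
                )
            )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def pair_insertions(
    hits: list[EndHit],
    min_element: int = 500,
    max_element: int = 20_000,
) -> list[CandidateInsertion]:
    """Pair each plus-strand hit with its nearest downstream minus-strand hit.

    Greedy left-to-right over hits sorted by (contig, start); both hits
    must be of the same query (terminal-inverted-repeat geometry), each
    hit is consumed at most once, and the element span (plus start to
    minus end) must lie within [min_element, max_element].  Nearest-span
    ties break to the lower start coordinate, which the sort guarantees.
    """
    if min_element >= max_element:
        raise ValueError("min_element must be < max_element")
    hits = sorted(hits, key=lambda h: (h.contig, h.start, h.strand))
    used = [False] * len(hits)
    out: list[CandidateInsertion] = []
    for i, left in enumerate(hits):
        if used[i] or left.strand != "+":
            continue
        best_j = -1
        best_span = None
        for j in range(i + 1, len(hits)):
            right = hits[j]
            if right.contig != left.contig or right.start - left.start > max_element:
                break  # sorted by start: nothing further can fit the window
            if used[j] or right.strand != "-" or right.query_id != left.query_id:
                continue
            if right.start < left.end:
                continue
            span = right.end - left.start
            if not (min_element <= span <= max_element):
                continue
            if best_span is None or span < best_span:
                best_span, best_j = span, j
        if best_j >= 0:
            used[i] = used[best_j] = True
            right = hits[best_j]
            out.append(
                CandidateInsertion(
                    contig=left.contig,
                    element_start=left.start,
                    element_end=right.end,
                    left_hit=left,
                    right_hit=right,
                    orientation="+",
                )
            )
    return out


def extract_tsd(
    genome: list[SequenceRecord],
    ins: CandidateInsertion,
    tsd_len: int = 8,
) -> TSDPair:
    """The flanking ``tsd_len``-mers of a candidate and their Hamming distance.

    valid <=> hamming <= tsd_len - 7 (i.e. <= 1 for the default 8-mer,
    the ">= 7 of 8 identical" rule) and neither copy contains N.
    """
    rec = next((r for r in genome if r.id == ins.contig), None)
    if rec is None:
        raise KeyError(f"contig {ins.contig!r} not in genome")
    if ins.element_start < tsd_len or ins.element_end + tsd_len > len(rec.sequence):
        raise FlankUnavailableError(
            f"candidate at {ins.contig}:{ins.element_start}-{ins.element_end} "
            f"too close to contig edge for a {tsd_len}-bp flank"
        )
    upstream = rec.sequence[ins.element_start - tsd_len : ins.element_start]
    downstream = rec.sequence[ins.element_end : ins.element_end + tsd_len]
    hd = hamming(upstream, downstream)
    valid = hd <= tsd_len - 7 and "N" not in upstream and "N" not in downstream
    return TSDPair(upstream=upstream, downstream=downstream, hamming=hd, valid=valid, tsd_len=tsd_len)


def discover(
    genome: list[SequenceRecord],
    end_query: SequenceRecord,
    min_identity: float = 0.9,
    min_length: int | None = None,
    min_element: int = 500,
    max_element: int = 20_000,
    tsd_len: int = 8,
) -> DiscoveryReport:
    """Full discovery pass: end hits -> insertion pairs -> TSD validation.

    Returns a report with every candidate, its TSD pair, the element
    sequence, and summary counts (hits, pairs, TSD-valid, edge-excluded).
    """
    hits = find_end_hits(genome, end_query, min_identity=min_identity, min_length=min_length)
    pairs = pair_insertions(hits, min_element=min_element, max_element=max_element)
    by_contig = {r.id: r for r in genome}
    candidates: list[CandidateInsertion] = []
    tsds: list[TSDPair] = []
    elements: list[SequenceRecord] = []
    n_valid = 0
    n_edge = 0
    for idx, cand in enumerate(pairs):
        try:
            tsd = extract_tsd(genome, cand, tsd_len=tsd_len)
        except FlankUnavailableError:
            n_edge += 1
            continue
        candidates.append(cand)
        tsds.append(tsd)
        n_valid += tsd.valid
        seq = by_contig[cand.contig].sequence[cand.element_start : cand.element_end]
        elements.append(
            SequenceRecord(
                id=f"insertion_{len(candidates)}",
                sequence=seq,
                description=(
                    f"insertion_{len(candidates)} {cand.contig}:"
                    f"{cand.element_start + 1}-{cand.element_end} tsd={tsd.upstream} "
                    f"hamming={tsd.hamming} valid={int(tsd.valid)}"
                ),
            )
        )
    return DiscoveryReport(
        candidates=candidates,
        tsd_pairs=tsds,
        elements=elements,
        n_hits=len(hits),
        n_pairs=len(pairs),
        n_tsd_valid=n_valid,
        n_flank_unavailable=n_edge,
    )


def write_insertions_bed(report: DiscoveryReport, path: str | Path) -> None:
    """BED6: name=insertion id, score=100*min hit identity, strand=orientation."""
    with open(path, "w") as fh:
        for i, cand in enumerate(report.candidates, start=1):
            score = int(round(100 * min(cand.left_hit.identity, cand.right_hit.identity)))
            fh.write(
                f"{cand.contig}\t{cand.element_start}\t{cand.element_end}\t"
                f"insertion_{i}\t{score}\t{cand.orientation}\n"
            )


def write_tsd_table(report: DiscoveryReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#insertion_id\tcontig\tstart\tend\tupstream\tdownstream\thamming\tvalid\n")
        for i, (cand, tsd) in enumerate(zip(report.candidates, report.tsd_pairs), start=1):
            fh.write(
                f"insertion_{i}\t{cand.contig}\t{cand.element_start}\t{cand.element_end}\t"
                f"{tsd.upstream}\t{tsd.downstream}\t{tsd.hamming}\t{int(tsd.valid)}\n"
            )
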