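"""Synthetic genomes, planted TE insertions and tagmentation reads.

Ground truth for every other module: genomes drawn i.i.d. from a chosen
composition; copies of a transposon planted with the 8-bp target site
duplicated on both flanks, the target chosen among *resident* 8-mers by
rejection sampling under a position-frequency bias model (mimicking a
transposase selecting among existing sites, and leaving the genome
composition intact); optional post-insertion degradation of copies; and
adapter-prefixed reads whose first 28 post-adapter bases follow a known
TSD+flank matrix, with i.i.d. sequencing errors and adapter-free decoys.

All generators are bit-reproducible given (seed, parameters); random
streams are split per operation so changing one rate leaves the other
draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import BASES, Background, SequenceRecord, reverse_complement
from .readbias import ReadRecord, write_fastq

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stream tags: independent substreams derived from the user seed
_STREAM_GENOME = 7
_STREAM_SITES = 11
_STREAM_DEGRADE = 13
_STREAM_READS = 17


class SamplingFailureError(RuntimeError):
    """Raised when rejection sampling cannot place the requested insertions."""


@dataclass
class InsertionTruth:
    """Ground truth for one planted copy.

    ``site`` is the 0-based position of the original (pre-duplication)
    target 8-mer on the input genome; ``element_start``/``element_end``
    are the copy's span on the *output* genome.  ``mutations`` lists
    (position-within-element, from, to) substitutions applied later by
    :func:`degrade_copies`.
    """

    contig: str
    site: int
    tsd: str
    element_copy_id: str
    element_start: int
    element_end: int
    mutations: list[tuple[int, str, str]] = field(default_factory=list)


@dataclass
class BiasModel:
    """Generating counterpart of the recovered frequency matrix.

    ``tsd_freqs`` (8x4, A/C/G/T order) weights target-site selection;
    ``flank_freqs`` (20x4) optionally shapes simulated read flanks.
    """

    tsd_freqs: np.ndarray
    flank_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tsd_freqs = self._check("tsd_freqs", self.tsd_freqs)
        if self.flank_freqs is not None:
            self.flank_freqs = self._check("flank_freqs", self.flank_freqs)

    @staticmethod
    def _check(name: str, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"{name} must be an Lx4 matrix")
        if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{name} rows must be non-negative and sum to 1")
        return m

    @classmethod
    def uniform(cls, tsd_len: int = 8, flank_len: int | None = None) -> "BiasModel":
        flank = np.full((flank_len, 4), 0.25) if flank_len else None
        return cls(np.full((tsd_len, 4), 0.25), flank)

    @classmethod
    def single_base_bias(
        cls,
        positions: list[int],
        base: str = "A",
        p: float = 0.8,
        tsd_len: int = 8,
        flank_len: int | None = None,
    ) -> "BiasModel":
        """Uniform matrix except ``p`` for ``base`` at the given 0-based rows."""
        m = np.full((tsd_len, 4), 0.25)
        bi = BASES.index(base)
        for pos in positions:
            row = np.full(4, (1.0 - p) / 3.0)
            row[bi] = p
            m[pos] = row
        flank = np.full((flank_len, 4), 0.25) if flank_len else None
        return cls(m, flank)


def _indices_to_dna(idx: np.ndarray) -> str:
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def simulate_genome(
    length: int,
    composition: Background | None = None,
    seed: int = 0,
    name: str = "chr1",
) -> SequenceRecord:
    """Genome of i.i.d. bases drawn from ``composition`` (default uniform)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    composition = composition or Background.uniform()
    rng = np.random.default_rng([seed, _STREAM_GENOME])
    idx = rng.choice(4, size=length, p=composition.array)
    return SequenceRecord(name, _indices_to_dna(idx), f"{name} simulated length={length}")


def default_element(tir_len: int = 30, orf_aa: int = 674, total_len: int = 2100) -> SequenceRecord:
    """The default synthetic transposon: 2.1 kb, perfect 30-bp terminal
    inverted repeats, and an internal 674-codon ORF bounded by stops.

    Deterministic (internally seeded); the right end is the reverse
    complement of the left, so one end query hits both boundaries.
    """
    rng = np.random.default_rng(20211220)
    sense_codons = [
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    lir = _indices_to_dna(rng.choice(4, size=tir_len))
    orf = "ATG" + "".join(rng.choice(sense_codons, size=orf_aa - 1))
    core = "TAA" + orf + "TAA"
    pad = total_len - 2 * tir_len - len(core) - 6
    if pad < 0:
        raise ValueError("total_len too small for the requested ORF and TIRs")
    spacer1 = _indices_to_dna(rng.choice(4, size=6))
    spacer2 = _indices_to_dna(rng.choice(4, size=pad))
    seq = lir + spacer1 + core + spacer2 + reverse_complement(lir)
    return SequenceRecord(
        "te_default",
        seq,
        f"te_default synthetic element len={len(seq)} tir={tir_len} orf_aa={orf_aa}",
    )


def element_end_query(te: SequenceRecord, length: int = 30) -> SequenceRecord:
    """The left-end prefix of an element, used as the search query."""
    return SequenceRecord(f"{te.id}_LE{length}", te.sequence[:length], f"left end {length} bp")


def plant_insertions(
    genome: SequenceRecord,
    te: SequenceRecord,
    n: int,
    bias: BiasModel | None = None,
    seed: int = 0,
    max_proposals: int | None = None,
) -> tuple[SequenceRecord, list[InsertionTruth]]:
    """Plant ``n`` non-overlapping copies of ``te`` with TSD duplication.

    Candidate target positions are uniform; a candidate's resident 8-mer
    is accepted with probability proportional to the product of the bias
    matrix entries at its bases (rejection sampling).  At each accepted
    site the 8-mer is duplicated to flank the inserted element.
    """
    bias = bias or BiasModel.uniform()
    tsd_len = bias.tsd_freqs.shape[0]
    g = genome.sequence
    L0 = len(g)
    if n * (len(te.sequence) + tsd_len) > L0:
        raise ValueError("insertions would exceed genome length; use a larger genome")
    rng = np.random.default_rng([seed, _STREAM_SITES])
    w_max = float(np.prod(bias.tsd_freqs.max(axis=1)))
    if w_max <= 0:
        raise SamplingFailureError("bias matrix admits no acceptable site")
    base_idx = {b: i for i, b in enumerate(BASES)}
    chosen: list[int] = []
    limit = max_proposals if max_proposals is not None else max(20_000, 5_000 * n)
    proposals = 0
    while len(chosen) < n:
        proposals += 1
        if proposals > limit:
            raise SamplingFailureError(
                f"placed {len(chosen)}/{n} insertions after {proposals - 1} proposals; "
                "the bias model may assign near-zero weight to this genome's 8-mers"
            )
        s = int(rng.integers(0, L0 - tsd_len + 1))
        if any(abs(s - c) < tsd_len for c in chosen):
            continue
        kmer = g[s : s + tsd_len]
        if "N" in kmer:
            continue
        w = float(np.prod([bias.tsd_freqs[i, base_idx[b]] for i, b in enumerate(kmer)]))
        if rng.random() >= w / w_max:
            continue
        chosen.append(s)
    chosen.sort()

    parts: list[str] = []
    truths: list[InsertionTruth] = []
    prev = 0
    te_len = len(te.sequence)
    for i, s in enumerate(chosen):
        parts.append(g[prev : s + tsd_len])
        parts.append(te.sequence)
        prev = s
        start = s + tsd_len + i * (te_len + tsd_len)
        truths.append(
            InsertionTruth(
                contig=genome.id,
                site=s,
                tsd=g[s : s + tsd_len],
                element_copy_id=f"{te.id}_copy{i + 1}",
                element_start=start,
                element_end=start + te_len,
            )
        )
    parts.append(g[prev:])
    new_seq = "".join(parts)
    out = SequenceRecord(genome.id, new_seq, f"{genome.id} with {n} planted {te.id} copies")
    return out, truths


def degrade_copies(
    genome: SequenceRecord,
    truths: list[InsertionTruth],
    sub_rate: float,
    seed: int = 0,
    protect_terminal: int = 30,
) -> tuple[SequenceRecord, list[InsertionTruth]]:
    """Substitute internal bases of each planted copy i.i.d. at ``sub_rate``.

    TSD flanks and the terminal ``protect_terminal`` bases of each copy
    (the inverted repeats) are never touched; every substitution is
    recorded in the truth entries.
    """
    if not (0.0 <= sub_rate < 0.2):
        raise ValueError("sub_rate must be in [0, 0.2)")
    rng = np.random.default_rng([seed, _STREAM_DEGRADE])
    seq = bytearray(genome.sequence, "ascii")
    base_idx = {ord(b): i for i, b in enumerate(BASES)}
    for truth in truths:
        lo = truth.element_start + protect_terminal
        hi = truth.element_end - protect_terminal
        if hi <= lo:
            continue
        span = hi - lo
        mask = rng.random(span) < sub_rate
        shifts = rng.integers(1, 4, size=span)  # drawn unconditionally: stable streams
        for off in np.nonzero(mask)[0]:
            pos = lo + int(off)
            old = seq[pos]
            if old not in base_idx:
                continue
            new = _BASE_BYTES[(base_idx[old] + int(shifts[off])) % 4]
            seq[pos] = new
            truth.mutations.append(
                (pos - truth.element_start, chr(old), chr(new))
            )
    out = SequenceRecord(genome.id, seq.decode("ascii"), genome.description + f" sub_rate={sub_rate}")
    return out, truths


def simulate_tagmented_reads(
    bias: BiasModel,
    adapter: str,
    n_reads: int,
    read_len: int = 75,
    seq_error: float = 0.0,
    seed: int = 0,
    decoy_fraction: float = 0.0,
    background: Background | None = None,
    out_path: str | Path | None = None,
) -> list[ReadRecord]:
    """Simulate tagmentation reads: adapter + 8 TSD + 20 flank + filler.

    TSD bases follow ``bias.tsd_freqs``, flank bases ``bias.flank_freqs``
    (background if absent), the filler the background composition; i.i.d.
    substitution errors at ``seq_error``; each read is independently a
    decoy (pure background, no adapter) with probability
    ``decoy_fraction``.  Writes FASTQ when ``out_path`` is given.
    """
    background = background or Background.uniform()
    adapter = adapter.upper()
    tsd_len = bias.tsd_freqs.shape[0]
    flank = bias.flank_freqs if bias.flank_freqs is not None else np.full((20, 4), background.array)
    flank_len = flank.shape[0]
    if read_len < len(adapter) + tsd_len + flank_len:
        raise ValueError("read_len must cover adapter + TSD + flank")
    rng = np.random.default_rng([seed, _STREAM_READS])

    # background-filled matrix of base indices, then overwrite insert reads
    idx = rng.choice(4, size=(n_reads, read_len), p=background.array)
    decoy = rng.random(n_reads) < decoy_fraction
    insert_rows = np.nonzero(~decoy)[0]
    a_idx = np.array([BASES.index(b) for b in adapter])
    idx[insert_rows, : len(adapter)] = a_idx
    for i in range(tsd_len):
        idx[insert_rows, len(adapter) + i] = rng.choice(4, size=insert_rows.size, p=bias.tsd_freqs[i])
    for i in range(flank_len):
        idx[insert_rows, len(adapter) + tsd_len + i] = rng.choice(
            4, size=insert_rows.size, p=flank[i]
        )
    if seq_error > 0:
        err = rng.random((n_reads, read_len)) < seq_error
        shift = rng.integers(1, 4, size=(n_reads, read_len))
        idx = np.where(err, (idx + shift) % 4, idx)

    reads = [
        ReadRecord(id=f"read_{i + 1}", bases=_indices_to_dna(idx[i]))
        for i in range(n_reads)
    ]
    if out_path is not None:
        write_fastq(reads, out_path)
    return reads


def write_truth_tables(
    truths: list[InsertionTruth],
    bed_path: str | Path,
    tsv_path: str | Path,
    config: dict | None = None,
) -> None:
    """Truth as BED6 (element spans on the output genome) and a detail TSV."""
    header = "".join(f"#{k}={v}\n" for k, v in (config or {}).items())
    with open(bed_path, "w") as fh:
        fh.write(header)
        for t in truths:
            fh.write(
                f"{t.contig}\t{t.element_start}\t{t.element_end}\t{t.element_copy_id}\t0\t+\n"
            )
    with open(tsv_path, "w") as fh:
        fh.write(header)
        fh.write("#contig\tsite\ttsd\telement_copy_id\telement_start\telement_end\tn_mutations\n")
        for t in truths:
            fh.write(
                f"{t.contig}\t{t.site}\t{t.tsd}\t{t.element_copy_id}\t"
                f"{t.element_start}\t{t.element_end}\t{len(t.mutations)}\n"
            )
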