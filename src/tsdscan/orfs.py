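"""ORF finding within discovered elements and consensus-protein derivation.

An intact hAT transposon encodes a single transposase of roughly 500-700
amino acids.  Genomic copies are usually degraded (missense and
frameshift mutations), so no single copy need carry an intact gene; the
working protein sequence is instead recovered as a per-column majority
consensus over an alignment of the surviving ORFs.

ORFs are defined stop-to-stop (maximal stretches free of internal stop
codons in any of the six frames), not ATG-initiated, so that truncated
and degraded copies still surface; an ATG-anchored mode is available.
Multiple sequence alignment itself is consumed as input, never computed.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .core import SequenceRecord, reverse_complement


class AlignmentError(ValueError):
    """Raised for ragged or undersized input alignments."""


@dataclass
class ORFRecord:
    """A stop-free translated stretch within an element.

    Coordinates are 0-based half-open on the element's forward strand
    regardless of the ORF's strand; ``partial`` marks stretches truncated
    by the element edge rather than bounded by stop codons.
    """

    element_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    protein: str
    length_aa: int
    partial: bool

    @property
    def orf_id(self) -> str:
        return f"{self.element_id}|{self.strand}|f{self.frame}|{self.nt_start}-{self.nt_end}"


@dataclass
class ConsensusProtein:
    """Majority-rule consensus over an alignment, with per-column support."""

    sequence: str
    support: list[float]
    n_inputs: int


def find_orfs(
    element: SequenceRecord,
    min_aa: int = 400,
    require_atg: bool = False,
) -> list[ORFRecord]:
    """Scan all six frames for ORFs of at least ``min_aa`` residues.

    An ORF is a maximal stop-to-stop stretch translated with the standard
    code; a stretch touching the element edge (no bounding stop on that
    side) is reported with ``partial=True``.  With ``require_atg`` the
    stretch is trimmed to its first methionine.  Results are sorted by
    length descending.
    """
    seq = element.sequence
    n = len(seq)
    out: list[ORFRecord] = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            ncod = (n - frame) // 3
            if ncod == 0:
                continue
            prot = str(Seq(s[frame : frame + 3 * ncod]).translate())
            # walk the stop-separated stretches, tracking codon offsets
            start_cod = 0
            for chunk in prot.split("*"):
                end_cod = start_cod + len(chunk)
                left_bounded = start_cod > 0  # preceded by a stop codon
                right_bounded = end_cod < len(prot)  # followed by a stop codon
                aa_start, stretch = start_cod, chunk
                if require_atg:
                    m = stretch.find("M")
                    if m == -1:
                        start_cod = end_cod + 1
                        continue
                    aa_start += m
                    stretch = stretch[m:]
                if len(stretch) >= min_aa:
                    nt_a = frame + 3 * aa_start
                    nt_b = frame + 3 * end_cod
                    if strand == "-":
                        nt_a, nt_b = n - nt_b, n - nt_a
                    out.append(
                        ORFRecord(
                            element_id=element.id,
                            strand=strand,
                            frame=frame,
                            nt_start=nt_a,
                            nt_end=nt_b,
                            protein=stretch,
                            length_aa=len(stretch),
                            partial=not (left_bounded and right_bounded),
                        )
                    )
                start_cod = end_cod + 1
    out.sort(key=lambda o: (-o.length_aa, o.strand, o.frame, o.nt_start))
    return out


def load_annotation_table(path: str | Path) -> dict[str, dict[str, str]]:
    """External per-ORF annotations: TSV with orf_id, homology_hit, domain_present."""
    table: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 columns "
                    f"(orf_id, homology_hit, domain_present), got {len(row)}"
                )
            table[row[0]] = {"homology_hit": row[1], "domain_present": row[2]}
    return table


def screen_orfs(
    orfs: list[ORFRecord],
    min_aa: int = 400,
    annotations: dict[str, dict[str, str]] | None = None,
    require_domain: bool = False,
) -> list[ORFRecord]:
    """Size filter plus optional external homology/domain annotation filter.

    Homology search and domain scanning are external steps: their results
    enter as an annotation table keyed by orf_id.  With ``require_domain``
    ORFs annotated ``domain_present=false`` are dropped (unannotated ORFs
    are kept).
    """
    kept = [o for o in orfs if o.length_aa >= min_aa]
    if annotations is not None and require_domain:
        kept = [
            o
            for o in kept
            if annotations.get(o.orf_id, {}).get("domain_present", "true").lower() != "false"
        ]
    return kept


def write_orf_fasta(orfs: list[ORFRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(
                f">{o.orf_id} length_aa={o.length_aa} partial={int(o.partial)}\n{o.protein}\n"
            )


def consensus_from_alignment(aligned: list[SequenceRecord]) -> ConsensusProtein:
    """Per-column majority consensus over an aligned protein set ('-' gaps).

    Columns gapped in more than half the inputs are dropped; elsewhere
    the most frequent non-gap residue wins (ties alphabetical) with
    support = winner count / non-gap count.
    """
    if len(aligned) < 2:
        raise AlignmentError("consensus needs at least 2 aligned sequences")
    length = len(aligned[0].sequence)
    if any(len(r.sequence) != length for r in aligned):
        raise AlignmentError("aligned sequences must all have equal length")
    residues: list[str] = []
    support: list[float] = []
    n = len(aligned)
    for col in range(length):
        column = [r.sequence[col] for r in aligned]
        non_gap = [c for c in column if c != "-"]
        if len(non_gap) * 2 < n:  # gap in > 50% of inputs
            continue
        counts = Counter(non_gap)
        top = max(counts.values())
        best = min(c for c in counts if counts[c] == top)  # ties alphabetical
        residues.append(best)
        support.append(top / len(non_gap))
    return ConsensusProtein(sequence="".join(residues), support=support, n_inputs=n)


def write_consensus(cons: ConsensusProtein, fasta_path: str | Path, support_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">consensus n_inputs={cons.n_inputs}\n{cons.sequence}\n")
    with open(support_path, "w") as fh:
        fh.write("#position\tresidue\tsupport\n")
        for i, (res, sup) in enumerate(zip(cons.sequence, cons.support), start=1):
            fh.write(f"{i}\t{res}\t{sup:.6f}\n")
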