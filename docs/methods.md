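# Methods

## Discovery model

A hAT-style DNA transposon is modelled as a sequence with terminal
inverted repeats (TIRs): the last bases of the element are the reverse
complement of the first. Searching a genome with the left-end sequence
therefore yields one plus-strand hit at each copy's left boundary and
one minus-strand hit at its right boundary. Insertion creates an 8-bp
target site duplication (TSD): the 8-mer immediately 5' of the element
equals the 8-mer immediately 3' of it, up to mutation accumulated since
insertion. A candidate is accepted as a genuine insertion when the two
flanking 8-mers agree at ≥ 7 of 8 positions. This rule is implemented
strictly as Hamming distance ≤ (tsd_len − 7) with no indels; an
indel-containing duplication is counted as invalid.

### End-hit matcher

The built-in matcher is gapless seed-and-extend. For a query of length
L at minimum identity `t`, the mismatch budget is `m = floor((1−t)·L)`
and the query's first `m+1` non-overlapping segments of length
`k = min(12, floor(L/(m+1)))` serve as exact seeds. By pigeonhole, any
genome locus matching the full query with ≤ m mismatches contains at
least one exact seed, so the matcher provably reports the same hit set
as a brute-force scan scoring every offset on both strands (this
equivalence is tested against an independent numpy sliding-window
oracle). The matcher scores the full query length at each seeded
offset; it does not produce gapped or partial-coverage alignments —
those can be supplied from an external aligner via the 12-column
tabular hit format (qseqid/sseqid/pident/…/sstart/send/…, subject
coordinates 1-based inclusive, sstart > send encoding the minus
strand).

N bases never match anything (a seed containing N cannot occur exactly;
at scoring, N counts as a mismatch).

### Pairing rule

The search itself is symmetric, so pairing imposes the element
geometry: hits sorted by (contig, start) are scanned left to right, and
each unused plus-strand hit is paired with the nearest unused
downstream minus-strand hit of the same query whose span (plus-hit
start to minus-hit end) lies within a window of 500–20,000 bp
(defaults; the default synthetic element is 2.1 kb). Each hit is
consumed at most once and ties break to the lower start coordinate, so
the output is deterministic. Nested or fragmented copies beyond what
this greedy rule resolves are out of scope.

### TSD extraction and logo input

For each paired candidate the two flanking 8-mers are read directly
from the genome; candidates within 8 bp of a contig edge are excluded
and counted. Each TSD-valid insertion contributes exactly one sequence
to the downstream logo — the upstream copy — because the two copies
differ in at most one base and using both would double-count every
site.

## Logo mathematics

Position count matrices exclude any window containing N (the exclusion
is counted). Frequencies use a symmetric pseudocount:
`p_i(b) = (C_i(b)+a) / (n+4a)`, with `a = 0` when n ≥ 50 and `a = 0.5`
otherwise (overridable). The small-sample default guards `log 0` in
tiny synthetic sets without perturbing realistically sized ones.

Per-position information is the Kullback–Leibler divergence in bits
against the genome composition, `D_i = Σ_b p_i(b)·log2(p_i(b)/q(b))`
with `0·log 0 := 0`; `D_i ≥ 0` with equality iff `p_i = q`. The
per-base "bias in bits" is the signed contribution
`h_i(b) = p_i(b)·log2(p_i(b)/q(b))`. This is this package's explicit
convention for composition-adjusted logo bar heights: it reproduces the
expected scale (a base at twice its background frequency `f` scores
`f` bits) and sums to `D_i` over bases. Significance-scaled variants
used by some logo tools are deliberately not implemented; the package
emits the numeric table a plotting layer consumes, not graphics.

The genome composition is computed on the given strand only (not
strand-symmetrized), with N excluded; published per-genome compositions
are near strand-symmetric anyway, and keeping the raw counts makes the
baseline auditable.

## ORFs and consensus

ORFs are stop-to-stop: maximal stretches free of internal stop codons
in any of the six frames, translated with the standard code. This
deliberately does not require ATG initiation because genomic copies are
degraded — frameshifts and nonsense mutations truncate ORFs, and
requiring a start codon would discard informative partials. Stretches
truncated by the element edge are reported with a `partial` flag; an
ATG-anchored mode is available. The default size threshold is 400 aa —
deliberately below the ~500 aa of an intact hAT transposase — to
tolerate truncation while still excluding spurious short ORFs.
Frameshift-aware repair of individual copies is not attempted; degraded
copies simply yield shorter ORFs, and the intact protein is recovered
instead by consensus over copies.

Homology search and protein-domain scanning are external steps: the
package emits candidate ORF FASTA and accepts a per-ORF annotation
table (orf_id, homology_hit, domain_present) whose `domain_present`
column can be used as a filter. Multiple sequence alignment is likewise
consumed, never computed.

The consensus is per-column majority over a supplied alignment: columns
gapped in more than half the inputs are dropped; elsewhere the most
frequent non-gap residue wins, ties breaking alphabetically (a fixed,
documented tie-break rather than an arbitrary one), with support =
winner count / non-gap count. With 10 copies at 5% independent
substitution per residue the probability that a majority of copies
corrupt the same column is negligible, which is why consensus recovery
is essentially exact at that depth.

## Read-bias pipeline

Reads carrying the transposon end oligo at their 5' end are identified
by gapless matching anchored within the first 5 bases, with mismatch
budget `floor(0.1 · adapter length)` (the 0.1 default mirrors common
adapter-trimming practice). Indels are deliberately not allowed in the
match: an indel would shift the register of the downstream 28-base
window, and the TSD analysis depends on exact framing. The leftmost
qualifying offset wins, making the decision deterministic and
enumerable — the matcher is tested against exhaustive (offset,
mismatch) enumeration.

After trimming, the 28 bases following the adapter (8 TSD + 20 flank)
feed the count matrix. Reads where the adapter matches but fewer than
28 bases remain, and windows containing N, are counted separately
rather than silently dropped, so the matched fraction remains
auditable. Paired FASTQ files are processed independently and pooled;
mates are not merged or deduplicated, and both mates are treated
identically. Quality scores are parsed but unused (no quality
trimming). Gzipped FASTQ is detected by magic bytes.

## Synthetic data: what it emulates and what it does not

`simulate_genome` draws i.i.d. bases from a target composition — it has
no repeats, no isochores, no N runs. `plant_insertions` imposes
target-site bias by rejection sampling over *resident* 8-mers
(candidate position uniform; acceptance probability proportional to the
product of bias-matrix entries over the resident bases), mimicking a
transposase choosing among existing sites rather than rewriting the
genome; on a uniform-composition genome the accepted-site marginals
equal the bias-matrix rows, which is what the recovery tests exploit.
Planted sites are pairwise non-overlapping. `degrade_copies` applies
i.i.d. substitutions to copy interiors while protecting the TSDs and
the terminal 30 bp of each copy — real decay would also erode TIRs and
flanks, so recovery rates measured here are an upper bound for real
data. `simulate_tagmented_reads` produces reads structured adapter +
TSD + flank + background filler with i.i.d. substitution errors and
adapter-free decoy reads; there is no quality model, no PCR
duplication, no indel error. Consequently, passing tests demonstrate
the correctness of the algorithms under their stated model, not
robustness to repeat-rich genomes or messy libraries — for real data
the external-aligner hit-table input and the exclusion counters are the
relevant escape hatches.

The default synthetic element is 2.1 kb with perfect 30-bp TIRs and an
internal 674-codon ORF bounded by stops — dimensions chosen to exercise
a realistic intact hAT element. It is a fixed, internally seeded
constant so tests and documentation refer to a single object.

Random streams are split per operation (genome, site choice,
degradation, reads) via seed sequences, so changing one rate leaves the
other draws unchanged — this keeps regression tests stable.

## Numerical and interface choices

* Coordinates: 0-based half-open internally and in BED; 1-based
  inclusive in human-readable descriptions.
* Matrices are ordered A, C, G, T everywhere.
* Frequency rows sum to 1 within 1e-9; analytic logo identities are
  asserted to 1e-9.
* Degenerate inputs (all-N composition, zero usable reads, all-excluded
  windows) raise typed errors rather than returning NaNs; the read
  pipeline attaches its stats to the error so a failed run is still
  auditable.
* CLI: results go to files, logs to stderr; exit 0 on success including
  empty results, 1 on usage errors, 2 on data/format errors. Every run
  writes a summary JSON embedding the resolved configuration and the
  tool version; outputs contain no timestamps, so identical
  configurations give byte-identical results.

## Problem sizes used in validation

The validation suite runs at desk scale: oracle equivalence over 50
random genomes of 50–100 kb with 20–30 bp queries at identities 1.0 and
0.9; adapter-matcher equivalence over 10,000 random 75-bp reads;
planted-insertion recovery with 200 copies in a 1 Mb genome (recovery
is 100% even at 1% substitution because degradation spares the TIRs and
TSDs by construction); bias recovery at n = 200 insertions and 5,000
reads with a 2/3 decoy fraction, with stochastic checks at 3-sigma
binomial tolerances under fixed seeds. These sizes make the binomial
bounds tight enough to be meaningful while keeping the whole suite in
the tens of seconds.

## Known limitations

* The built-in matcher is gapless; diverged TIRs with indels need an
  external aligner.
* Greedy nearest pairing can mispair tandem or nested insertions whose
  boundaries interleave.
* The TSD rule ignores indel-containing duplications.
* Per-base bias uses the signed KL contribution; it is not comparable
  numerically with entropy-logo (small-sample-corrected) letter heights.
* The read profiler assumes mate orientation places the TSD first on
  both mates; libraries violating this need pre-orientation.
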