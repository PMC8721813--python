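"""End-hit search, insertion pairing and TSD extraction."""

import numpy as np
import pytest

from oracles import brute_force_end_hits
from tsdscan import (
    CandidateInsertion,
    EndHit,
    GenomicInterval,
    SequenceRecord,
    discover,
    extract_tsd,
    find_end_hits,
    load_hit_table,
    pair_insertions,
    reverse_complement,
)
from tsdscan.discovery import FlankUnavailableError, HitTableFormatError
from tsdscan.simulate import default_element, element_end_query, plant_insertions, simulate_genome


def _hit(contig, start, end, strand, query="q", identity=1.0):
    return EndHit(GenomicInterval(contig, start, end, strand), query, identity, end - start)


def _random_record(rng, length, name="g"):
    return SequenceRecord(name, "".join("ACGT"[i] for i in rng.integers(0, 4, length)))


class TestFindEndHits:
    def test_exact_planted_copy(self, rng):
        g = _random_record(rng, 10_000)
        query = SequenceRecord("q", g.sequence[1000:1030])
        hits = [h for h in find_end_hits([g], query, min_identity=1.0) if h.start == 1000]
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.identity) == (1000, 1030, "+", 1.0)

    def test_no_match_in_homopolymer(self):
        g = SequenceRecord("g", "A" * 5000)
        query = SequenceRecord("q", "ACCCGTTGACCACGTTAGCA")
        assert find_end_hits([g], query, min_identity=0.9) == []

    def test_reverse_complement_copy_on_minus_strand(self, rng):
        g = _random_record(rng, 5000)
        core = g.sequence[2000:2030]
        query = SequenceRecord("q", reverse_complement(core))
        hits = [h for h in find_end_hits([g], query, min_identity=1.0) if h.start == 2000]
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            find_end_hits([SequenceRecord("g", "A" * 100)], SequenceRecord("q", "ACGTACGT"))

    @pytest.mark.parametrize("min_identity", [1.0, 0.9])
    def test_oracle_equivalence_random_genomes(self, min_identity):
        """Seed-and-extend equals the exhaustive per-offset scan."""
        rng = np.random.default_rng(7)
        for trial in range(8):
            g = _random_record(rng, 20_000, name=f"g{trial}")
            qlen = int(rng.integers(20, 31))
            pos = int(rng.integers(0, 20_000 - qlen))
            query = SequenceRecord("q", g.sequence[pos : pos + qlen])
            got = {
                (h.contig, h.start, h.strand, h.identity)
                for h in find_end_hits([g], query, min_identity=min_identity)
            }
            assert got == brute_force_end_hits([g], query, min_identity)

    def test_mismatched_copy_found_at_reduced_identity(self, rng):
        g = _random_record(rng, 10_000)
        seq = list(g.sequence[4000:4030])
        for i in (3, 17):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        query = SequenceRecord("q", "".join(seq))
        hits = [h for h in find_end_hits([g], query, min_identity=0.9) if h.start == 4000]
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(28 / 30)


class TestLoadHitTable:
    ROW = "q\tchr1\t{pident}\t30\t1\t0\t1\t30\t{sstart}\t{send}\t1e-10\t55.4\n"

    def test_plus_strand_coordinates(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.ROW.format(pident=100.0, sstart=1001, send=1030))
        (h,) = load_hit_table(p)
        assert (h.start, h.end, h.strand) == (1000, 1030, "+")

    def test_minus_strand_coordinates(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.ROW.format(pident=96.7, sstart=1030, send=1001))
        (h,) = load_hit_table(p)
        assert (h.start, h.end, h.strand) == (1000, 1030, "-")
        assert h.identity == pytest.approx(0.967)

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.ROW.format(pident=100.0, sstart=1, send=30) + "a\tb\tc\n")
        with pytest.raises(HitTableFormatError, match="line 2"):
            load_hit_table(p)


class TestPairInsertions:
    def test_single_pair_within_window(self):
        hits = [_hit("c", 100, 130, "+"), _hit("c", 3070, 3100, "-")]
        (cand,) = pair_insertions(hits, 500, 10_000)
        assert (cand.element_start, cand.element_end) == (100, 3100)

    def test_two_plus_hits_pair_nothing(self):
        hits = [_hit("c", 100, 130, "+"), _hit("c", 3070, 3100, "+")]
        assert pair_insertions(hits, 500, 10_000) == []

    def test_nearest_downstream_minus_wins(self):
        hits = [
            _hit("c", 100, 130, "+"),
            _hit("c", 3070, 3100, "-"),
            _hit("c", 8070, 8100, "-"),
        ]
        (cand,) = pair_insertions(hits, 500, 10_000)
        assert cand.element_end == 3100

    def test_each_hit_used_once(self):
        hits = [
            _hit("c", 100, 130, "+"),
            _hit("c", 1100, 1130, "+"),
            _hit("c", 3070, 3100, "-"),
        ]
        cands = pair_insertions(hits, 500, 10_000)
        assert len(cands) == 1 and cands[0].element_start == 100

    def test_window_excludes_out_of_range_spans(self):
        hits = [_hit("c", 0, 30, "+"), _hit("c", 50, 80, "-"), _hit("c", 40_000, 40_030, "-")]
        assert pair_insertions(hits, 500, 20_000) == []

    def test_cross_query_hits_never_pair(self):
        hits = [_hit("c", 100, 130, "+", query="q1"), _hit("c", 3070, 3100, "-", query="q2")]
        assert pair_insertions(hits, 500, 10_000) == []

    def test_disjoint_hit_usage(self, rng):
        starts = sorted(rng.choice(50_000, size=40, replace=False))
        hits = [
            _hit("c", int(s), int(s) + 30, "+" if i % 2 == 0 else "-")
            for i, s in enumerate(starts)
        ]
        cands = pair_insertions(hits, 100, 20_000)
        used = [(c.left_hit.start, c.right_hit.start) for c in cands]
        flat = [s for pair in used for s in pair]
        assert len(flat) == len(set(flat))


class TestExtractTSD:
    def _genome_with_flanks(self, up, down):
        filler = "G" * 50
        seq = filler + up + "C" * 600 + down + filler
        g = SequenceRecord("c", seq)
        cand = CandidateInsertion(
            contig="c",
            element_start=50 + len(up),
            element_end=50 + len(up) + 600,
            left_hit=_hit("c", 58, 88, "+"),
            right_hit=_hit("c", 620, 650, "-"),
        )
        return g, cand

    def test_identical_flanks_valid(self):
        g, cand = self._genome_with_flanks("TATATATA", "TATATATA")
        tsd = extract_tsd([g], cand)
        assert tsd.hamming == 0 and tsd.valid

    def test_one_mismatch_still_valid(self):
        g, cand = self._genome_with_flanks("TATATATA", "TATATATT")
        tsd = extract_tsd([g], cand)
        assert tsd.hamming == 1 and tsd.valid

    def test_two_mismatches_invalid(self):
        g, cand = self._genome_with_flanks("TATATATA", "TGTATATT")
        tsd = extract_tsd([g], cand)
        assert tsd.hamming == 2 and not tsd.valid

    def test_n_in_flank_invalidates(self):
        g, cand = self._genome_with_flanks("TANATATA", "TANATATA")
        assert not extract_tsd([g], cand).valid

    def test_contig_edge_raises(self):
        g = SequenceRecord("c", "A" * 700)
        cand = CandidateInsertion("c", 3, 650, _hit("c", 3, 33, "+"), _hit("c", 620, 650, "-"))
        with pytest.raises(FlankUnavailableError):
            extract_tsd([g], cand)


class TestDiscover:
    def test_all_planted_copies_tsd_valid(self, te):
        genome = simulate_genome(200_000, seed=5)
        genome, truths = plant_insertions(genome, te, 20, seed=5)
        report = discover([genome], element_end_query(te))
        assert report.n_tsd_valid == 20
        found = {(c.element_start, c.element_end) for c in report.candidates}
        assert found == {(t.element_start, t.element_end) for t in truths}
        assert all(t.hamming == 0 for t in report.tsd_pairs)

    def test_mutated_downstream_flank_goes_invalid(self, te):
        genome = simulate_genome(200_000, seed=6)
        genome, truths = plant_insertions(genome, te, 20, seed=6)
        t0 = truths[0]
        seq = bytearray(genome.sequence, "ascii")
        for off in (0, 1):  # two substitutions in the downstream TSD copy
            pos = t0.element_end + off
            seq[pos] = ord("A") if seq[pos] != ord("A") else ord("C")
        genome = SequenceRecord(genome.id, seq.decode())
        report = discover([genome], element_end_query(te))
        assert report.n_pairs == 20
        assert report.n_tsd_valid == 19
        invalid = [t for t in report.tsd_pairs if not t.valid]
        assert len(invalid) == 1 and invalid[0].hamming == 2

    def test_empty_genome_zero_report(self, te):
        report = discover([], element_end_query(te))
        assert (report.n_hits, report.n_pairs, report.n_tsd_valid) == (0, 0, 0)
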