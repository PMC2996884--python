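"""seed_align: seeding, ungapped/gapped extension, pipeline properties."""
import numpy as np
import pytest

from cisarch.seed_align import (DEFAULT_SEED_PATTERN, HOXD70, HSP,
                                ExtensionParams, PairScan, SeedHit,
                                SeedParams, align_pair, filter_hsps,
                                find_seed_hits, gapped_extend,
                                ungapped_extend)
from cisarch.seqio import MaskedSequence
from cisarch.synthetic import make_locus_fixture
from tests.conftest import mutate


def seq(s, id="x"):
    return MaskedSequence.from_string(id, s)


def brute_force_seed_hits(q, t, pattern, strand_mode="forward"):
    """Independent oracle: test the pattern at every position pair."""
    from cisarch.seed_align import _revcomp_codes

    care = [i for i, c in enumerate(pattern) if c == "1"]
    L = len(pattern)
    hits = []
    strands = ("+",) if strand_mode == "forward" else ("+", "-")
    for strand in strands:
        tc = t.codes if strand == "+" else _revcomp_codes(t.codes)
        for i in range(len(q) - L + 1):
            for j in range(len(t) - L + 1):
                ok = all(q.codes[i + k] == tc[j + k] and q.codes[i + k] < 4
                         for k in care)
                if ok:
                    hits.append(SeedHit(i, j, strand))
    return sorted(hits, key=lambda h: (h.strand, h.query_pos, h.target_pos))


class TestSeedParams:
    def test_default_pattern_is_12_of_19(self):
        p = SeedParams()
        assert p.length == 19 and p.weight == 12

    def test_rejects_bad_pattern(self):
        with pytest.raises(ValueError):
            SeedParams("10201")
        with pytest.raises(ValueError):
            SeedParams("0110")  # must end with care positions


class TestFindSeedHits:
    def test_identity_19mer_single_hit(self):
        s = seq("ACGTACGTACGTACGTACG")
        hits = find_seed_hits(s, seq(s.residues, "y"), strand_mode="forward")
        assert (0, 0) in {(h.query_pos, h.target_pos) for h in hits}

    def test_self_comparison_diagonal(self, random_locus):
        hits = find_seed_hits(random_locus, random_locus,
                              strand_mode="forward")
        diag = {(h.query_pos, h.target_pos) for h in hits
                if h.query_pos == h.target_pos}
        assert len(diag) == len(random_locus) - 19 + 1

    def test_too_short_sequence_yields_no_hits(self):
        assert find_seed_hits(seq("ACGT"), seq("ACGT", "y")) == []

    def test_masked_care_position_blocks_window(self):
        s = seq("ACGTACGTACGTACGTACG")
        t = seq("ACGTACGTACGTACGTACg", "y")  # soft-masked last position (care)
        hits = find_seed_hits(s, t, strand_mode="forward")
        assert not hits

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_brute_force_oracle(self, trial, rng):
        q = mutate(make_locus_fixture([60], rng_seed=trial)[0], 0.3, rng, "q")
        t = mutate(q, 0.15, rng, "t")
        got = find_seed_hits(q, t, strand_mode="both")
        want = brute_force_seed_hits(q, t, DEFAULT_SEED_PATTERN, "both")
        assert got == want


class TestUngappedExtend:
    def test_identical_region_extends_to_boundaries(self, random_locus):
        t = MaskedSequence(id="t", residues=random_locus.residues,
                           mask=random_locus.mask.copy())
        h = ungapped_extend(SeedHit(500, 500, "+"), random_locus, t)
        assert (h.query_start, h.query_end) == (0, len(random_locus))
        assert h.mismatches == 0

    def test_immediate_stop_trims_to_seed(self):
        base = make_locus_fixture([60], rng_seed=5)[0]
        arr = list(base.residues)
        tarr = list(arr)
        # mismatches immediately flanking the seed at columns 18,19 and 39,40
        for pos in (18, 19, 39, 40):
            tarr[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arr[pos]]
        q = seq("".join(arr), "q")
        t = seq("".join(tarr), "t")
        h = ungapped_extend(SeedHit(20, 20, "+"), q, t)
        assert (h.query_start, h.query_end) == (20, 39)

    def test_handchecked_two_sided_construction(self):
        # 40-bp pair, seed at columns 10..28; right side: 29=match,
        # 30=mismatch, 31=match, 32=mismatch; left side: 9,8 mismatch.
        base = make_locus_fixture([40], rng_seed=9)[0]
        arr = list(base.residues)
        tarr = list(arr)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for pos in (8, 9, 30, 32):
            tarr[pos] = flip[arr[pos]]
        q = seq("".join(arr), "q")
        t = seq("".join(tarr), "t")
        h = ungapped_extend(SeedHit(10, 10, "+"), q, t)
        # stops at second mismatch each side, trimmed to outermost matches
        assert (h.query_start, h.query_end) == (10, 32)
        assert h.length == 22

    def test_masked_position_stops_extension(self):
        base = make_locus_fixture([60], rng_seed=6)[0]
        arr = list(base.residues)
        arr[45] = "N"
        q = MaskedSequence.from_string("q", "".join(arr))
        t = MaskedSequence.from_string("t", "".join(arr))
        h = ungapped_extend(SeedHit(20, 20, "+"), q, t)
        assert h.query_end == 45  # stops at the masked column


class TestFilterHsps:
    def _hsp(self, start, length, diag=0, score=None):
        return HSP(start, start + length, start + diag, start + diag + length,
                   "+", 0, score if score is not None else length * 91)

    def test_length_threshold(self):
        hsps = [self._hsp(i * 100, l) for i, l in enumerate((19, 22, 23, 40))]
        assert {h.length for h in filter_hsps(hsps, 23)} == {23, 40}
        assert {h.length for h in filter_hsps(hsps, 19)} == {19, 22, 23, 40}

    def test_same_diagonal_overlap_merged_to_longest(self):
        a = self._hsp(0, 30)
        b = self._hsp(10, 50)
        kept = filter_hsps([a, b], 19)
        assert kept == [b]


class TestGappedExtend:
    def test_identical_sequences_full_block(self, random_locus):
        t = MaskedSequence(id="t", residues=random_locus.residues,
                           mask=random_locus.mask.copy())
        blocks = align_pair(random_locus, t)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.query_start, b.query_end) == (0, len(random_locus))
        assert b.gaps == 0

    def test_insertion_bridged_with_one_gap_matches_sw_oracle(self):
        from Bio import Align
        from Bio.Align import substitution_matrices

        parts = make_locus_fixture([200, 200, 10], rng_seed=7)
        q = seq(parts[0].residues + parts[1].residues, "q")
        t = seq(parts[0].residues + parts[2].residues + parts[1].residues, "t")
        blocks = align_pair(q, t)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.gaps == 1

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        m = substitution_matrices.Array("ACGT", 2)
        for i, x in enumerate("ACGT"):
            for j, y in enumerate("ACGT"):
                m[x, y] = HOXD70[i, j]
        aligner.substitution_matrix = m
        aligner.open_gap_score = -430
        aligner.extend_gap_score = -30
        best = aligner.align(q.residues, t.residues)[0]
        assert b.score == best.score
        assert (b.query_start, b.query_end) == (
            best.aligned[0][0][0], best.aligned[0][-1][1])
        assert (b.target_start, b.target_end) == (
            best.aligned[1][0][0], best.aligned[1][-1][1])

    def test_block_contains_anchor_and_threshold_applies(self):
        parts = make_locus_fixture([400, 400], rng_seed=8)
        q, t = parts
        # no real homology: any anchor-free call must return None or a block
        # containing its anchor
        scan = PairScan(q, t)
        for h in scan.hsps()[:5]:
            block = gapped_extend(h, q, t)
            if block is not None:
                assert block.query_start <= h.query_start
                assert block.query_end >= h.query_end


class TestAlignPair:
    def test_symmetry_under_transpose(self, rng):
        q = make_locus_fixture([600], rng_seed=21)[0]
        t = mutate(q, 0.1, rng, "t")
        ab = align_pair(q, t)
        ba = align_pair(t, q)
        fwd = {(b.query_start, b.query_end, b.target_start, b.target_end,
                b.strand, b.score) for b in ab}
        rev = {(b.target_start, b.target_end, b.query_start, b.query_end,
                b.strand, b.score) for b in ba}
        assert fwd == rev

    def test_monotone_in_min_hsp_len(self, rng):
        q = make_locus_fixture([1500], rng_seed=22)[0]
        t = mutate(q, 0.25, rng, "t")
        scan = PairScan(q, t)
        counts = [len(scan.blocks(th)) for th in range(19, 41)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_homologous_exons_only(self, rng):
        # exons shared at ~85% identity, intergenic independent
        ex1 = make_locus_fixture([300], gc=0.5, rng_seed=31)[0]
        flank_q = make_locus_fixture([1000, 1000], rng_seed=32)
        flank_t = make_locus_fixture([1000, 1000], rng_seed=33)
        ex1_t = mutate(ex1, 0.15, rng)
        q = seq(flank_q[0].residues + ex1.residues + flank_q[1].residues, "q")
        t = seq(flank_t[0].residues + ex1_t.residues + flank_t[1].residues, "t")
        blocks = align_pair(q, t)
        assert blocks, "homologous exon should be found"
        for b in blocks:
            assert b.query_start >= 900 and b.query_end <= 1400

    def test_reverse_strand_hit_reported(self, rng):
        core = make_locus_fixture([300], rng_seed=34)[0]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(core.residues))
        flank = make_locus_fixture([500, 500], rng_seed=35)
        q = seq(flank[0].residues + core.residues + flank[1].residues, "q")
        t = seq(flank[1].residues + rc + flank[0].residues, "t")
        blocks = align_pair(q, t)
        minus = [b for b in blocks if b.strand == "-"
                 and b.query_start >= 400 and b.query_end <= 900]
        assert minus
        b = max(minus, key=lambda x: x.score)
        # forward-strand target coordinates of the reverse-complemented core
        assert b.target_start >= 400 and b.target_end <= 900


class TestHspOracleEquivalence:
    """Pipeline HSPs equal brute-force per-diagonal enumeration."""

    @staticmethod
    def oracle_hsps(q, t):
        hits = find_seed_hits(q, t, strand_mode="both")
        hsps = [ungapped_extend(h, q, t) for h in hits]
        return set(filter_hsps(hsps, SeedParams().length))

    @pytest.mark.parametrize("trial", range(10))
    def test_equivalence_on_diverged_pairs(self, trial, rng):
        q = make_locus_fixture([700], rng_seed=600 + trial)[0]
        t = mutate(q, 0.2, rng, "t")
        assert set(PairScan(q, t).hsps()) == self.oracle_hsps(q, t)
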