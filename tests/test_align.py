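"""Aligner unit and property tests, cross-checked against Smith-Waterman.

The independent oracle is Biopython's PairwiseAligner in local mode with
the same scoring scheme (open_gap_score = gap_open + gap_extend so that a
gap of length L costs gap_open + L*gap_extend in both implementations).
"""

import math

import numpy as np
import pytest
from Bio import Align

from conftest import diverged_pair
from genrelate.align import (
    HSP,
    ScoringScheme,
    bit_score,
    find_hsps,
    index_subject,
    read_alignment_tsv,
)
from genrelate.seqs import GenomeSequence, encode, reverse_complement
from genrelate.simulate import generate_ancestor


def sw_aligner(scheme):
    return Align.PairwiseAligner(
        mode="local",
        match_score=scheme.match_reward,
        mismatch_score=scheme.mismatch_penalty,
        open_gap_score=scheme.gap_open + scheme.gap_extend,
        extend_gap_score=scheme.gap_extend,
    )


class TestScoringScheme:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"match_reward": 0},
            {"mismatch_penalty": 1},
            {"gap_open": 0},
            {"lam": -1.0},
            {"k": 1.5},
            {"kmer_size": 4},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoringScheme(**kwargs)


class TestBitScore:
    def test_zero_raw_score_closed_form(self, scheme):
        # (0 - ln 0.41) / ln 2
        assert bit_score(0, scheme) == pytest.approx(
            -math.log(0.41) / math.log(2), abs=1e-9
        )
        assert bit_score(0, scheme) == pytest.approx(1.286, abs=5e-4)

    def test_raw_100_closed_form(self, scheme):
        # (62.5 - ln 0.41) / ln 2 = 91.4547...
        exact = (0.625 * 100 - math.log(0.41)) / math.log(2)
        assert bit_score(100, scheme) == pytest.approx(exact, abs=1e-9)
        assert bit_score(100, scheme) == pytest.approx(91.455, abs=1e-3)

    def test_strictly_increasing(self, scheme):
        assert bit_score(101, scheme) > bit_score(100, scheme)

    def test_negative_raw_rejected(self, scheme):
        with pytest.raises(ValueError):
            bit_score(-1, scheme)


class TestKmerIndex:
    def test_direct_enumeration(self):
        idx = index_subject(GenomeSequence.from_string("s", "ACGTACGT"), 4)
        qpos, spos = idx.lookup(encode("ACGT"))
        assert sorted(spos.tolist()) == [0, 4]

    def test_k_longer_than_sequence_is_empty(self):
        with pytest.warns(UserWarning, match="no indexable"):
            idx = index_subject(
                GenomeSequence.from_string("s", "ACGTACGT"), 11
            )
        assert idx.is_empty

    def test_ambiguous_only_sequence_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="no indexable"):
            idx = index_subject(GenomeSequence.from_string("n", "N" * 64), 11)
        assert idx.is_empty

    def test_positions_verified_by_string_equality(self):
        # brute-force oracle: every reported hit is an exact k-mer match
        g = generate_ancestor(10_000, 0.5, seed=5, id="g")
        idx = index_subject(g, 12)
        query = g.sequence[4321 : 4321 + 300]
        qpos, spos = idx.lookup(encode(query))
        assert len(qpos) > 0
        for q, s in zip(qpos.tolist(), spos.tolist()):
            assert g.sequence[s : s + 12] == query[q : q + 12]


class TestFindHsps:
    def test_identity_region(self, scheme):
        g = generate_ancestor(3000, 0.5, seed=7, id="g")
        idx = index_subject(g, scheme.kmer_size)
        region = g.sequence[500:1520]
        hsps = find_hsps(region, idx, scheme)
        top = hsps[0]
        assert top.strand == "+"
        assert top.identities == top.alignment_length == 1020
        assert (top.subject_start, top.subject_end) == (500, 1520)

    def test_reverse_complement_region(self, scheme):
        g = generate_ancestor(3000, 0.5, seed=7, id="g")
        idx = index_subject(g, scheme.kmer_size)
        region = reverse_complement(g.sequence[500:1520])
        top = find_hsps(region, idx, scheme)[0]
        assert top.strand == "-"
        assert top.identities == 1020
        assert (top.subject_start, top.subject_end) == (500, 1520)

    def test_divergent_pair_identity_within_binomial_band(self, scheme):
        # 3 SD band around 95% for a ~500-column alignment, plus SW raw-score
        # cross-check (gap-free pair: scores must be equal)
        anc, ev, d = diverged_pair(500, 0.05, seed=21)
        idx = index_subject(anc, scheme.kmer_size)
        top = find_hsps(ev.sequence, idx, scheme)[0]
        n = top.alignment_length
        sd = math.sqrt(n * 0.05 * 0.95) / n
        assert top.identity_fraction == pytest.approx(0.95, abs=3 * sd)
        sw = sw_aligner(scheme).score(anc.sequence, ev.sequence)
        assert top.raw_score == sw

    def test_no_seeds_gives_empty_list(self, scheme):
        idx = index_subject(GenomeSequence.from_string("s", "A" * 2000), 11)
        assert find_hsps("C" * 600, idx, scheme) == []

    def test_sorted_by_bit_score(self, scheme):
        anc, ev, _ = diverged_pair(4000, 0.05, seed=31)
        hsps = find_hsps(ev.sequence, index_subject(anc, 11), scheme)
        bits = [h.bit_score for h in hsps]
        assert bits == sorted(bits, reverse=True)


class TestSmithWatermanOracle:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_gap_free_top_score_equals_sw(self, scheme, seed):
        anc, ev, _ = diverged_pair(2000, 0.05, seed=seed)
        top = find_hsps(ev.sequence, index_subject(anc, 11), scheme)[0]
        assert top.raw_score == sw_aligner(scheme).score(
            anc.sequence, ev.sequence
        )

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_gapped_top_score_within_95_percent_of_sw(self, scheme, seed):
        anc, ev, _ = diverged_pair(2000, 0.05, seed=seed, indel_rate=2.0)
        top = find_hsps(ev.sequence, index_subject(anc, 11), scheme)[0]
        sw = sw_aligner(scheme).score(anc.sequence, ev.sequence)
        assert top.raw_score >= 0.95 * sw

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_identity_count_invariant_under_role_swap(self, scheme, seed):
        # gap-free alignments: swapping query and subject roles preserves
        # the identity count of the top HSP
        anc, ev, _ = diverged_pair(1500, 0.04, seed=seed)
        fwd = find_hsps(ev.sequence, index_subject(anc, 11), scheme)[0]
        rev = find_hsps(anc.sequence, index_subject(ev, 11), scheme)[0]
        assert fwd.identities == rev.identities


class TestRoundTrip:
    @pytest.mark.parametrize("indel_rate", [0.0, 2.0])
    @pytest.mark.parametrize("seed", [41, 42])
    def test_rescoring_reproduces_raw_score(self, scheme, seed, indel_rate):
        anc, ev, _ = diverged_pair(1500, 0.05, seed=seed,
                                   indel_rate=indel_rate)
        for h in find_hsps(ev.sequence, index_subject(anc, 11), scheme):
            assert h.rescore(ev.sequence, anc.sequence, scheme) == h.raw_score

    def test_minus_strand_rescore(self, scheme):
        anc, ev, _ = diverged_pair(1200, 0.05, seed=47)
        rc = reverse_complement(ev.sequence)
        for h in find_hsps(rc, index_subject(anc, 11), scheme):
            assert h.strand == "-"
            assert h.rescore(rc, anc.sequence, scheme) == h.raw_score


class TestTabularIngest:
    def test_outfmt6_like_round_trip(self, tmp_path, scheme):
        p = tmp_path / "aln.tsv"
        p.write_text(
            "q1\ts1\t95.0\t1000\t1\t1000\t2001\t3000\t1700.5\t950\n"
            "q1\ts1\t90.0\t500\t1\t500\t800\t301\t700.0\t400\n"
        )
        hsps = read_alignment_tsv(p, scheme)
        assert len(hsps) == 2
        top = hsps[0]
        assert (top.query_start, top.query_end) == (0, 1000)
        assert (top.subject_start, top.subject_end) == (2000, 3000)
        assert top.strand == "+"
        assert top.identities == 950
        minus = hsps[1]
        assert minus.strand == "-"
        assert (minus.subject_start, minus.subject_end) == (300, 800)


class TestHSPInvariants:
    def test_identities_bounds_enforced(self):
        with pytest.raises(ValueError):
            HSP("q", "s", 0, 10, 0, 10, "+", 10, 11, 20, 30.0)

    def test_bit_score_formula_holds_for_produced_hsps(self, scheme):
        anc, ev, _ = diverged_pair(800, 0.03, seed=51)
        for h in find_hsps(ev.sequence, index_subject(anc, 11), scheme):
            expected = (scheme.lam * h.raw_score - math.log(scheme.k)) / \
                math.log(2)
            assert h.bit_score == pytest.approx(expected, abs=1e-9)
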