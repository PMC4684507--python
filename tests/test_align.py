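import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import sw_oracle

from xorfeome.align import (
    ContigIndex,
    ScoringParams,
    best_cluster_match,
    local_align,
    tag_similarity,
)
from xorfeome.model import CloneRecord, EstContig, SequenceTag, XorfeomeError

UNIT = ScoringParams(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0)

nucseq = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestLocalAlign:
    def test_self_alignment_full_identity(self):
        rng = random.Random(3)
        s = "".join(rng.choice("ACGT") for _ in range(100))
        (hit,) = local_align(s, s)
        assert hit.identity_pct == 100.0
        assert (hit.q_start, hit.q_end) == (0, 100)
        assert (hit.s_start, hit.s_end) == (0, 100)

    def test_single_mismatch_score_and_identity(self):
        # exhaustive-DP-checked example: 7 matches, 1 mismatch, no gap wins
        (hit,) = local_align("ACGTACGT", "ACGAACGT", UNIT)
        assert hit.raw_score == 6.0
        assert hit.identity_pct == pytest.approx(87.5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(XorfeomeError):
            local_align("", "ACGT")

    def test_non_nucleotide_rejected(self):
        with pytest.raises(XorfeomeError):
            local_align("ACGT", "ACXT")

    def test_n_never_counts_as_match(self):
        (hit,) = local_align("ACGTNNACGT", "ACGTNNACGT")
        assert hit.n_matches == 8

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(q=nucseq, s=nucseq)
    def test_score_matches_bruteforce_dp(self, q, s):
        hits = local_align(q, s)
        got = hits[0].raw_score if hits else 0.0
        assert got == sw_oracle(q, s)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(q=nucseq, s=nucseq)
    def test_score_symmetry(self, q, s):
        h1 = local_align(q, s)
        h2 = local_align(s, q)
        s1 = h1[0].raw_score if h1 else 0.0
        s2 = h2[0].raw_score if h2 else 0.0
        assert s1 == s2

    def test_bit_score_monotone_in_raw(self):
        p = ScoringParams()
        assert p.bit_score(100) > p.bit_score(50) > p.bit_score(0)


class TestTagSimilarity:
    def _tag(self, seq, pos=0, label="REF"):
        return SequenceTag(seq, pos, label)

    def test_identical_tags(self):
        t = self._tag("ACGT" * 24)
        assert tag_similarity(t, t) == 1.0

    def test_ten_substitutions(self):
        a = "ACGT" * 24
        b = list(a)
        for i in range(10):
            b[i * 9] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i * 9]]
        sim = tag_similarity(self._tag(a), self._tag("".join(b)))
        assert sim == pytest.approx(86 / 96)

    def test_all_n_tag_scores_zero(self):
        a = self._tag("ACGT" * 24)
        n = self._tag("N" * 96)
        assert tag_similarity(a, n) == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(XorfeomeError):
            SequenceTag("ACGT", 0, "REF")


def _contig(cid, seq):
    return EstContig(cid, seq, 0, len(seq) - len(seq) % 3 or 3)


class TestBestClusterMatch:
    def _setup(self):
        rng = random.Random(11)
        base = "ATG" + "".join(rng.choice("ACGT") for _ in range(597))
        # Y: ~90% identical copy of base
        y = list(base)
        positions = rng.sample(range(60, 600), 60)
        for p in positions:
            y[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[y[p]]
        clone = CloneRecord("c1", base, 0, 600)
        return clone, base, "".join(y)

    def test_identical_contig_dominates(self):
        clone, base, y = self._setup()
        contigs = [_contig("X", base), _contig("Y", y)]
        assert best_cluster_match(clone, contigs, 95.0) == "X"

    def test_permutation_invariance(self):
        clone, base, y = self._setup()
        a = best_cluster_match(clone, [_contig("X", base), _contig("Y", y)], 80.0)
        b = best_cluster_match(clone, [_contig("Y", y), _contig("X", base)], 80.0)
        assert a == b

    def test_below_cutoff_absent(self):
        clone, base, y = self._setup()
        assert best_cluster_match(clone, [_contig("Y", y)], 95.0) is None
        # the caller's second pass at 80% then finds the alternate homeolog
        assert best_cluster_match(clone, [_contig("Y", y)], 80.0) == "Y"

    def test_five_prime_start_outranks_bit_score(self):
        # contig A aligns from clone position 0 but over a shorter stretch
        # (lower bit score); contig B aligns from position 10.  The more 5'
        # hit wins.
        rng = random.Random(5)
        core = "".join(rng.choice("ACGT") for _ in range(300))
        clone = CloneRecord("c1", "ATG" + core[3:300], 0, 300, canonical=True)
        contig_a = _contig("A", clone.cdna[:150])
        contig_b = _contig("B", clone.cdna[10:300])
        got = best_cluster_match(clone, [contig_a, contig_b], 95.0)
        assert got == "A"

    def test_empty_collection_absent(self):
        clone, _, _ = self._setup()
        assert best_cluster_match(clone, [], 95.0) is None


def test_contig_index_candidates_only_related():
    rng = random.Random(13)
    a = "".join(rng.choice("ACGT") for _ in range(400))
    b = "".join(rng.choice("ACGT") for _ in range(400))
    idx = ContigIndex({"A": a, "B": b}, k=12)
    assert idx.candidates(a) == ["A"]
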