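import random

import pytest
from hypothesis import given, settings, strategies as st

from xorfeome.coverage import (
    GeneRecord,
    diploid_equivalent_estimate,
    homeolog_pair_stats,
    two_pass_match,
)
from xorfeome.model import CloneRecord, EstContig, XorfeomeError


class TestDiploidEquivalentEstimate:
    def test_collection_scale_arithmetic(self):
        # curated 6946 ORFs covering 6507 loci; 1456 uncurated ORFs
        assert diploid_equivalent_estimate(6946, 6507, 1456) == (1364, 7871)

    def test_no_collapse(self):
        assert diploid_equivalent_estimate(100, 100, 50) == (50, 150)

    def test_all_paired_limit(self):
        assert diploid_equivalent_estimate(10, 5, 10) == (5, 10)

    def test_zero_curated_rejected(self):
        with pytest.raises(XorfeomeError):
            diploid_equivalent_estimate(0, 0, 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n_c=st.integers(1, 5000),
        g_c=st.integers(0, 5000),
        n_u=st.integers(0, 5000),
        k=st.integers(1, 7),
    )
    def test_homogeneous_in_counts(self, n_c, g_c, n_u, k):
        g_c = min(g_c, n_c)
        est1, _ = diploid_equivalent_estimate(n_c, g_c, n_u)
        estk, _ = diploid_equivalent_estimate(k * n_c, k * g_c, k * n_u)
        assert abs(estk - k * est1) <= k  # equal before rounding


class TestHomeologPairStats:
    def test_no_umbrella_groups(self):
        recs = [GeneRecord(f"o{i}", f"g{i}") for i in range(5)]
        s = homeolog_pair_stats(recs)
        assert s.n_pairs == 0
        assert s.n_genes_diploid_equiv == 5

    def test_pair_and_duplicate_distinguished(self):
        recs = [
            GeneRecord("o1", "g1", "u1", True),
            GeneRecord("o2", "g2", "u1", True),  # homeolog pair with g1
            GeneRecord("o3", "g3"),
            GeneRecord("o4", "g3"),  # duplicate ORF of g3, no umbrella
        ]
        s = homeolog_pair_stats(recs)
        assert s.n_pairs == 1
        assert s.n_extra_duplicates == 1
        assert s.n_genes_diploid_equiv == 2  # u1 group + g3

    def test_same_gene_twice_in_umbrella_not_a_pair(self):
        recs = [
            GeneRecord("o1", "g1", "u1", True),
            GeneRecord("o2", "g1", "u1", True),
        ]
        s = homeolog_pair_stats(recs)
        assert s.n_pairs == 0
        assert s.n_extra_duplicates == 1

    def test_collection_scale_fraction(self):
        # 531 pairs among 7871 diploid-equivalent genes -> 6.7%
        recs = []
        for i in range(531):
            recs.append(GeneRecord(f"oL{i}", f"gL{i}", f"u{i}", True))
            recs.append(GeneRecord(f"oS{i}", f"gS{i}", f"u{i}", True))
        for i in range(7871 - 531):
            recs.append(GeneRecord(f"o{i}", f"g{i}"))
        s = homeolog_pair_stats(recs)
        assert s.n_pairs == 531
        assert s.n_genes_diploid_equiv == 7871
        assert s.pct_paired == 6.7

    def test_pairs_bounded_by_half_genes(self):
        recs = [
            GeneRecord("o1", "g1", "u1", True),
            GeneRecord("o2", "g2", "u1", True),
            GeneRecord("o3", "g3", "u2", True),
            GeneRecord("o4", "g4", "u2", True),
        ]
        s = homeolog_pair_stats(recs)
        # every pair consumes at least two distinct raw gene ids
        n_raw_genes = len({r.gene_id for r in recs})
        assert s.n_pairs <= n_raw_genes // 2

    def test_umbrella_iff_curated_enforced(self):
        with pytest.raises(XorfeomeError):
            GeneRecord("o1", "g1", umbrella_id="u1", curated=False)


def _mutated_copy(seq, n_subs, seed):
    rng = random.Random(seed)
    s = list(seq)
    for p in rng.sample(range(30, len(seq) - 3), n_subs):
        s[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[p]]
    return "".join(s)


class TestTwoPassMatch:
    def _clone(self, seed=23, n=600):
        rng = random.Random(seed)
        seq = "ATG" + "".join(rng.choice("ACGT") for _ in range(n - 3))
        return CloneRecord("c1", seq, 0, n)

    def _contig(self, cid, seq):
        return EstContig(cid, seq, 0, len(seq) - len(seq) % 3 or 3)

    def test_high_identity_uses_primary(self):
        clone = self._clone()
        contig = self._contig("X", _mutated_copy(clone.cdna, 18, 1))  # ~97%
        assert two_pass_match(clone, [contig]) == ("X", "primary_95")

    def test_alternate_homeolog_uses_fallback(self):
        clone = self._clone()
        contig = self._contig("Y", _mutated_copy(clone.cdna, 72, 2))  # ~88%
        cid, pass_used = two_pass_match(clone, [contig])
        assert cid == "Y"
        assert pass_used == "fallback_80"

    def test_unrelated_sequence_matches_nothing(self):
        clone = self._clone(seed=23)
        other = self._clone(seed=99).cdna
        assert two_pass_match(clone, [self._contig("Z", other)]) == (None, "none")
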