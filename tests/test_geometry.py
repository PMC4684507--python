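import pytest
from hypothesis import given, settings, strategies as st

from xorfeome.geometry import (
    dedupe_best_per_species,
    hit_geometry,
    summarize_geometry,
)
from xorfeome.geometry import test_2p as mean_start_test
from xorfeome.geometry import test_3p as exact_count_test
from xorfeome.geometry import test_6n as utr_truncation_test
from xorfeome.model import ProteinHit, XorfeomeError


class TestHitGeometry:
    @pytest.mark.parametrize(
        "C,c_aa,P",
        [(0, 0, 0), (30, 10, 0), (15, 20, -45)],
    )
    def test_p_from_c_and_residue_offset(self, C, c_aa, P):
        h = hit_geometry("c1", "human", C, c_aa)
        assert h.c_nt == 3 * c_aa
        assert h.P == P

    def test_negative_inputs_rejected(self):
        with pytest.raises(XorfeomeError):
            hit_geometry("c1", "human", -1, 0)


class TestSummarize:
    def test_hand_arithmetic(self):
        hits = [hit_geometry("c", "human", 10, 0), hit_geometry("c", "mouse", 20, 0)]
        s = summarize_geometry(hits, A=15)
        assert s.P_bar == 15.0
        assert s.sigma_P == 5.0  # population standard deviation
        assert s.P_max == 20
        assert s.n_exact == 0

    def test_single_exact_hit(self):
        s = summarize_geometry([hit_geometry("c", "human", 30, 0)], A=30)
        assert s.n_exact == 1
        assert s.sigma_P == 0.0

    def test_no_hits_abstains(self):
        assert summarize_geometry([], A=10) is None

    def test_dedupe_keeps_first_per_species(self):
        hits = [
            hit_geometry("c", "human", 10, 0),
            hit_geometry("c", "human", 99, 0),
            hit_geometry("c", "mouse", 20, 0),
        ]
        kept = dedupe_best_per_species(hits)
        assert [(h.species, h.C) for h in kept] == [("human", 10), ("mouse", 20)]


class TestMeanStartTest:
    def test_exact_agreement(self):
        s = summarize_geometry([hit_geometry("c", "h", 100, 0)], A=100)
        assert mean_start_test(s, 100) == 1

    def test_twelve_bp_boundary(self):
        # P_bar = 100: within 12 bp of A=112 (inclusive), outside for A=113
        s = summarize_geometry([hit_geometry("c", "h", 100, 0)], A=112)
        assert mean_start_test(s, 112) == 1
        assert mean_start_test(s, 113) == 0

    def test_abstains_without_hits(self):
        assert mean_start_test(None, 100) == 0


class TestExactCountTest:
    @pytest.mark.parametrize("n_species_exact,expected", [(2, 1), (1, 0), (0, 0)])
    def test_requires_two_exact(self, n_species_exact, expected):
        species = ["human", "mouse", "chicken"]
        hits = [
            hit_geometry("c", species[i], 90 if i < n_species_exact else 300, 0)
            for i in range(3)
        ]
        s = summarize_geometry(hits, A=90)
        assert exact_count_test(s) == expected


class TestUtrTruncationTest:
    def test_pmax_branch(self):
        hits = [hit_geometry("c", "h", 5, 15)]  # C=5, P=-40
        s = summarize_geometry(hits, A=200)
        assert utr_truncation_test(s, 200) == 1

    def test_sigma_branch(self):
        # P_max = -12 (not < -15) but P_bar + sigma_P < -15
        hits = [
            hit_geometry("c", "h1", 0, 4),
            hit_geometry("c", "h2", 0, 10),
            hit_geometry("c", "h3", 0, 10),
        ]
        s = summarize_geometry(hits, A=200)
        assert s.P_max == -12
        assert s.P_bar + s.sigma_P < -15
        assert utr_truncation_test(s, 200) == 1

    def test_conservation_not_in_utr(self):
        hits = [hit_geometry("c", "h", 40, 30)]  # C_bar = 40
        s = summarize_geometry(hits, A=200)
        assert utr_truncation_test(s, 200) == 0

    def test_short_utr_effective_cutoff(self):
        # A=6: effective cutoff is ceil(6/2)=3, so C_bar=4 cannot fire
        hits = [hit_geometry("c", "h", 4, 20)]
        s = summarize_geometry(hits, A=6)
        assert utr_truncation_test(s, 6) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        cs=st.lists(st.integers(0, 300), min_size=1, max_size=6),
        caas=st.lists(st.integers(0, 100), min_size=6, max_size=6),
        A=st.integers(0, 300),
    )
    def test_never_fires_when_all_p_nonnegative(self, cs, caas, A):
        hits = []
        for i, C in enumerate(cs):
            c_aa = min(caas[i], C // 3)  # forces P = C - 3*c_aa >= 0
            hits.append(hit_geometry("c", f"sp{i}", C, c_aa))
        s = summarize_geometry(hits, A)
        assert all(h.P >= 0 for h in hits)
        assert utr_truncation_test(s, A) == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        params=st.lists(
            st.tuples(st.integers(0, 200), st.integers(0, 60)), min_size=1, max_size=6
        ),
        A=st.integers(0, 200),
        d=st.integers(0, 300),
    )
    def test_translation_invariance_under_5prime_padding(self, params, A, d):
        """Prepending d nt shifts A, C and P together; test outcomes are unchanged."""
        hits = [hit_geometry("c", f"sp{i}", C, c_aa) for i, (C, c_aa) in enumerate(params)]
        shifted = [hit_geometry("c", f"sp{i}", C + d, c_aa) for i, (C, c_aa) in enumerate(params)]
        s0 = summarize_geometry(hits, A)
        s1 = summarize_geometry(shifted, A + d)
        assert s1.P_bar == pytest.approx(s0.P_bar + d)
        assert s1.C_bar == pytest.approx(s0.C_bar + d)
        assert (mean_start_test(s0, A), exact_count_test(s0)) == (mean_start_test(s1, A + d), exact_count_test(s1))
        # the UTR-truncation test is anchored to the absolute 5' end (its
        # conservation-start cutoff does not shift), so padding can only
        # ever switch it off, never on
        assert utr_truncation_test(s1, A + d) <= utr_truncation_test(s0, A)
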