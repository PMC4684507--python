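import random

import pytest

from xorfeome.model import CloneRecord, EstContig, SequenceTag
from xorfeome.simulate import SimConfig, simulate_collection
from xorfeome.tags import (
    extract_atg_tags,
    match_reference_tag,
    reference_tag,
    relabel_tags,
    tag_tests,
)
from xorfeome.tags import test_1p as atg_word_test
from xorfeome.tags import test_5n as upstream_atg_test

BODY = "GAACCCGGTTCA"  # stop-free, ATG-free filler codons


def _orf(codons):
    return "".join(codons)


def _contig(seq, start, end, atg=(), cli=()):
    return EstContig("e1", seq, start, end, atg_score_positions=atg, cli_score_positions=cli)


def make_contig(n_codons=60, ladder=(), u5="C" * 30, atg=(), cli=()):
    """Codon-structured contig: ATG ladder only at requested codon indices."""
    rng = random.Random(17)
    body = ["GAA", "CCC", "GGT", "TCA", "CTT", "AGA"]
    codons = ["ATG"] + [
        "ATG" if i in ladder else body[rng.randrange(len(body))]
        for i in range(1, n_codons)
    ]
    seq = u5 + _orf(codons) + "TAA" + "C" * 30
    return _contig(seq, len(u5), len(u5) + 3 * n_codons, atg=atg, cli=cli)


class TestExtractTags:
    def test_successive_inframe_atgs(self):
        c = make_contig(ladder=(3,))
        tags = extract_atg_tags(c)
        assert [t.label for t in tags] == ["ATG1", "ATG2"]
        assert tags[0].origin_position == c.est_orf_start
        assert tags[1].origin_position == c.est_orf_start + 9

    def test_at_most_nine_tags(self):
        c = make_contig(n_codons=80, ladder=tuple(range(2, 26, 2)))  # 13 ATGs
        tags = extract_atg_tags(c)
        assert len(tags) == 9
        assert tags[-1].label == "ATG9"

    def test_out_of_frame_atg_not_tagged(self):
        # ATG at +1 relative to the frame must be ignored
        seq = "C" * 12 + "ATGCATGAACCCGGT" + "TAA" + "C" * 9
        c = _contig(seq, 12, 27)
        tags = extract_atg_tags(c)
        assert [t.origin_position for t in tags] == [12]

    def test_tag_past_contig_end_padded(self):
        c = make_contig(n_codons=20, u5="C" * 6)
        (tag,) = extract_atg_tags(c)
        assert tag.padded
        assert tag.sequence.endswith("N")

    def test_no_inframe_atg_empty(self):
        seq = "C" * 6 + "TTGAAACCC" + "TAA"
        c = _contig(seq, 6, 15)
        assert extract_atg_tags(c) == []


class TestRelabel:
    def test_blh_at_first_atg_becomes_orf(self):
        c = make_contig(atg=((30, 25),))
        tags = relabel_tags(extract_atg_tags(c), c)
        assert tags[0].label == "ORF"

    def test_blh_at_later_atg_becomes_cons(self):
        c = make_contig(ladder=(10,), atg=((60, 25),))
        tags = relabel_tags(extract_atg_tags(c), c)
        assert [t.label for t in tags] == ["ATG1", "CONS"]

    def test_scores_below_floor_ignored(self):
        c = make_contig(ladder=(10,), atg=((60, 8),))
        tags = relabel_tags(extract_atg_tags(c), c)
        assert [t.label for t in tags] == ["ATG1", "ATG2"]

    def test_orf_preferred_over_cli(self):
        # conservation at ATG1 and a transcription start 5 nt 3' of it
        c = make_contig(atg=((30, 25),), cli=((35, 30),))
        tags = relabel_tags(extract_atg_tags(c), c)
        assert tags[0].label == "ORF"

    def test_cli_within_window_relabels(self):
        c = make_contig(cli=((42, 30),))  # 12 nt 3' of ATG1 at 30: inside window
        tags = relabel_tags(extract_atg_tags(c), c)
        assert tags[0].label == "CLI"
        c2 = make_contig(cli=((43, 30),))  # 13 nt 3': outside
        tags2 = relabel_tags(extract_atg_tags(c2), c2)
        assert tags2[0].label == "ATG1"

    def test_idempotent(self):
        c = make_contig(ladder=(10,), atg=((60, 25),), cli=((0, 30),))
        once = relabel_tags(extract_atg_tags(c), c)
        twice = relabel_tags(once, c)
        assert once == twice


class TestMatchReferenceTag:
    def test_exact_match_returns_label(self):
        c = make_contig(atg=((30, 25),))
        tags = relabel_tags(extract_atg_tags(c), c)
        ref = SequenceTag(tags[0].sequence, 0, "REF")
        assert match_reference_tag(ref, tags) == "ORF"

    def test_eighty_percent_boundary(self):
        c = make_contig()
        (tag,) = extract_atg_tags(c)
        # 20 substitutions -> 76/96 = 0.79 similarity: below the cutoff
        seq = list(tag.sequence)
        for i in range(3, 63, 3):
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        ref = SequenceTag("".join(seq), 0, "REF")
        assert match_reference_tag(ref, [tag]) is None

    def test_best_match_wins(self):
        c = make_contig(ladder=(10, 20))
        tags = extract_atg_tags(c)
        ref = SequenceTag(tags[2].sequence, 0, "REF")
        assert match_reference_tag(ref, tags) == "ATG3"


class TestAtgWordTest:
    def test_matching_words(self):
        c = make_contig()
        clone = CloneRecord("c1", c.consensus, c.est_orf_start, c.est_orf_end)
        assert atg_word_test(clone, c) == 1

    def test_single_substitution_fails(self):
        c = make_contig()
        seq = list(c.consensus)
        seq[c.est_orf_start + 5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[c.est_orf_start + 5]]
        clone = CloneRecord("c1", "".join(seq), c.est_orf_start, c.est_orf_end)
        assert atg_word_test(clone, c) == 0

    def test_no_contig_scores_zero(self):
        c = make_contig()
        clone = CloneRecord("c1", c.consensus, c.est_orf_start, c.est_orf_end)
        assert atg_word_test(clone, None) == 0


class TestUpstreamAtgTest:
    def test_downstream_annotation_with_upstream_present(self):
        # clone ORF annotated at the second in-frame ATG; the true start is
        # upstream, physically present in the clone's nominal 5' UTR
        c = make_contig(ladder=(10,))
        clone = CloneRecord("c1", c.consensus, c.est_orf_start + 30, c.est_orf_end)
        assert upstream_atg_test(clone, c) == 1

    def test_same_start_negative(self):
        c = make_contig()
        clone = CloneRecord("c1", c.consensus, c.est_orf_start, c.est_orf_end)
        assert upstream_atg_test(clone, c) == 0

    def test_physically_truncated_cdna_abstains(self):
        # the upstream ATG is absent from the cDNA entirely: this test must
        # NOT fire (the whole-cDNA truncation geometry test handles it)
        c = make_contig(ladder=(10,))
        cut = c.est_orf_start + 6
        clone = CloneRecord(
            "c1", c.consensus[cut:], c.est_orf_start + 30 - cut, c.est_orf_end - cut
        )
        assert upstream_atg_test(clone, c) == 0


class TestTagTests:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("ORF", (1, 0)),
            ("CONS", (1, 0)),
            ("CLI", (1, 0)),
            ("ATG1", (1, 0)),
            ("ATG2", (0, 1)),
            ("ATG4", (0, 1)),
            ("ATG9", (0, 1)),
            (None, (0, 0)),
        ],
    )
    def test_label_partition(self, label, expected):
        assert tag_tests(label) == expected

    def test_mutual_exclusion(self):
        for label in ["ORF", "CONS", "CLI"] + [f"ATG{i}" for i in range(1, 10)]:
            p, n = tag_tests(label)
            assert p + n == 1


class TestGeneratorRoundTrip:
    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_downstream_truncation_matches_atgk(self, k):
        """A clone annotated at the k-th in-frame ATG with no conserving
        annotation must match tag ATGk and fire the negative tag test."""
        c = make_contig(n_codons=100, ladder=tuple(7 * j for j in range(1, k)),
                        atg=((30, 25),))
        clone = CloneRecord("c1", c.consensus, c.est_orf_start + 21 * (k - 1), c.est_orf_end)
        tags = relabel_tags(extract_atg_tags(c), c)
        label = match_reference_tag(reference_tag(clone), tags)
        assert label == f"ATG{k}"
        assert tag_tests(label) == (0, 1)


def test_pipeline_tags_recover_conserved_offsets(small_bundle):
    """Generator bookkeeping: conserved clones carry their lost-residue count."""
    lost = [t.lost_residues for t in small_bundle.truth.values() if t.mode == "conserved"]
    assert len(lost) == 5 and all(l >= 1 for l in lost)
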