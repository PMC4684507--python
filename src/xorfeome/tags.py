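"""Positional 96-bp sequence tags and the tag-based full-length tests.

Tags are 96-bp windows anchored at successive in-frame ATGs of an EST
contig's annotated ORF (labelled ATG1, ATG2, ... up to ATG9), then
relabelled from the contig's positional full-length annotations:

* a start-codon conservation (BLH/ATG) score at ATG1 relabels it ORF; at a
  later ATGn it relabels that tag CONS (a conserved, slightly internal
  start); scores below the floor (default 10) are ignored;
* a transcription-start (EST/CLI, "cliff") score upstream of, or within 12
  bp 3' of, ATG1 relabels ATG1 CLI — unless it is already ORF, which takes
  precedence.

The 96-bp tag taken at the clone's annotated start codon is then matched
against all contig tags (>= 80% similarity) and the matched label feeds the
classifier: ORF/CONS/CLI/ATG1 are full-length or conserved evidence, while
ATG2..ATG9 indicate a truncated ORF.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from . import align as _align
from .align import ScoringParams, alignment_position_map, tag_similarity
from .model import CloneRecord, EstContig, SequenceTag, XorfeomeError

__all__ = [
    "extract_atg_tags",
    "relabel_tags",
    "reference_tag",
    "match_reference_tag",
    "test_1p",
    "test_5n",
    "tag_tests",
]

TAG_LEN = 96
MAX_ATG_TAGS = 9
ATG_WORD_LEN = 12


def _window(seq: str, start: int, length: int = TAG_LEN) -> Tuple[str, bool]:
    """Sequence window, N-padded (and flagged) past the 3' end."""
    raw = seq[start : start + length]
    padded = len(raw) < length
    return raw + "N" * (length - len(raw)), padded


def extract_atg_tags(contig: EstContig) -> List[SequenceTag]:
    """One 96-bp tag per in-frame ATG of the contig ORF, 5'->3'.

    Only ATGs in the annotated reading frame, at or after the annotated
    start and before the ORF end, are tagged; anything beyond the ninth is
    ignored.  Returns an empty list when the ORF has no in-frame ATG.
    """
    out: List[SequenceTag] = []
    n = 0
    for pos in range(contig.est_orf_start, contig.est_orf_end, 3):
        if contig.consensus[pos : pos + 3] == "ATG":
            n += 1
            if n > MAX_ATG_TAGS:
                break
            seq, padded = _window(contig.consensus, pos)
            out.append(
                SequenceTag(sequence=seq, origin_position=pos, label=f"ATG{n}", padded=padded)
            )
    return out


def relabel_tags(
    tags: List[SequenceTag],
    contig: EstContig,
    score_floor: float = 10.0,
    cli_window: int = 12,
) -> List[SequenceTag]:
    """Relabel ATG tags from the contig's positional annotations.

    Deterministic and idempotent: a tag already relabelled ORF/CONS/CLI is
    never relabelled again.  The score floor applies to both annotation
    kinds.
    """
    atg_positions = {
        pos for pos, score in contig.atg_score_positions if score >= score_floor
    }
    cli_positions = [
        pos for pos, score in contig.cli_score_positions if score >= score_floor
    ]
    out: List[SequenceTag] = []
    for t in tags:
        label = t.label
        if label == "ATG1" and t.origin_position in atg_positions:
            label = "ORF"
        elif label.startswith("ATG") and label != "ATG1" and t.origin_position in atg_positions:
            label = "CONS"
        elif label == "ATG1" and any(
            p <= t.origin_position + cli_window for p in cli_positions
        ):
            # transcription start at/upstream of (or just 3' of) the first ATG;
            # ORF precedence is implicit: the ORF branch above ran first.
            label = "CLI"
        out.append(
            SequenceTag(
                sequence=t.sequence,
                origin_position=t.origin_position,
                label=label,
                padded=t.padded,
            )
        )
    return out


def reference_tag(clone: CloneRecord) -> SequenceTag:
    """96-bp tag at the clone's annotated start codon (label REF)."""
    seq, padded = _window(clone.cdna, clone.orf_start)
    return SequenceTag(
        sequence=seq, origin_position=clone.orf_start, label="REF", padded=padded
    )


def match_reference_tag(
    ref_tag: SequenceTag,
    est_tags: List[SequenceTag],
    min_similarity: float = 0.80,
    params: Optional[ScoringParams] = None,
) -> Optional[str]:
    """Label of the best-matching contig tag at >= ``min_similarity``.

    Ties are broken toward the more 5' tag; None when nothing qualifies.
    """
    params = params or _align.DEFAULT_PARAMS
    best: Optional[Tuple[float, int, str]] = None
    for t in est_tags:
        sim = tag_similarity(ref_tag, t, params)
        if sim < min_similarity:
            continue
        key = (-sim, t.origin_position)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], t.label)
    return best[2] if best else None


def _atg_word(seq: str, start: int) -> Optional[str]:
    w = seq[start : start + ATG_WORD_LEN]
    if len(w) < ATG_WORD_LEN or "N" in w:
        return None
    return w


def test_1p(clone: CloneRecord, contig: Optional[EstContig]) -> int:
    """1 iff the 12-base ATG words at the two annotated starts match exactly."""
    if contig is None:
        return 0
    a = _atg_word(clone.cdna, clone.orf_start)
    b = _atg_word(contig.consensus, contig.est_orf_start)
    return int(a is not None and a == b)


def test_5n(
    clone: CloneRecord,
    contig: Optional[EstContig],
    params: Optional[ScoringParams] = None,
) -> int:
    """1 iff the clone's start matches a downstream in-frame ATG of the EST ORF.

    All of the following must hold under the clone<->contig alignment:
    the ATG words differ; the contig's start codon maps upstream of the
    clone's annotated start; the clone's start maps onto a downstream
    in-frame ATG of the contig ORF; and an in-frame ATG in the clone's 5'
    UTR aligns to the contig's start codon.  A cDNA physically lacking the
    upstream sequence cannot satisfy the last condition (that situation is
    the whole-cDNA-truncation geometry test's job).
    """
    if contig is None:
        return 0
    if test_1p(clone, contig):
        return 0  # ATG words agree: starts coincide
    params = params or _align.DEFAULT_PARAMS
    pmap = alignment_position_map(clone.cdna, contig.consensus, params)
    if pmap is None:
        return 0
    # (b) contig start codon maps upstream of the clone's annotated start
    est_start_on_clone = pmap.subject_to_query(contig.est_orf_start)
    if est_start_on_clone is None or est_start_on_clone >= clone.orf_start:
        return 0
    # (c) clone start maps onto a downstream in-frame ATG of the contig ORF
    clone_start_on_contig = pmap.query_to_subject(clone.orf_start)
    if clone_start_on_contig is None:
        return 0
    if not (
        clone_start_on_contig > contig.est_orf_start
        and (clone_start_on_contig - contig.est_orf_start) % 3 == 0
        and contig.consensus[clone_start_on_contig : clone_start_on_contig + 3] == "ATG"
    ):
        return 0
    # (d) an in-frame ATG in the clone's 5' UTR aligns to the contig start
    for p in range(clone.orf_start % 3, clone.orf_start, 3):
        if (clone.orf_start - p) % 3 == 0 and clone.cdna[p : p + 3] == "ATG":
            if pmap.query_to_subject(p) == contig.est_orf_start:
                return 1
    return 0


def tag_tests(matched_label: Optional[str]) -> Tuple[int, int]:
    """Positive / negative tag-test scores from the matched tag label.

    Returns ``(score_4p, score_7n)``: the positive test fires on
    ORF/CONS/CLI/ATG1, the negative on ATG2..ATG9; both are 0 when no tag
    matched.  The two are mutually exclusive by label partition.
    """
    if matched_label is None:
        return 0, 0
    if matched_label in ("ORF", "CONS", "CLI", "ATG1"):
        return 1, 0
    if matched_label.startswith("ATG"):
        return 0, 1
    return 0, 0
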