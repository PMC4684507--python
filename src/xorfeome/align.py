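"""Pairwise local alignment and identity computation.

This module is the package's self-contained stand-in for the BLASTn /
BLASTx steps of the original clone-verification workflow: an affine-gap
Smith-Waterman (via Bio.Align.PairwiseAligner) over an A/C/G/T/N alphabet,
with a k-mer seed prefilter for database-style searches and a
Karlin-Altschul transform to BLAST-like bit scores.  Scoring defaults are
BLASTN-like (match +2, mismatch -3, gap of length L costs 5 + 2L) and all
thresholds are configurable.

N is treated as a hard wildcard-mismatch: it scores as a mismatch against
everything (including N) and never counts toward identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import CloneRecord, EstContig, SequenceTag, XorfeomeError, normalize_seq

__all__ = [
    "ScoringParams",
    "AlignmentHit",
    "PositionMap",
    "local_align",
    "aa_local_align",
    "tag_similarity",
    "best_cluster_match",
    "seed_candidates",
    "ContigIndex",
]

_NUC_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class ScoringParams:
    """Affine-gap nucleotide scoring.

    A gap of length L scores ``gap_open + L * gap_extend`` (both are
    negative numbers, BLAST cost convention).  ``lambda_k`` are the
    Karlin-Altschul parameters used to convert raw scores to bit scores,
    ``bits = (lambda * S - ln K) / ln 2``.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    lambda_k: Tuple[float, float] = (0.625, 0.41)

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise XorfeomeError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise XorfeomeError("mismatch and gap penalties must be <= 0")
        lam, k = self.lambda_k
        if lam <= 0 or k <= 0:
            raise XorfeomeError("Karlin-Altschul lambda and K must be positive")

    def bit_score(self, raw_score: float) -> float:
        lam, k = self.lambda_k
        return (lam * raw_score - math.log(k)) / math.log(2.0)


DEFAULT_PARAMS = ScoringParams()


@dataclass(frozen=True)
class AlignmentHit:
    """One maximal-scoring local alignment between a query and a subject."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    identity_pct: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_columns: int = 0
    n_matches: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise XorfeomeError("identity_pct outside [0, 100]")
        if self.q_start >= self.q_end:
            raise XorfeomeError("empty query interval in alignment hit")


class PositionMap:
    """Bidirectional query<->subject coordinate map from aligned blocks."""

    def __init__(self, q_blocks: Sequence[Tuple[int, int]], s_blocks: Sequence[Tuple[int, int]]):
        self._q2s: Dict[int, int] = {}
        self._s2q: Dict[int, int] = {}
        for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
            for off in range(qe - qs):
                self._q2s[qs + off] = ss + off
                self._s2q[ss + off] = qs + off

    def query_to_subject(self, pos: int) -> Optional[int]:
        return self._q2s.get(pos)

    def subject_to_query(self, pos: int) -> Optional[int]:
        return self._s2q.get(pos)


def _make_nuc_matrix(params: ScoringParams) -> substitution_matrices.Array:
    m = substitution_matrices.Array(_NUC_ALPHABET, dims=2)
    for a in _NUC_ALPHABET:
        for b in _NUC_ALPHABET:
            if a == b and a != "N":
                m[a, b] = params.match
            else:
                m[a, b] = params.mismatch
    return m


def _make_aligner(params: ScoringParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _make_nuc_matrix(params)
    # biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one; our convention charges
    # gap_open once plus gap_extend per position.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _blocks(alignment) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int]]]:
    aligned = alignment.aligned
    q_blocks = [(int(a), int(b)) for a, b in aligned[0]]
    s_blocks = [(int(a), int(b)) for a, b in aligned[1]]
    return q_blocks, s_blocks


def _hit_from_alignment(
    alignment, query: str, subject: str, query_id: str, subject_id: str, params: ScoringParams
) -> Optional[AlignmentHit]:
    q_blocks, s_blocks = _blocks(alignment)
    if not q_blocks:
        return None
    n_matches = 0
    n_block_cols = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        n_block_cols += qe - qs
        for off in range(qe - qs):
            a, b = query[qs + off], subject[ss + off]
            if a == b and a != "N":
                n_matches += 1
    # gap columns between consecutive blocks
    n_gap_cols = 0
    for i in range(1, len(q_blocks)):
        n_gap_cols += q_blocks[i][0] - q_blocks[i - 1][1]
        n_gap_cols += s_blocks[i][0] - s_blocks[i - 1][1]
    n_columns = n_block_cols + n_gap_cols
    raw = float(alignment.score)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=raw,
        bit_score=params.bit_score(raw),
        identity_pct=100.0 * n_matches / n_columns if n_columns else 0.0,
        q_start=q_blocks[0][0],
        q_end=q_blocks[-1][1],
        s_start=s_blocks[0][0],
        s_end=s_blocks[-1][1],
        n_columns=n_columns,
        n_matches=n_matches,
    )


def local_align(
    query: str,
    subject: str,
    params: ScoringParams = DEFAULT_PARAMS,
    query_id: str = "query",
    subject_id: str = "subject",
) -> List[AlignmentHit]:
    """Best local alignment(s) of two nucleotide sequences, best-first.

    Returns the maximal-scoring local alignment under affine-gap scoring
    (one hit; co-optimal tracebacks are resolved deterministically).  An
    empty list is returned when the optimal local score is not positive,
    i.e. the sequences share no aligning segment at all.
    """
    query = normalize_seq(query)
    subject = normalize_seq(subject)
    if not query or not subject:
        raise XorfeomeError("cannot align empty sequences")
    aligner = _make_aligner(params, "local")
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return []
    hit = _hit_from_alignment(alignments[0], query, subject, query_id, subject_id, params)
    return [hit] if hit is not None else []


def alignment_position_map(
    query: str, subject: str, params: ScoringParams = DEFAULT_PARAMS
) -> Optional[PositionMap]:
    """Coordinate map between two sequences from their best local alignment."""
    query = normalize_seq(query)
    subject = normalize_seq(subject)
    aligner = _make_aligner(params, "local")
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return None
    q_blocks, s_blocks = _blocks(alignments[0])
    if not q_blocks:
        return None
    return PositionMap(q_blocks, s_blocks)


def aa_local_align(
    query_aa: str,
    subject_aa: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
):
    """Best local amino-acid alignment (BLOSUM62 by default).

    Returns ``(raw_score, q_start, s_start)`` of the best local alignment,
    or ``None`` when nothing aligns.  Used to derive translated-alignment
    geometry (conservation start on the cDNA frame vs on the protein).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    alignments = aligner.align(query_aa, subject_aa)
    if alignments.score <= 0:
        return None
    q_blocks, s_blocks = _blocks(alignments[0])
    if not q_blocks:
        return None
    return float(alignments.score), q_blocks[0][0], s_blocks[0][0]


def tag_similarity(
    a: SequenceTag, b: SequenceTag, params: ScoringParams = DEFAULT_PARAMS
) -> float:
    """Identity fraction of a global end-to-end alignment of two 96-bp tags.

    The identity is always computed over the 96 tag columns, so gapped
    alignments cannot inflate it; N columns never count as matches.
    """
    if len(a.sequence) != 96 or len(b.sequence) != 96:
        raise XorfeomeError("tag similarity requires two 96-bp tags")
    sa, sb = a.sequence, b.sequence
    # ungapped identity; a gapped global alignment can only beat this when
    # the shift gain exceeds the gap costs, so check both.
    ungapped = sum(1 for x, y in zip(sa, sb) if x == y and x != "N")
    aligner = _make_aligner(params, "global")
    alignment = aligner.align(sa, sb)[0]
    q_blocks, s_blocks = _blocks(alignment)
    gapped = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        for off in range(qe - qs):
            if sa[qs + off] == sb[ss + off] and sa[qs + off] != "N":
                gapped += 1
    return max(ungapped, gapped) / 96.0


class ContigIndex:
    """k-mer word index over a subject collection (BLAST-database stand-in).

    Built once per collection; ``candidates(query)`` returns the ids of
    subjects sharing at least one exact k-mer word with the query.
    N-containing words are skipped.
    """

    def __init__(self, subjects: Mapping[str, str], k: int = 12):
        self.k = k
        self.subjects = {sid: normalize_seq(s) for sid, s in subjects.items()}
        self._index: Dict[str, set] = {}
        for sid, s in self.subjects.items():
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if "N" not in w:
                    self._index.setdefault(w, set()).add(sid)

    def candidates(self, query: str) -> List[str]:
        query = normalize_seq(query)
        k = self.k
        hit: set = set()
        for i in range(len(query) - k + 1):
            ids = self._index.get(query[i : i + k])
            if ids:
                hit |= ids
        return sorted(hit)


def seed_candidates(
    query: str,
    subjects: Mapping[str, str],
    k: int = 12,
    min_shared: int = 1,
) -> List[str]:
    """Subject ids sharing at least ``min_shared`` exact k-mers with the query.

    One-shot convenience wrapper over :class:`ContigIndex`.
    """
    index = ContigIndex(subjects, k=k)
    if min_shared <= 1:
        return index.candidates(query)
    query_n = normalize_seq(query)
    out = []
    for sid in index.candidates(query_n):
        s = index.subjects[sid]
        words = {
            query_n[i : i + k]
            for i in range(len(query_n) - k + 1)
            if "N" not in query_n[i : i + k]
        }
        shared = sum(1 for i in range(len(s) - k + 1) if s[i : i + k] in words)
        if shared >= min_shared:
            out.append(sid)
    return out


def best_cluster_match(
    clone: CloneRecord,
    contigs: Iterable[EstContig],
    identity_cutoff: float,
    params: ScoringParams = DEFAULT_PARAMS,
    bit_floor: float = 50.0,
    seed_k: int = 12,
    index: Optional["ContigIndex"] = None,
) -> Optional[str]:
    """Best-matching EST cluster for a clone cDNA at an identity cutoff.

    Among per-contig best hits with ``identity_pct >= identity_cutoff``
    (and bit score above ``bit_floor``, screening out short spurious local
    hits), the winner is the hit starting most 5' on the clone cDNA,
    tie-broken by descending bit score and then by contig id.  Returns the
    contig id, or None when no hit qualifies.
    """
    if not (0.0 < identity_cutoff <= 100.0):
        raise XorfeomeError("identity cutoff must be in (0, 100]")
    contigs = list(contigs)
    by_id = {c.contig_id: c.consensus for c in contigs}
    if len(by_id) != len(contigs):
        raise XorfeomeError("duplicate contig ids in collection")
    if index is None:
        index = ContigIndex(by_id, k=seed_k)
    candidates = [c for c in index.candidates(clone.cdna) if c in by_id]
    ranked = []
    for cid in candidates:
        hits = local_align(
            clone.cdna, by_id[cid], params, query_id=clone.clone_id, subject_id=cid
        )
        if not hits:
            continue
        hit = hits[0]
        if hit.identity_pct >= identity_cutoff and hit.bit_score >= bit_floor:
            ranked.append((hit.q_start, -hit.bit_score, cid))
    if not ranked:
        return None
    ranked.sort()
    return ranked[0][2]
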