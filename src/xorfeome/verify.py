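"""EST-based verification of Gateway cloning success, and consolidation.

Each Gateway PCR product is end-sequenced to give 5' and 3' reads; a clone
passes when at least one read aligns to its own reference ORF with a bit
score at or above the threshold (default 50 bits).  Passing clones are
consolidated into 96-well distribution plates, and collection-level
summary statistics (pass rate, median ORF lengths) are reported.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .align import DEFAULT_PARAMS, AlignmentHit, ScoringParams, local_align
from .classify import round_half_up
from .model import CloneRecord, FullLengthClass, PlateMapRow, XorfeomeError

__all__ = [
    "EstRead",
    "VerifyResult",
    "verify_clone",
    "consolidate",
    "collection_summary",
    "CollectionSummary",
    "percentage",
]

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12


@dataclass(frozen=True)
class EstRead:
    """A single-pass end read from one clone's PCR product."""

    clone_id: str
    end: str  # "five_prime" | "three_prime"
    sequence: str

    def __post_init__(self) -> None:
        if self.end not in ("five_prime", "three_prime"):
            raise XorfeomeError(f"read end must be five_prime/three_prime, got {self.end!r}")
        if not self.sequence:
            raise XorfeomeError(f"read for clone {self.clone_id} has empty sequence")


@dataclass(frozen=True)
class VerifyResult:
    passed: bool
    best_hit: Optional[AlignmentHit]
    reason: str = ""


def verify_clone(
    reads: Sequence[EstRead],
    reference_orfs: Sequence[str],
    threshold: float = 50.0,
    params: ScoringParams = DEFAULT_PARAMS,
) -> VerifyResult:
    """Pass iff any read hits any of the clone's reference ORF sequences.

    ``reference_orfs`` normally holds the clone's own reference ORF (one
    sequence); the best hit over all reads is recorded for audit either
    way.  Zero reads fail with reason ``no_reads``.  Lowering the
    threshold can only turn failures into passes (monotonicity).
    """
    if threshold <= 0:
        raise XorfeomeError("bit-score threshold must be positive")
    if not reads:
        return VerifyResult(passed=False, best_hit=None, reason="no_reads")
    best: Optional[AlignmentHit] = None
    for read in reads:
        for i, ref in enumerate(reference_orfs):
            hits = local_align(
                read.sequence, ref, params,
                query_id=f"{read.clone_id}.{read.end}", subject_id=f"ref{i}",
            )
            if hits and (best is None or hits[0].bit_score > best.bit_score):
                best = hits[0]
    passed = best is not None and best.bit_score >= threshold
    return VerifyResult(passed=passed, best_hit=best, reason="" if passed else "below_threshold")


def _well_name(index: int) -> Tuple[int, str]:
    """Plate number (1-based) and well label for the i-th clone, row-major A01..H12."""
    per_plate = len(PLATE_ROWS) * PLATE_COLS
    plate = index // per_plate + 1
    within = index % per_plate
    row = PLATE_ROWS[within // PLATE_COLS]
    col = within % PLATE_COLS + 1
    return plate, f"{row}{col:02d}"


def consolidate(
    clones: Sequence[CloneRecord],
    verdicts: Mapping[str, bool],
    classes: Mapping[str, FullLengthClass],
    gene_symbols: Optional[Mapping[str, str]] = None,
    umbrella_ids: Optional[Mapping[str, str]] = None,
    primers: Optional[Mapping[str, Tuple[str, str]]] = None,
) -> List[PlateMapRow]:
    """Re-array passing clones into 96-well plates, preserving input order.

    Wells are filled row-major (A01..A12, B01..) plate by plate.  Only
    clones whose verdict is a pass appear; every clone must have a verdict.
    """
    missing = [c.clone_id for c in clones if c.clone_id not in verdicts]
    if missing:
        raise XorfeomeError(f"verdicts missing for clones: {missing[:5]}")
    rows: List[PlateMapRow] = []
    for clone in clones:
        if not verdicts[clone.clone_id]:
            continue
        plate, well = _well_name(len(rows))
        fwd, rev = (primers or {}).get(clone.clone_id, ("", ""))
        rows.append(
            PlateMapRow(
                clone_id=clone.clone_id,
                plate=plate,
                well=well,
                full_length_status=classes.get(clone.clone_id, FullLengthClass.UNKNOWN),
                gene_symbol=(gene_symbols or {}).get(clone.clone_id, ""),
                umbrella_gene_id=(umbrella_ids or {}).get(clone.clone_id),
                forward_primer=fwd,
                reverse_primer=rev,
                verified=True,
            )
        )
    return rows


def percentage(numerator: int, denominator: int) -> int:
    """Integer percentage, half-up (the convention for whole-collection rates)."""
    if denominator == 0:
        return 0
    return int(round_half_up(100.0 * numerator / denominator))


@dataclass(frozen=True)
class CollectionSummary:
    n_attempted: int
    n_passed: int
    pct_passed: int
    median_orf_len_passed: float
    median_orf_len_all: float


def collection_summary(
    clones: Sequence[CloneRecord], verdicts: Mapping[str, bool]
) -> CollectionSummary:
    """Attempted/passed counts, pass rate and median ORF lengths (nt)."""
    if not clones:
        return CollectionSummary(0, 0, 0, 0.0, 0.0)
    passed = [c for c in clones if verdicts.get(c.clone_id, False)]
    return CollectionSummary(
        n_attempted=len(clones),
        n_passed=len(passed),
        pct_passed=percentage(len(passed), len(clones)),
        median_orf_len_passed=float(statistics.median([c.orf_len for c in passed])) if passed else 0.0,
        median_orf_len_all=float(statistics.median([c.orf_len for c in clones])),
    )
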