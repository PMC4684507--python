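"""Rule-based five-way classification of full-length status.

With p = number of positive tests passed and n = number of negative tests
fired, a clone is:

* ``conserved`` when the positive tag test passed with matched label CONS
  (a conserved N-terminus at a slightly internal start codon) — checked
  first, so it overrides any negative indications;
* ``good``     when p > 0 and n == 0;
* ``mixed``    when p > 0 and n > 0;
* ``bad``      when p == 0 and n > 0;
* ``unknown``  when p == 0 and n == 0.

The five predicates partition the scorecard space, so classification is
total and single-valued.
"""

from __future__ import annotations

from collections import Counter
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import FullLengthClass, TestScorecard, XorfeomeError

__all__ = [
    "classify",
    "summarize_classes",
    "lost_residue_distribution",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention used for all reported percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify(card: TestScorecard) -> FullLengthClass:
    """Map a complete seven-test scorecard to a full-length status."""
    p = card.n_positive
    n = card.n_negative
    if card.scores["4.p"] == 1 and card.matched_tag_label == "CONS":
        return FullLengthClass.CONSERVED
    if p > 0 and n == 0:
        return FullLengthClass.GOOD
    if p > 0 and n > 0:
        return FullLengthClass.MIXED
    if p == 0 and n > 0:
        return FullLengthClass.BAD
    return FullLengthClass.UNKNOWN


def summarize_classes(
    classes: Iterable[FullLengthClass],
) -> Dict[str, Dict[str, float]]:
    """Counts and percentages per class, plus the combined good+conserved group.

    Percentages are of the total, rounded half-up to one decimal.  Returns
    ``{status: {"count": int, "pct": float}, ..., "good_or_conserved": ...}``.
    """
    classes = list(classes)
    total = len(classes)
    counts = Counter(classes)
    out: Dict[str, Dict[str, float]] = {}
    for cls in FullLengthClass:
        c = counts.get(cls, 0)
        pct = round_half_up(100.0 * c / total, 1) if total else 0.0
        out[cls.value] = {"count": c, "pct": pct}
    combined = counts.get(FullLengthClass.GOOD, 0) + counts.get(
        FullLengthClass.CONSERVED, 0
    )
    out["good_or_conserved"] = {
        "count": combined,
        "pct": round_half_up(100.0 * combined / total, 1) if total else 0.0,
    }
    out["total"] = {"count": total, "pct": 100.0 if total else 0.0}
    return out


def lost_residue_distribution(
    offsets_nt: Sequence[int],
) -> Tuple[Counter, float]:
    """Histogram of N-terminal residues lost by conserved-start clones.

    ``offsets_nt`` are per-clone nucleotide distances between the
    EST-defined start and the annotated (internal) start; residues lost is
    the offset divided by 3 (floor division, non-multiples are still
    counted).  Returns ``(histogram, fraction with <= 10 residues lost)``.
    """
    hist: Counter = Counter()
    for off in offsets_nt:
        if off < 0:
            raise XorfeomeError(f"negative start offset {off}")
        hist[off // 3] += 1
    total = sum(hist.values())
    frac = sum(v for k, v in hist.items() if k <= 10) / total if total else 0.0
    return hist, frac
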