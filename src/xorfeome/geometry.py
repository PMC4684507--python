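"""Translated-alignment geometry and the start-position tests.

For each clone, translated alignments to proteins from non-Xenopus species
give, on a zero-based nucleotide scale along the cDNA: the annotated start
codon position A, the conservation start C (>= 0), and the predicted start
position P = C - 3*c_aa where c_aa is the 0-based residue at which
conservation begins on the foreign protein.  P < 0 means the conserved
protein extends 5' of the cDNA itself.  Averages over hits drive three of
the seven full-length tests:

* positive: the mean predicted start lies within 12 bp of A; or at least
  two independent species predict P == A exactly;
* negative: conservation reaches into the 5' UTR (C_bar below an effective
  cutoff) while the protein is typically longer than the cDNA allows
  (P_max < -15, or P_bar + sigma_P < -15), indicating the whole cDNA is
  5'-truncated.
"""

from __future__ import annotations

import math
import statistics
from typing import Iterable, List, Optional, Sequence

from .model import GeometrySummary, ProteinHit, XorfeomeError

__all__ = [
    "hit_geometry",
    "dedupe_best_per_species",
    "summarize_geometry",
    "test_2p",
    "test_3p",
    "test_6n",
]


def hit_geometry(clone_id: str, species: str, C: int, c_aa: int) -> ProteinHit:
    """Build a ProteinHit from a cDNA offset and a protein residue offset.

    ``C`` is in nucleotides on the cDNA; ``c_aa`` is the 0-based amino-acid
    offset of the conservation start on the foreign protein, converted here
    to nucleotide equivalents (3 per residue).
    """
    if C < 0 or c_aa < 0:
        raise XorfeomeError(f"hit {clone_id}/{species}: negative offsets")
    return ProteinHit(clone_id=clone_id, species=species, C=C, c_nt=3 * c_aa)


def dedupe_best_per_species(hits: Iterable[ProteinHit]) -> List[ProteinHit]:
    """Keep one hit per species (first in input order, inputs best-first)."""
    seen = set()
    out = []
    for h in hits:
        if h.species not in seen:
            seen.add(h.species)
            out.append(h)
    return out


def summarize_geometry(hits: Sequence[ProteinHit], A: int) -> Optional[GeometrySummary]:
    """Mean/spread of P and C over hits; None (abstain) when there are no hits.

    ``sigma_P`` is the population standard deviation (0 for a single hit);
    ``n_exact`` counts hits whose predicted start P equals the annotated
    start A exactly.
    """
    hits = dedupe_best_per_species(hits)
    if not hits:
        return None
    Ps = [h.P for h in hits]
    Cs = [h.C for h in hits]
    return GeometrySummary(
        P_bar=statistics.fmean(Ps),
        C_bar=statistics.fmean(Cs),
        sigma_P=statistics.pstdev(Ps),
        P_max=max(Ps),
        n_exact=sum(1 for p in Ps if p == A),
        n_hits=len(hits),
    )


def test_2p(summary: Optional[GeometrySummary], A: int, window: float = 12.0) -> int:
    """1 iff the mean predicted start position is within ``window`` bp of A."""
    if summary is None:
        return 0
    return int(abs(summary.P_bar - A) <= window)


def test_3p(summary: Optional[GeometrySummary], min_exact: int = 2) -> int:
    """1 iff at least ``min_exact`` separate species predict P == A exactly."""
    if summary is None:
        return 0
    return int(summary.n_exact >= min_exact)


def test_6n(
    summary: Optional[GeometrySummary],
    A: int,
    c_cutoff: float = 15.0,
    p_cutoff: float = -15.0,
) -> int:
    """1 iff conservation reaches the 5' UTR and the protein is typically longer.

    Fires when C_bar < min(c_cutoff, ceil(A/2)) — the second term keeps a
    clone whose entire 5' UTR is shorter than the cutoff from trivially
    qualifying — and either P_max < p_cutoff or P_bar + sigma_P < p_cutoff.
    Indicates 5' truncation of the whole cDNA (ORF plus UTR).
    """
    if summary is None:
        return 0
    effective = min(c_cutoff, math.ceil(A / 2))
    if summary.C_bar >= effective:
        return 0
    return int(
        summary.P_max < p_cutoff or (summary.P_bar + summary.sigma_P) < p_cutoff
    )
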