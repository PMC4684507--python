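"""Gateway attB-tailed, ORF-specific primer design.

The forward primer core starts at the first base of the start codon; the
reverse core is the reverse complement of an ORF suffix ending at the last
base before the stop codon, so the amplified insert is exactly the ORF
with no stop codon and no UTR.  Cores are extended with the attB1/attB2
recombination adapters; core lengths are chosen within a window to bring
the melting temperature closest to a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from Bio.SeqUtils import MeltingTemp

from .model import CloneRecord, XorfeomeError, orf_sequence, revcomp

__all__ = ["PrimerPair", "design_primers", "simulate_pcr", "ATTB1_TAIL", "ATTB2_TAIL"]

# Canonical Gateway attB adapter sequences (data, not code: substitute
# lab-specific tails via the design_primers arguments).
ATTB1_TAIL = "GGGGACAAGTTTGTACAAAAAAGCAGGCT"
ATTB2_TAIL = "GGGGACCACTTTGTACAAGAAAGCTGGGT"


@dataclass(frozen=True)
class PrimerPair:
    forward_core: str
    reverse_core: str
    forward_full: str
    reverse_full: str
    tm_forward: float
    tm_reverse: float
    warnings: Tuple[str, ...] = ()


def _tm(seq: str, method: str = "nn") -> float:
    """Melting temperature of a primer core (nearest-neighbour or Wallace)."""
    if method == "wallace" or "N" in seq:
        # Wallace rule; ambiguous N weighted like A/T
        at = sum(seq.count(b) for b in "ATN")
        gc = sum(seq.count(b) for b in "GC")
        return float(2 * at + 4 * gc)
    if method != "nn":
        raise XorfeomeError(f"unknown Tm method {method!r}")
    return float(MeltingTemp.Tm_NN(seq))


def _pick_core(candidates: List[str], target_tm: float, method: str) -> Tuple[str, float]:
    best = None
    for core in candidates:  # ascending length; ties go to the shorter core
        tm = _tm(core, method)
        key = (abs(tm - target_tm), len(core))
        if best is None or key < best[0]:
            best = (key, core, tm)
    return best[1], best[2]


def design_primers(
    clone: CloneRecord,
    min_len: int = 18,
    max_len: int = 30,
    target_tm: float = 60.0,
    tm_method: str = "nn",
    attb1_tail: str = ATTB1_TAIL,
    attb2_tail: str = ATTB2_TAIL,
) -> PrimerPair:
    """Design the attB-tailed primer pair for one clone's ORF.

    Deterministic: for fixed inputs the same pair is always returned.
    Ambiguous bases inside a chosen core are recorded as warnings, not
    errors.  Raises when the ORF is shorter than twice the minimum core
    length (the two cores may not overlap meaningfully).
    """
    orf = orf_sequence(clone)
    if len(orf) < 2 * min_len:
        raise XorfeomeError(
            f"clone {clone.clone_id}: ORF of {len(orf)} nt too short for "
            f"primer cores of >= {min_len} nt"
        )
    max_len = min(max_len, len(orf) // 2)
    lengths = range(min_len, max_len + 1)
    fwd_core, tm_f = _pick_core([orf[:L] for L in lengths], target_tm, tm_method)
    rev_core, tm_r = _pick_core([revcomp(orf[-L:]) for L in lengths], target_tm, tm_method)
    warnings = []
    if "N" in fwd_core:
        warnings.append("ambiguous base in forward core")
    if "N" in rev_core:
        warnings.append("ambiguous base in reverse core")
    return PrimerPair(
        forward_core=fwd_core,
        reverse_core=rev_core,
        forward_full=attb1_tail + fwd_core,
        reverse_full=attb2_tail + rev_core,
        tm_forward=tm_f,
        tm_reverse=tm_r,
        warnings=tuple(warnings),
    )


def simulate_pcr(template: str, pair: PrimerPair) -> Optional[str]:
    """Exact-match priming on a template; returns the amplified insert.

    The insert is the template segment from the forward core's 5' end to
    the 3' end of the (reverse-complemented) reverse core — for a correct
    design on the source cDNA this is exactly the ORF, stop codon and UTRs
    excluded.  None when either core fails to prime.
    """
    fpos = template.find(pair.forward_core)
    rsite = revcomp(pair.reverse_core)
    rpos = template.rfind(rsite)
    if fpos < 0 or rpos < 0 or rpos + len(rsite) <= fpos:
        return None
    return template[fpos : rpos + len(rsite)]
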