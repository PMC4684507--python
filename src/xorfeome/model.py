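"""Domain types shared by every pipeline stage.

Coordinate conventions
----------------------
All sequence coordinates are 0-based, half-open nucleotide offsets on the
clone cDNA or EST contig consensus, running 5'->3'.  For an annotated open
reading frame, ``orf_start`` is the first base of the start codon and
``orf_end`` is the base *after* the last codon preceding the stop codon, so
the stop codon occupies ``[orf_end, orf_end + 3)`` and is never part of the
ORF sequence.  Protein-alignment geometry stores the conservation start on
the protein pre-converted to nucleotide equivalents (3 x the 0-based
amino-acid offset), so the predicted start-codon position ``P = C - c_nt``
is unit-consistent and may be negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "XorfeomeError",
    "CoordinateError",
    "FullLengthClass",
    "CloneRecord",
    "EstContig",
    "ProteinHit",
    "GeometrySummary",
    "SequenceTag",
    "TestScorecard",
    "PlateMapRow",
    "TEST_IDS",
    "POSITIVE_TESTS",
    "NEGATIVE_TESTS",
    "TAG_LABELS",
    "normalize_seq",
    "revcomp",
    "orf_sequence",
]

NUCLEOTIDES = frozenset("ACGTN")

#: The seven binary full-length tests, positive (.p) and negative (.n).
POSITIVE_TESTS = ("1.p", "2.p", "3.p", "4.p")
NEGATIVE_TESTS = ("5.n", "6.n", "7.n")
TEST_IDS = POSITIVE_TESTS + NEGATIVE_TESTS

#: Closed vocabulary of positional tag labels.
TAG_LABELS = frozenset(
    {f"ATG{i}" for i in range(1, 10)} | {"ORF", "CONS", "CLI", "REF"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class XorfeomeError(Exception):
    """Base class for structured pipeline errors."""


class CoordinateError(XorfeomeError):
    """Raised when ORF coordinates are inconsistent with their sequence."""


def normalize_seq(seq: str) -> str:
    """Uppercase a nucleotide sequence and convert RNA U to T.

    Raises :class:`XorfeomeError` on symbols outside A/C/G/T/N.
    """
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - NUCLEOTIDES
    if bad:
        raise XorfeomeError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class FullLengthClass(str, enum.Enum):
    """Five-way full-length status of a cloned ORF."""

    GOOD = "good"
    CONSERVED = "conserved"
    MIXED = "mixed"
    BAD = "bad"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CloneRecord:
    """One cDNA clone with its reference ORF coordinates.

    ``orf_start`` is the first base of the annotated start codon (the
    quantity ``A`` used by the geometry tests); ``orf_end`` excludes the
    stop codon.  ``canonical`` flags clones whose annotated ORF is expected
    to begin with ATG; non-ATG starts are permitted but flagged.
    """

    clone_id: str
    cdna: str
    orf_start: int
    orf_end: int
    plate: str = ""
    well: str = ""
    canonical: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "cdna", normalize_seq(self.cdna))
        if not (0 <= self.orf_start < self.orf_end <= len(self.cdna)):
            raise CoordinateError(
                f"clone {self.clone_id}: ORF [{self.orf_start}, {self.orf_end}) "
                f"outside cDNA of length {len(self.cdna)}"
            )
        if (self.orf_end - self.orf_start) % 3:
            raise CoordinateError(
                f"clone {self.clone_id}: ORF length not a multiple of 3"
            )
        if self.canonical and self.cdna[self.orf_start : self.orf_start + 3] != "ATG":
            raise CoordinateError(
                f"clone {self.clone_id}: canonical ORF does not start with ATG"
            )

    @property
    def orf_len(self) -> int:
        return self.orf_end - self.orf_start


def orf_sequence(clone: CloneRecord) -> str:
    """Return the clone's ORF sequence, stop codon excluded.

    This is the insert amplified into the Gateway construct: coordinates
    are validated on :class:`CloneRecord` construction, so this is a plain
    slice ``cdna[orf_start:orf_end]``.
    """
    return clone.cdna[clone.orf_start : clone.orf_end]


@dataclass(frozen=True)
class EstContig:
    """Assembled EST cluster consensus with an annotated ORF.

    ``atg_score_positions`` carries start-codon conservation annotations
    (BLH/ATG-style scores: the ATG most consistent with conserved
    translation starts); ``cli_score_positions`` carries transcription-start
    ("cliff") annotations.  Both are consumed as given, never recomputed.
    """

    contig_id: str
    consensus: str
    est_orf_start: int
    est_orf_end: int
    atg_score_positions: tuple = ()
    cli_score_positions: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "consensus", normalize_seq(self.consensus))
        object.__setattr__(
            self, "atg_score_positions", tuple(tuple(p) for p in self.atg_score_positions)
        )
        object.__setattr__(
            self, "cli_score_positions", tuple(tuple(p) for p in self.cli_score_positions)
        )
        if not (0 <= self.est_orf_start < self.est_orf_end <= len(self.consensus)):
            raise CoordinateError(
                f"contig {self.contig_id}: ORF [{self.est_orf_start}, "
                f"{self.est_orf_end}) outside consensus of length {len(self.consensus)}"
            )
        for pos, score in self.atg_score_positions + self.cli_score_positions:
            if not (0 <= pos < len(self.consensus)):
                raise CoordinateError(
                    f"contig {self.contig_id}: annotation position {pos} out of range"
                )
            if score < 0:
                raise XorfeomeError(
                    f"contig {self.contig_id}: negative annotation score {score}"
                )


@dataclass(frozen=True)
class ProteinHit:
    """One translated alignment between a clone cDNA and a non-Xenopus protein.

    ``C`` is the nucleotide offset on the cDNA where conserved alignment
    starts; ``c_nt`` is the conservation start on the protein in nucleotide
    equivalents (3 x amino-acid offset); ``P = C - c_nt`` is the predicted
    start-codon position, which may be negative.
    """

    clone_id: str
    species: str
    C: int
    c_nt: int

    def __post_init__(self) -> None:
        if self.C < 0 or self.c_nt < 0:
            raise XorfeomeError(
                f"hit {self.clone_id}/{self.species}: negative alignment offsets"
            )
        if self.c_nt % 3:
            raise XorfeomeError(
                f"hit {self.clone_id}/{self.species}: c_nt not a multiple of 3"
            )

    @property
    def P(self) -> int:
        return self.C - self.c_nt


@dataclass(frozen=True)
class GeometrySummary:
    """Per-clone summary of protein-alignment geometry (means over hits)."""

    P_bar: float
    C_bar: float
    sigma_P: float
    P_max: int
    n_exact: int
    n_hits: int

    def __post_init__(self) -> None:
        if self.n_hits >= 1 and self.P_max < self.P_bar - 1e-9:
            raise XorfeomeError("P_max below mean P")
        if self.n_exact > self.n_hits:
            raise XorfeomeError("n_exact exceeds number of hits")


@dataclass(frozen=True)
class SequenceTag:
    """A 96-bp positional sequence tag.

    Tags shorter than the window (running off the 3' end of their source)
    are padded with N and flagged ``padded``.  ``ATGn`` labels are only
    legal on tags that begin with ATG.
    """

    sequence: str
    origin_position: int
    label: str
    padded: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        if len(self.sequence) != 96:
            raise XorfeomeError(
                f"tag at {self.origin_position}: length {len(self.sequence)} != 96"
            )
        if self.label not in TAG_LABELS:
            raise XorfeomeError(f"unknown tag label {self.label!r}")
        if self.label.startswith("ATG") and not self.sequence.startswith("ATG"):
            raise XorfeomeError(
                f"tag at {self.origin_position}: {self.label} label on non-ATG tag"
            )


@dataclass(frozen=True)
class TestScorecard:
    """Outcomes of the seven full-length tests plus the matched tag label."""

    scores: Mapping[str, int]
    matched_tag_label: Optional[str] = None
    evidence: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        got = set(self.scores)
        if got != set(TEST_IDS):
            raise XorfeomeError(
                f"scorecard must cover exactly {TEST_IDS}; got {sorted(got)}"
            )
        for tid, v in self.scores.items():
            if v not in (0, 1):
                raise XorfeomeError(f"test {tid}: score {v!r} not in {{0,1}}")
        object.__setattr__(self, "scores", dict(self.scores))
        object.__setattr__(self, "evidence", dict(self.evidence))

    @property
    def n_positive(self) -> int:
        return sum(self.scores[t] for t in POSITIVE_TESTS)

    @property
    def n_negative(self) -> int:
        return sum(self.scores[t] for t in NEGATIVE_TESTS)


@dataclass(frozen=True)
class PlateMapRow:
    """Consolidated plate-map record for one verified clone."""

    clone_id: str
    plate: int
    well: str
    full_length_status: FullLengthClass
    gene_symbol: str = ""
    umbrella_gene_id: Optional[str] = None
    forward_primer: str = ""
    reverse_primer: str = ""
    verified: bool = True
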