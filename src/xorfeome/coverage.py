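"""Homeolog-aware gene accounting for an allotetraploid clone collection.

X. laevis genes are frequently duplicated (homeologs); both copies are
orthologous to the single X. tropicalis gene.  Gene coverage is therefore
reported in *diploid equivalents*, where a homeologous pair counts as one
gene.  Curation groups homeologs under an umbrella gene id; for ORFs
without curated homeology, coverage is extrapolated by assuming the same
proportion of homeologous pairs as in the curated group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import ScoringParams, best_cluster_match
from .align import DEFAULT_PARAMS
from .classify import round_half_up
from .model import CloneRecord, EstContig, XorfeomeError

__all__ = [
    "GeneRecord",
    "two_pass_match",
    "diploid_equivalent_estimate",
    "homeolog_pair_stats",
]


@dataclass(frozen=True)
class GeneRecord:
    """One distinct ORF with its gene assignment and homeology curation."""

    orf_id: str
    gene_id: str
    umbrella_id: Optional[str] = None
    curated: bool = False

    def __post_init__(self) -> None:
        if self.curated != (self.umbrella_id is not None):
            raise XorfeomeError(
                f"orf {self.orf_id}: umbrella id must be present iff curated"
            )


def two_pass_match(
    clone: CloneRecord,
    contigs: Iterable[EstContig],
    primary_cutoff: float = 95.0,
    fallback_cutoff: float = 80.0,
    params: ScoringParams = DEFAULT_PARAMS,
    bit_floor: float = 50.0,
    index=None,
) -> Tuple[Optional[str], str]:
    """Best EST cluster at 95% identity, falling back to 80% for the alternate homeolog.

    Returns ``(contig_id or None, pass_used)`` with ``pass_used`` in
    ``{"primary_95", "fallback_80", "none"}`` (names keep the default
    cutoffs for readability; the cutoffs themselves are configurable).
    """
    contigs = list(contigs)
    cid = best_cluster_match(
        clone, contigs, primary_cutoff, params=params, bit_floor=bit_floor, index=index
    )
    if cid is not None:
        return cid, "primary_95"
    cid = best_cluster_match(
        clone, contigs, fallback_cutoff, params=params, bit_floor=bit_floor, index=index
    )
    if cid is not None:
        return cid, "fallback_80"
    return None, "none"


def diploid_equivalent_estimate(
    n_curated: int, g_curated: int, n_uncurated: int
) -> Tuple[int, int]:
    """Extrapolate diploid-equivalent gene coverage to the uncurated ORFs.

    Given ``n_curated`` ORFs known to cover ``g_curated`` diploid-equivalent
    gene loci, the ``n_uncurated`` remaining ORFs are assumed to collapse at
    the same rate: the estimate is ``round(n_uncurated * g_curated /
    n_curated)`` (half-up), and the total adds the curated loci.
    """
    if n_curated <= 0:
        raise XorfeomeError("curated ORF count must be positive")
    if g_curated < 0 or n_uncurated < 0:
        raise XorfeomeError("counts must be non-negative")
    g_uncurated_est = int(round_half_up(n_uncurated * g_curated / n_curated))
    return g_uncurated_est, g_curated + g_uncurated_est


@dataclass(frozen=True)
class HomeologPairStats:
    n_pairs: int
    n_genes_diploid_equiv: int
    pct_paired: float
    n_extra_duplicates: int


def homeolog_pair_stats(records: Sequence[GeneRecord]) -> HomeologPairStats:
    """Homeologous-pair accounting over distinct ORFs.

    A *pair* is an umbrella group containing at least two distinct gene
    ids; diploid-equivalent genes count each umbrella group once and each
    un-grouped gene once; *extra duplicates* are ORFs beyond the first per
    gene id.  ``pct_paired`` is 100 * pairs / diploid-equivalent genes,
    one decimal, half-up.
    """
    by_gene: Dict[str, List[GeneRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    n_extra_duplicates = sum(len(v) - 1 for v in by_gene.values())

    umbrella_genes: Dict[str, set] = {}
    solo_genes = set()
    for gene_id, recs in by_gene.items():
        umbrellas = {r.umbrella_id for r in recs if r.umbrella_id is not None}
        if umbrellas:
            for u in umbrellas:
                umbrella_genes.setdefault(u, set()).add(gene_id)
        else:
            solo_genes.add(gene_id)

    n_pairs = sum(1 for genes in umbrella_genes.values() if len(genes) >= 2)
    n_genes = len(umbrella_genes) + len(solo_genes)
    pct = round_half_up(100.0 * n_pairs / n_genes, 1) if n_genes else 0.0
    return HomeologPairStats(
        n_pairs=n_pairs,
        n_genes_diploid_equiv=n_genes,
        pct_paired=pct,
        n_extra_duplicates=n_extra_duplicates,
    )
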