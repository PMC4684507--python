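"""Propagation of human gene-disease associations onto ORFeome clones.

Two association modes are distinguished: *direct* links come from a curated
gene-phenotype catalogue (OMIM-style MIM phenotype ids) joined to clones
through a human-Xenopus ortholog map; *indirect* links are inherited
through co-membership in an inferred protein complex that contains at
least one directly linked gene.  A gene directly linked to a phenotype
never also carries that phenotype indirectly, and indirect links are
deduplicated across complexes (one link listing every contributing
complex).  ID bridging (Ensembl/Entrez/MIM) is assumed to have been
resolved upstream into the supplied join tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .model import XorfeomeError

__all__ = [
    "DiseaseLink",
    "direct_links",
    "indirect_links",
    "disease_coverage_summary",
    "DiseaseCoverageSummary",
]


@dataclass(frozen=True)
class DiseaseLink:
    """One ORF-phenotype association, direct or complex-inherited."""

    orf_id: str
    human_gene_id: str
    phenotype_id: str
    mode: str  # "direct" | "indirect"
    complex_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "indirect"):
            raise XorfeomeError(f"unknown association mode {self.mode!r}")
        if self.mode == "indirect" and not self.complex_ids:
            raise XorfeomeError("indirect links must name at least one complex")
        if self.mode == "direct" and self.complex_ids:
            raise XorfeomeError("direct links carry no complex ids")


def direct_links(
    phenotype_table: Iterable[Tuple[str, str]],
    ortholog_map: Iterable[Tuple[str, str]],
) -> List[DiseaseLink]:
    """Direct ORF-phenotype links through the human-Xenopus ortholog map.

    ``phenotype_table`` holds (human_gene_id, phenotype_id) rows;
    ``ortholog_map`` holds (human_gene_id, orf_id) rows.  One link per
    reachable (orf, phenotype) pair, deduplicated, deterministic order.
    """
    gene_phenos: Dict[str, Set[str]] = {}
    for g, ph in phenotype_table:
        gene_phenos.setdefault(g, set()).add(ph)
    out: List[DiseaseLink] = []
    seen = set()
    for g, orf in sorted(set(ortholog_map)):
        for ph in sorted(gene_phenos.get(g, ())):
            key = (orf, ph)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                DiseaseLink(orf_id=orf, human_gene_id=g, phenotype_id=ph, mode="direct")
            )
    return out


def indirect_links(
    complex_members: Iterable[Tuple[str, str]],
    direct: Sequence[DiseaseLink],
    ortholog_map: Iterable[Tuple[str, str]],
) -> List[DiseaseLink]:
    """Complex-inherited ORF-phenotype links.

    ``complex_members`` holds (complex_id, human_gene_id) rows.  Each
    complex with at least one directly linked member gene donates the union
    of its members' direct phenotypes to every other member; genes already
    carrying a phenotype directly never receive it indirectly.  Links are
    deduplicated across complexes, recording every contributing complex.
    """
    gene_direct: Dict[str, Set[str]] = {}
    for link in direct:
        gene_direct.setdefault(link.human_gene_id, set()).add(link.phenotype_id)

    members: Dict[str, Set[str]] = {}
    for cid, g in complex_members:
        members.setdefault(cid, set()).add(g)

    orfs_by_gene: Dict[str, Set[str]] = {}
    for g, orf in ortholog_map:
        orfs_by_gene.setdefault(g, set()).add(orf)

    # (gene, phenotype) -> contributing complexes
    inherited: Dict[Tuple[str, str], Set[str]] = {}
    for cid in sorted(members):
        genes = members[cid]
        complex_phenos: Set[str] = set()
        for g in genes:
            complex_phenos |= gene_direct.get(g, set())
        if not complex_phenos:
            continue  # no disease-linked member: contributes nothing
        for g in genes:
            for ph in complex_phenos:
                if ph in gene_direct.get(g, set()):
                    continue
                inherited.setdefault((g, ph), set()).add(cid)

    out: List[DiseaseLink] = []
    for (g, ph), cids in sorted(inherited.items()):
        for orf in sorted(orfs_by_gene.get(g, ())):
            out.append(
                DiseaseLink(
                    orf_id=orf,
                    human_gene_id=g,
                    phenotype_id=ph,
                    mode="indirect",
                    complex_ids=tuple(sorted(cids)),
                )
            )
    return out


@dataclass(frozen=True)
class DiseaseCoverageSummary:
    n_clones_linked: int
    n_genes_linked: int
    n_phenotypes: int
    n_phenotypes_direct: int
    n_complexes_touched: int
    n_complexes_fully_covered: int


def disease_coverage_summary(
    links: Sequence[DiseaseLink],
    complex_members: Iterable[Tuple[str, str]],
    ortholog_map: Iterable[Tuple[str, str]],
    orf_set: Iterable[str],
) -> DiseaseCoverageSummary:
    """Collection-level disease coverage counts.

    A complex is *touched* when at least one member gene carries a (direct
    or indirect) link to an ORF in ``orf_set``; it is *fully covered* when
    every member gene has an ortholog ORF in ``orf_set``.
    """
    orf_set = set(orf_set)
    links = [l for l in links if l.orf_id in orf_set]
    phenos = {l.phenotype_id for l in links}
    phenos_direct = {l.phenotype_id for l in links if l.mode == "direct"}

    members: Dict[str, Set[str]] = {}
    for cid, g in complex_members:
        members.setdefault(cid, set()).add(g)
    orfs_by_gene: Dict[str, Set[str]] = {}
    for g, orf in ortholog_map:
        orfs_by_gene.setdefault(g, set()).add(orf)

    linked_genes = {l.human_gene_id for l in links}
    touched = 0
    fully = 0
    for cid, genes in members.items():
        if genes & linked_genes:
            touched += 1
        if genes and all(orfs_by_gene.get(g, set()) & orf_set for g in genes):
            fully += 1
    return DiseaseCoverageSummary(
        n_clones_linked=len({l.orf_id for l in links}),
        n_genes_linked=len(linked_genes),
        n_phenotypes=len(phenos),
        n_phenotypes_direct=len(phenos_direct),
        n_complexes_touched=touched,
        n_complexes_fully_covered=fully,
    )
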