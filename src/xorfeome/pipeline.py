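"""End-to-end orchestration: verification, full-length tests, classification.

`score_clone` runs the seven full-length tests for a single clone against
its best-matching EST cluster and translated-alignment geometry;
`classify_collection` applies it to a whole bundle; `run_pipeline` runs
the complete stage chain (verify -> tests/classify -> coverage -> disease)
on an on-disk bundle, emitting one TSV per stage plus a run log.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .align import DEFAULT_PARAMS, ScoringParams, aa_local_align
from .classify import classify, lost_residue_distribution, summarize_classes
from .coverage import GeneRecord, diploid_equivalent_estimate, homeolog_pair_stats, two_pass_match
from .disease import direct_links, disease_coverage_summary, indirect_links
from .geometry import hit_geometry, summarize_geometry, test_2p, test_3p, test_6n
from .io import write_table
from .model import (
    CloneRecord,
    EstContig,
    FullLengthClass,
    ProteinHit,
    TEST_IDS,
    TestScorecard,
    XorfeomeError,
    orf_sequence,
)
from .simulate import Bundle
from .tags import (
    extract_atg_tags,
    match_reference_tag,
    reference_tag,
    relabel_tags,
    tag_tests,
    test_1p,
    test_5n,
)
from .verify import collection_summary, consolidate, verify_clone

__all__ = [
    "PipelineConfig",
    "CloneEvidence",
    "score_clone",
    "classify_collection",
    "run_pipeline",
    "translated_hit_geometry",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the verification tests, with defaults.

    The defaults are the published operating points: 95/80% identity for
    the two-pass cluster match, a 50-bit verification score, 12-bp windows
    for the mean-start test and the transcription-start rule, 96-bp tags
    at >= 80% similarity, an annotation score floor of 10, and the
    truncation cutoffs C_bar < 15 (or half the 5' UTR) with P below -15.
    """

    identity_primary: float = 95.0
    identity_fallback: float = 80.0
    bit_floor: float = 50.0
    verify_threshold: float = 50.0
    min_similarity: float = 0.80
    score_floor: float = 10.0
    cli_window: int = 12
    p_window: float = 12.0
    min_exact: int = 2
    c_cutoff: float = 15.0
    p_cutoff: float = -15.0
    params: ScoringParams = field(default_factory=ScoringParams)


@dataclass(frozen=True)
class CloneEvidence:
    """Per-clone audit record: matched cluster, test scores, class."""

    clone_id: str
    contig_id: Optional[str]
    pass_used: str
    scorecard: TestScorecard
    full_length_class: FullLengthClass


def _clone_hits(clone_id: str, hit_table: pd.DataFrame) -> List[ProteinHit]:
    rows = hit_table[hit_table["clone_id"] == clone_id]
    return [
        hit_geometry(clone_id, r.species, int(r.C), int(r.c_aa))
        for r in rows.itertuples()
    ]


def score_clone(
    clone: CloneRecord,
    contigs: Mapping[str, EstContig],
    hits: Sequence[ProteinHit],
    config: PipelineConfig = PipelineConfig(),
    index=None,
) -> CloneEvidence:
    """Run the seven full-length tests and classify one clone."""
    contig_id, pass_used = two_pass_match(
        clone,
        contigs.values(),
        primary_cutoff=config.identity_primary,
        fallback_cutoff=config.identity_fallback,
        params=config.params,
        bit_floor=config.bit_floor,
        index=index,
    )
    contig = contigs.get(contig_id) if contig_id else None

    s1 = test_1p(clone, contig)
    label = None
    if contig is not None:
        tags = relabel_tags(
            extract_atg_tags(contig), contig, config.score_floor, config.cli_window
        )
        label = match_reference_tag(
            reference_tag(clone), tags, config.min_similarity, config.params
        )
    s4, s7 = tag_tests(label)
    s5 = test_5n(clone, contig, config.params)

    A = clone.orf_start
    summary = summarize_geometry(list(hits), A)
    s2 = test_2p(summary, A, config.p_window)
    s3 = test_3p(summary, config.min_exact)
    s6 = test_6n(summary, A, config.c_cutoff, config.p_cutoff)

    evidence = {
        "1.p": f"contig={contig_id or 'none'}",
        "2.p": f"P_bar={summary.P_bar:.1f} A={A}" if summary else "no hits",
        "3.p": f"n_exact={summary.n_exact}" if summary else "no hits",
        "4.p": f"label={label or 'none'}",
        "5.n": "aligned" if contig else "no contig",
        "6.n": f"C_bar={summary.C_bar:.1f} P_max={summary.P_max}" if summary else "no hits",
        "7.n": f"label={label or 'none'}",
    }
    card = TestScorecard(
        scores={"1.p": s1, "2.p": s2, "3.p": s3, "4.p": s4, "5.n": s5, "6.n": s6, "7.n": s7},
        matched_tag_label=label,
        evidence=evidence,
    )
    return CloneEvidence(
        clone_id=clone.clone_id,
        contig_id=contig_id,
        pass_used=pass_used,
        scorecard=card,
        full_length_class=classify(card),
    )


def classify_collection(
    bundle: Bundle, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Evidence table (one row per clone) for a whole bundle."""
    from .align import ContigIndex

    index = ContigIndex({cid: c.consensus for cid, c in bundle.contigs.items()})
    rows = []
    for clone in bundle.clones:
        hits = _clone_hits(clone.clone_id, bundle.protein_hits)
        ev = score_clone(clone, bundle.contigs, hits, config, index=index)
        row = {
            "clone_id": ev.clone_id,
            "contig_id": ev.contig_id or "",
            "pass_used": ev.pass_used,
            "matched_tag_label": ev.scorecard.matched_tag_label or "",
            "class": ev.full_length_class.value,
        }
        for tid in TEST_IDS:
            row[f"test_{tid}"] = ev.scorecard.scores[tid]
        rows.append(row)
    return pd.DataFrame(rows)


def translated_hit_geometry(
    clone: CloneRecord, species: str, protein_aa: str
) -> Optional[ProteinHit]:
    """Derive translated-alignment geometry by aligning cDNA frames to a protein.

    The three forward frames of the cDNA are translated and locally
    aligned (BLOSUM62) to the foreign protein; the best frame gives the
    conservation start C on the cDNA (nt) and c on the protein (residues).
    """
    from Bio.Seq import Seq

    best = None
    for frame in range(3):
        sub = clone.cdna[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate())
        res = aa_local_align(aa, protein_aa)
        if res is None:
            continue
        score, q_aa, s_aa = res
        if best is None or score > best[0]:
            best = (score, frame + 3 * q_aa, s_aa)
    if best is None:
        return None
    return hit_geometry(clone.clone_id, species, C=best[1], c_aa=best[2])


def run_pipeline(
    bundle: Bundle,
    out_dir,
    config: PipelineConfig = PipelineConfig(),
    seed: Optional[int] = None,
    force: bool = False,
) -> Dict[str, object]:
    """Run every stage on a bundle, writing one TSV per stage to ``out_dir``.

    Stage outputs already present are reused unless ``force`` (cheap
    resume).  Returns a dictionary of summary statistics; a ``run_log.json``
    records version, parameters and stage order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {}

    # stage 1: verification from end reads
    verify_path = out_dir / "verification.tsv"
    reads_by_clone: Dict[str, list] = {}
    for r in bundle.reads:
        reads_by_clone.setdefault(r.clone_id, []).append(r)
    if verify_path.exists() and not force:
        vdf = pd.read_csv(verify_path, sep="\t", dtype=str)
        verdicts = {r.clone_id: r.passed == "True" for r in vdf.itertuples()}
    else:
        verdicts = {}
        vrows = []
        for clone in bundle.clones:
            res = verify_clone(
                reads_by_clone.get(clone.clone_id, []),
                [orf_sequence(clone)],
                threshold=config.verify_threshold,
                params=config.params,
            )
            verdicts[clone.clone_id] = res.passed
            vrows.append(
                {
                    "clone_id": clone.clone_id,
                    "passed": str(res.passed),
                    "best_bit_score": f"{res.best_hit.bit_score:.1f}" if res.best_hit else "",
                    "reason": res.reason,
                }
            )
        write_table(pd.DataFrame(vrows), verify_path)
    coll = collection_summary(bundle.clones, verdicts)
    summary["verification"] = dataclasses.asdict(coll)

    # stage 2: full-length tests and classification
    evidence_path = out_dir / "evidence.tsv"
    if evidence_path.exists() and not force:
        evidence = pd.read_csv(evidence_path, sep="\t", dtype=str, keep_default_na=False)
    else:
        evidence = classify_collection(bundle, config)
        write_table(evidence, evidence_path)
    classes = {
        row["clone_id"]: FullLengthClass(row["class"])
        for _, row in evidence.iterrows()
    }
    summary["classification"] = summarize_classes(classes.values())

    # consolidated plate map for passing clones
    gene_symbols = {
        r.clone_id: r.gene_symbol for r in bundle.gene_table.itertuples()
    } if "gene_symbol" in bundle.gene_table.columns else {}
    plate_rows = consolidate(bundle.clones, verdicts, classes, gene_symbols=gene_symbols)
    write_table(
        pd.DataFrame(
            [
                {
                    "plate": r.plate,
                    "well": r.well,
                    "clone_id": r.clone_id,
                    "status": r.full_length_status.value,
                    "gene_symbol": r.gene_symbol,
                    "verified": str(r.verified),
                }
                for r in plate_rows
            ]
        ),
        out_dir / "plate_map.tsv",
    )

    # stage 3: homeolog-aware gene coverage
    gene_records = [
        GeneRecord(
            orf_id=r.clone_id,
            gene_id=r.gene_id,
            umbrella_id=r.umbrella_id or None,
            curated=r.curated == "True",
        )
        for r in bundle.gene_table.itertuples()
    ]
    curated = [g for g in gene_records if g.curated]
    uncurated = [g for g in gene_records if not g.curated]
    pair_stats = homeolog_pair_stats(gene_records)
    cov: Dict[str, object] = dataclasses.asdict(pair_stats)
    if curated:
        g_curated = homeolog_pair_stats(curated).n_genes_diploid_equiv
        g_unc_est, g_total = diploid_equivalent_estimate(
            len(curated), g_curated, len(uncurated)
        )
        cov.update(
            n_curated=len(curated),
            g_curated=g_curated,
            n_uncurated=len(uncurated),
            g_uncurated_est=g_unc_est,
            g_total_est=g_total,
        )
    summary["coverage"] = cov
    write_table(pd.DataFrame([cov]), out_dir / "coverage.tsv")

    # stage 4: disease orthology
    direct = direct_links(bundle.phenotype_table, bundle.ortholog_map)
    indirect = indirect_links(bundle.complex_members, direct, bundle.ortholog_map)
    links = direct + indirect
    write_table(
        pd.DataFrame(
            [
                {
                    "orf_id": l.orf_id,
                    "human_gene_id": l.human_gene_id,
                    "phenotype_id": l.phenotype_id,
                    "direct": l.phenotype_id if l.mode == "direct" else "",
                    "indirect": l.phenotype_id if l.mode == "indirect" else "",
                    "complex_ids": ";".join(l.complex_ids),
                }
                for l in links
            ]
        ),
        out_dir / "disease_links.tsv",
    )
    orf_set = {c.clone_id for c in bundle.clones}
    dsum = disease_coverage_summary(
        links, bundle.complex_members, bundle.ortholog_map, orf_set
    )
    summary["disease"] = dataclasses.asdict(dsum)

    log = {
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "seed": seed,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": ["verify", "classify", "coverage", "disease"],
        "n_clones": len(bundle.clones),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return summary
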