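"""Synthetic clone collections with known ground truth.

The generator emulates the inputs of the verification pipeline — cDNA
clones with reference ORF coordinates, assembled EST cluster consensus
sequences with positional start-codon (BLH/ATG) and transcription-start
(EST/CLI) annotations, per-species translated-alignment geometry, 5'/3'
end reads, and gene/orthology/disease join tables — for six controllable
clone error modes:

``good``                   annotated start is the true conserved start;
``conserved``              annotated start is a later in-frame ATG whose
                           N-terminus is conserved (a CONS-scored ATG),
                           1-28 residues downstream of the EST start;
``bad_downstream_atg``     annotated start is a later in-frame ATG with no
                           conservation support (true start is upstream
                           and present in the clone's nominal 5' UTR);
``bad_5prime_truncated``   the cDNA itself is 5'-truncated: the upstream
                           sequence is physically absent, and translated
                           alignments run off the 5' end (P << 0);
``upstream_noncanonical``  the cDNA carries extra 5' sequence with a
                           spurious in-frame upstream ATG (non-canonical
                           transcription); the annotated ORF is correct;
``unknown``                no matching EST cluster and no protein hits.

ORFs are codon-structured: bodies are drawn from sense codons excluding
ATG and stops, and in-frame ATGs are placed only at controlled ladder
positions (spacing >= 21 nt) so that 96-bp tags at distinct ATGs stay
safely below the 80% similarity cutoff.  Fixed seeds give byte-identical
bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import file_checksum, read_fasta, read_table, write_fasta, write_table
from .model import (
    CloneRecord,
    EstContig,
    FullLengthClass,
    XorfeomeError,
    orf_sequence,
)
from .verify import EstRead

__all__ = ["SimConfig", "Bundle", "simulate_collection", "write_bundle", "read_bundle", "MODES"]

MODES = (
    "good",
    "conserved",
    "bad_downstream_atg",
    "bad_5prime_truncated",
    "upstream_noncanonical",
    "unknown",
)

EXPECTED_CLASS = {
    "good": FullLengthClass.GOOD,
    "conserved": FullLengthClass.CONSERVED,
    "bad_downstream_atg": FullLengthClass.BAD,
    "bad_5prime_truncated": FullLengthClass.BAD,
    "upstream_noncanonical": FullLengthClass.GOOD,
    "unknown": FullLengthClass.UNKNOWN,
}

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
#: sense codons excluding ATG: the random ORF body alphabet
_BODY_CODONS = [c for c in _ALL_CODONS if c not in _STOPS and c != "ATG"]
_SPECIES = ("human", "mouse", "chicken", "zebrafish", "yeast", "fly")

#: per-species jitter (nt) applied to the predicted start position P
_P_JITTER = (0, 0, 3, -3, 6, -6)


def _default_class_counts() -> Dict[str, int]:
    return {
        "good": 20,
        "conserved": 10,
        "bad_downstream_atg": 10,
        "bad_5prime_truncated": 10,
        "upstream_noncanonical": 5,
        "unknown": 5,
    }


@dataclass
class SimConfig:
    """Study conditions for a synthetic clone collection.

    Defaults mirror the real collection where it states them (homeolog
    pair fraction ~6.7%, a ~12% cloning-failure rate giving the 88% pass
    rate, 6 non-Xenopus evidence species, annotation scores well above the
    floor of 10) and otherwise use desk-scale but realistic values (ORFs
    of 120-260 codons against the collection's 75 bp - 7.5 kb range,
    UTRs of 30-90 nt, 250 nt end reads at 1% error).
    """

    seed: int = 0
    class_counts: Dict[str, int] = field(default_factory=_default_class_counts)
    homeolog_pair_fraction: float = 0.067
    homeolog_identity_pct: float = 90.0
    fallback_fraction: float = 0.5  # fraction of paired clones whose own contig is withheld
    noise_rate: float = 0.0  # substitution rate applied to clone cDNAs
    read_error_rate: float = 0.01
    read_len: int = 250
    read_failure_fraction: float = 0.12
    n_species: int = 6
    conservation_offsets: Tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 14, 20, 28)
    orf_codons: Tuple[int, int] = (120, 260)
    utr_len: Tuple[int, int] = (30, 90)
    ortholog_fraction: float = 0.8
    phenotype_fraction: float = 0.35
    curated_fraction: float = 0.83
    blh_score: float = 25.0
    cli_score: float = 30.0
    include_protein_fasta: bool = False

    def __post_init__(self) -> None:
        for k in self.class_counts:
            if k not in MODES:
                raise XorfeomeError(f"unknown clone mode {k!r}")
        if any(v < 0 for v in self.class_counts.values()):
            raise XorfeomeError("class counts must be >= 0")
        for frac in (
            self.homeolog_pair_fraction,
            self.fallback_fraction,
            self.noise_rate,
            self.read_error_rate,
            self.read_failure_fraction,
            self.ortholog_fraction,
            self.phenotype_fraction,
            self.curated_fraction,
        ):
            if not (0.0 <= frac <= 1.0):
                raise XorfeomeError("fractions must be in [0, 1]")
        if not (1 <= self.n_species <= len(_SPECIES)):
            raise XorfeomeError(f"n_species must be in [1, {len(_SPECIES)}]")
        if min(self.orf_codons) < 60:
            raise XorfeomeError("ORFs must be at least 60 codons for the ATG ladder")
        if max(self.conservation_offsets) > min(self.orf_codons) - 40:
            raise XorfeomeError("conservation offsets too large for the ORF length range")


@dataclass(frozen=True)
class TruthRecord:
    clone_id: str
    mode: str
    expected_class: FullLengthClass
    lost_residues: Optional[int] = None
    reads_ok: bool = True


@dataclass
class Bundle:
    """In-memory synthetic collection: pipeline inputs plus truth labels."""

    clones: List[CloneRecord]
    contigs: Dict[str, EstContig]
    protein_hits: pd.DataFrame  # clone_id, species, C, c_aa
    reads: List[EstRead]
    gene_table: pd.DataFrame  # clone_id, gene_id, gene_symbol, umbrella_id, curated
    ortholog_map: List[Tuple[str, str]]  # (human_gene_id, orf_id)
    phenotype_table: List[Tuple[str, str]]  # (human_gene_id, phenotype_id)
    complex_members: List[Tuple[str, str]]  # (complex_id, human_gene_id)
    truth: Dict[str, TruthRecord]
    proteins: Dict[str, str] = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _rand_utr(rng: np.random.Generator, n: int) -> str:
    """Random UTR sequence containing no ATG trinucleotide."""
    while True:
        s = _rand_seq(rng, n)
        if "ATG" not in s:
            return s


def _make_orf(rng: np.random.Generator, n_codons: int, ladder: Sequence[int]) -> str:
    """Codon-structured ORF: ATG start, in-frame ATGs only at ladder codons."""
    codons = ["ATG"]
    for i in range(1, n_codons):
        codons.append("ATG" if i in ladder else _BODY_CODONS[rng.integers(len(_BODY_CODONS))])
    return "".join(codons)


def _substitute(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    s = list(seq)
    for p in positions:
        choices = [b for b in _BASES if b != s[p]]
        s[p] = choices[rng.integers(3)]
    return "".join(s)


def _add_noise(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    return _substitute(rng, seq, positions)


def _mutate_homeolog(
    rng: np.random.Generator,
    seq: str,
    orf_start: int,
    orf_end: int,
    ladder_positions: Sequence[int],
    identity_pct: float,
) -> str:
    """Substitution-only homeolog copy at a target percent identity.

    Functional positions are protected: the 12-base ATG word at the start,
    ladder ATG codons, and non-third codon positions; third positions of
    AT*/TA*/TG* codons are skipped so no new in-frame ATG or stop appears.
    """
    protected = set(range(orf_start, orf_start + 12))
    for lp in ladder_positions:
        protected.update(range(lp, lp + 3))
    eligible = []
    for i in range(len(seq)):
        if i in protected:
            continue
        if orf_start <= i < orf_end + 3:  # ORF plus its stop codon
            if (i - orf_start) % 3 != 2:
                continue
            codon_start = i - 2
            if seq[codon_start : codon_start + 2] in ("AT", "TA", "TG"):
                continue
        eligible.append(i)
    n_mut = int(round(len(seq) * (100.0 - identity_pct) / 100.0))
    if n_mut > len(eligible):
        raise XorfeomeError("homeolog identity target infeasible for this sequence")
    positions = rng.choice(len(eligible), size=n_mut, replace=False)
    return _substitute(rng, seq, [eligible[i] for i in positions])


@dataclass
class _Gene:
    """One simulated transcript: UTR5 + ORF + stop + UTR3 with an ATG ladder."""

    seq: str
    u5: int
    orf_codons: int
    ladder: Tuple[int, ...]  # codon indices (0 = start codon) forced to ATG

    @property
    def orf_start(self) -> int:
        return self.u5

    @property
    def orf_end(self) -> int:
        return self.u5 + 3 * self.orf_codons

    def ladder_nt(self) -> List[int]:
        return [self.u5 + 3 * c for c in (0,) + self.ladder]


def _make_gene(rng: np.random.Generator, cfg: SimConfig, ladder: Sequence[int]) -> _Gene:
    n_codons = int(rng.integers(cfg.orf_codons[0], cfg.orf_codons[1] + 1))
    u5 = int(rng.integers(cfg.utr_len[0], cfg.utr_len[1] + 1))
    u3 = int(rng.integers(cfg.utr_len[0], cfg.utr_len[1] + 1))
    orf = _make_orf(rng, n_codons, ladder)
    stop = _STOPS[rng.integers(3)]
    seq = _rand_utr(rng, u5) + orf + stop + _rand_utr(rng, u3)
    return _Gene(seq=seq, u5=u5, orf_codons=n_codons, ladder=tuple(sorted(ladder)))


def _contig_for_gene(
    gene: _Gene, contig_id: str, blh_pos: Optional[int], cfg: SimConfig,
    cli_pos: Optional[int] = None,
) -> EstContig:
    atg = ((blh_pos, cfg.blh_score),) if blh_pos is not None else ()
    cli = ((cli_pos, cfg.cli_score),) if cli_pos is not None else ()
    return EstContig(
        contig_id=contig_id,
        consensus=gene.seq,
        est_orf_start=gene.orf_start,
        est_orf_end=gene.orf_end,
        atg_score_positions=atg,
        cli_score_positions=cli,
    )


def _protein_rows(
    rng: np.random.Generator, cfg: SimConfig, clone_id: str, A: int, mode: str,
    m_removed: int = 0,
) -> List[Dict]:
    """Per-species translated-alignment geometry rows for one clone.

    For supported starts (good/conserved/upstream_noncanonical) the
    predicted start P clusters on A with small jitter and >= 2 exact
    hits.  For downstream-ATG truncations P clusters on the upstream true
    start (passed in as A of the *true* start).  For whole-cDNA
    truncations conservation starts at the clone's 5' end (C = 0) with
    ``m_removed`` leading residues missing, driving P << 0.
    """
    rows = []
    for si in range(cfg.n_species):
        species = _SPECIES[si]
        jit = _P_JITTER[si % len(_P_JITTER)]
        if mode == "bad_5prime_truncated":
            extra = int(rng.integers(0, 3)) if si >= 2 else 0
            C, c_aa = 0, m_removed + extra
        else:
            c_aa = int(rng.integers(0, 11))
            P = A + jit
            C = P + 3 * c_aa
            if C < 0:
                C, c_aa = max(P, 0), 0
        rows.append({"clone_id": clone_id, "species": species, "C": C, "c_aa": c_aa})
    return rows


def _protein_fasta_entries(
    rng: np.random.Generator, clone_id: str, cdna: str, rows: List[Dict]
) -> Dict[str, str]:
    """Foreign-protein sequences consistent with the geometry rows.

    Each protein is ``c_aa`` random leading residues followed by the
    translation of the cDNA from C onward (up to 80 conserved residues).
    """
    from Bio.Seq import Seq

    out = {}
    aa_alphabet = "ARNDCQEGHILKMFPSTWYV"
    for r in rows:
        C, c_aa = r["C"], r["c_aa"]
        span = cdna[C : C + 3 * 80]
        span = span[: len(span) - len(span) % 3]
        body = str(Seq(span).translate()).split("*")[0]
        if len(body) < 20:
            continue
        prefix = "".join(aa_alphabet[rng.integers(20)] for _ in range(c_aa))
        out[f"{clone_id}|{r['species']}"] = prefix + body
    return out


def simulate_collection(config: SimConfig) -> Bundle:
    """Generate a full synthetic collection with ground-truth labels.

    Deterministic for a fixed config (byte-identical bundles on re-run).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    clones: List[CloneRecord] = []
    contigs: Dict[str, EstContig] = {}
    hit_rows: List[Dict] = []
    reads: List[EstRead] = []
    gene_rows: List[Dict] = []
    truth: Dict[str, TruthRecord] = {}
    proteins: Dict[str, str] = {}

    order: List[str] = []
    for mode in MODES:
        order.extend([mode] * config.class_counts.get(mode, 0))
    n_total = len(order)

    n_pairs = int(round(config.homeolog_pair_fraction * n_total))
    n_good = config.class_counts.get("good", 0)
    n_pairs = min(n_pairs, n_good // 2)
    # the first 2*n_pairs good clones are homeolog pairs (even index = L copy)
    good_seen = 0

    pending_pair: Optional[Tuple[_Gene, str, str]] = None  # gene, umbrella, partner clone
    pair_count = 0

    for idx, mode in enumerate(order):
        clone_id = f"XOC{idx:04d}"
        gene_id = f"g{idx:04d}"
        contig_id = f"ctg-{gene_id}"
        umbrella_id: Optional[str] = None
        lost: Optional[int] = None

        if mode == "good":
            good_seen += 1
            if pending_pair is not None:
                # homeolog partner: mutated copy of the pending gene
                base_gene, umbrella_id, _partner = pending_pair
                mutated = _mutate_homeolog(
                    rng,
                    base_gene.seq,
                    base_gene.orf_start,
                    base_gene.orf_end,
                    base_gene.ladder_nt(),
                    config.homeolog_identity_pct,
                )
                gene = replace(base_gene, seq=mutated)
                pending_pair = None
                withhold_contig = rng.random() < config.fallback_fraction
            else:
                gene = _make_gene(rng, config, ladder=())
                withhold_contig = False
                if pair_count < n_pairs and good_seen <= 2 * n_pairs:
                    umbrella_id = f"umb{pair_count:03d}"
                    pending_pair = (gene, umbrella_id, clone_id)
                    pair_count += 1
            cdna = gene.seq
            orf_start, orf_end = gene.orf_start, gene.orf_end
            if not withhold_contig:
                contigs[contig_id] = _contig_for_gene(
                    gene, contig_id, blh_pos=gene.orf_start, cfg=config, cli_pos=0
                )
            rows = _protein_rows(rng, config, clone_id, orf_start, mode)

        elif mode == "conserved":
            off = int(config.conservation_offsets[rng.integers(len(config.conservation_offsets))])
            if off >= 14:
                ladder = (off // 2, off)  # an intermediate ATG: clone start is ATG3
            else:
                ladder = (off,)
            gene = _make_gene(rng, config, ladder=ladder)
            cdna = gene.seq
            orf_start = gene.u5 + 3 * off
            orf_end = gene.orf_end
            contigs[contig_id] = _contig_for_gene(
                gene, contig_id, blh_pos=orf_start, cfg=config, cli_pos=0
            )
            rows = _protein_rows(rng, config, clone_id, orf_start, mode)
            lost = off

        elif mode == "bad_downstream_atg":
            k = int(rng.integers(2, 10))  # clone start is the k-th in-frame ATG
            ladder = tuple(7 * j for j in range(1, k))
            gene = _make_gene(rng, config, ladder=ladder)
            cdna = gene.seq
            orf_start = gene.u5 + 21 * (k - 1)
            orf_end = gene.orf_end
            contigs[contig_id] = _contig_for_gene(
                gene, contig_id, blh_pos=gene.orf_start, cfg=config
            )
            # protein evidence supports the upstream true start
            rows = _protein_rows(rng, config, clone_id, gene.orf_start, mode)

        elif mode == "bad_5prime_truncated":
            gene = _make_gene(rng, config, ladder=(7, 14))
            m = int(rng.integers(9, 13))  # leading codons physically absent
            cut = gene.u5 + 3 * m
            cdna = gene.seq[cut:]
            orf_start = 42 - 3 * m  # next ladder ATG (codon 14) in clone coords
            orf_end = gene.orf_end - cut
            contigs[contig_id] = _contig_for_gene(
                gene, contig_id, blh_pos=gene.orf_start, cfg=config
            )
            rows = _protein_rows(rng, config, clone_id, orf_start, mode, m_removed=m)

        elif mode == "upstream_noncanonical":
            gene = _make_gene(rng, config, ladder=())
            ext_len = 30
            orf_start = ext_len + gene.orf_start
            p0 = orf_start % 3
            p = p0 + 3 * int(rng.integers(0, (ext_len - 3 - p0) // 3 + 1))
            ext = list(_rand_utr(rng, ext_len))
            ext[p : p + 3] = "ATG"
            cdna = "".join(ext) + gene.seq
            orf_end = ext_len + gene.orf_end
            contigs[contig_id] = _contig_for_gene(
                gene, contig_id, blh_pos=gene.orf_start, cfg=config, cli_pos=0
            )
            rows = _protein_rows(rng, config, clone_id, orf_start, mode)

        elif mode == "unknown":
            gene = _make_gene(rng, config, ladder=())
            cdna = gene.seq
            orf_start, orf_end = gene.orf_start, gene.orf_end
            rows = []  # no contig, no protein evidence

        else:  # pragma: no cover
            raise XorfeomeError(f"unhandled mode {mode}")

        cdna = _add_noise(rng, cdna, config.noise_rate)
        canonical = cdna[orf_start : orf_start + 3] == "ATG"
        plate = idx // 96 + 1
        well = f"{'ABCDEFGH'[(idx % 96) // 12]}{idx % 12 + 1:02d}"
        clone = CloneRecord(
            clone_id=clone_id,
            cdna=cdna,
            orf_start=orf_start,
            orf_end=orf_end,
            plate=str(plate),
            well=well,
            canonical=canonical,
        )
        clones.append(clone)
        hit_rows.extend(rows)
        if config.include_protein_fasta and rows:
            proteins.update(_protein_fasta_entries(rng, clone_id, cdna, rows))

        # end reads from the ORF insert; a fraction of clones get junk reads
        reads_ok = rng.random() >= config.read_failure_fraction
        orf = orf_sequence(clone)
        rl = min(config.read_len, len(orf))
        if reads_ok:
            r5 = _add_noise(rng, orf[:rl], config.read_error_rate)
            r3 = _add_noise(
                rng,
                orf[-rl:].translate(str.maketrans("ACGTN", "TGCAN"))[::-1],
                config.read_error_rate,
            )
        else:
            r5, r3 = _rand_seq(rng, rl), _rand_seq(rng, rl)
        reads.append(EstRead(clone_id=clone_id, end="five_prime", sequence=r5))
        reads.append(EstRead(clone_id=clone_id, end="three_prime", sequence=r3))

        curated = umbrella_id is not None or rng.random() < config.curated_fraction
        if curated and umbrella_id is None:
            umbrella_id = f"umbS{idx:04d}"  # curated singleton group
        gene_rows.append(
            {
                "clone_id": clone_id,
                "gene_id": gene_id,
                "gene_symbol": f"sym{idx:04d}",
                "umbrella_id": umbrella_id or "",
                "curated": str(curated),
            }
        )
        truth[clone_id] = TruthRecord(
            clone_id=clone_id,
            mode=mode,
            expected_class=EXPECTED_CLASS[mode],
            lost_residues=lost,
            reads_ok=reads_ok,
        )

    # homeolog partners share the human ortholog; map a fraction of clones
    ortholog_map: List[Tuple[str, str]] = []
    phenotype_table: List[Tuple[str, str]] = []
    complex_members: List[Tuple[str, str]] = []
    umbrella_to_human: Dict[str, str] = {}
    human_genes: List[str] = []
    for row in gene_rows:
        if rng.random() >= config.ortholog_fraction:
            continue
        umb = row["umbrella_id"]
        if umb and umb in umbrella_to_human:
            hg = umbrella_to_human[umb]
        else:
            hg = f"HS_{row['gene_id']}"
            human_genes.append(hg)
            if umb:
                umbrella_to_human[umb] = hg
        ortholog_map.append((hg, row["clone_id"]))
    pheno_n = 0
    for hg in human_genes:
        if rng.random() < config.phenotype_fraction:
            for _ in range(int(rng.integers(1, 4))):
                phenotype_table.append((hg, f"MIM:{600000 + pheno_n}"))
                pheno_n += 1
    n_cpx = max(1, len(human_genes) // 4) if human_genes else 0
    for ci in range(n_cpx):
        size = int(rng.integers(3, 7))
        members = rng.choice(len(human_genes), size=min(size, len(human_genes)), replace=False)
        for mi in members:
            complex_members.append((f"CPX{ci:03d}", human_genes[int(mi)]))

    return Bundle(
        clones=clones,
        contigs=contigs,
        protein_hits=pd.DataFrame(
            hit_rows, columns=["clone_id", "species", "C", "c_aa"]
        ),
        reads=reads,
        gene_table=pd.DataFrame(
            gene_rows,
            columns=["clone_id", "gene_id", "gene_symbol", "umbrella_id", "curated"],
        ),
        ortholog_map=ortholog_map,
        phenotype_table=phenotype_table,
        complex_members=complex_members,
        truth=truth,
        proteins=proteins,
    )


def _scores_to_str(pairs) -> str:
    return ";".join(f"{int(p)}:{g:g}" for p, g in pairs)


def _scores_from_str(s: str):
    if not s:
        return ()
    return tuple(
        (int(p), float(g)) for p, g in (item.split(":") for item in s.split(";"))
    )


def write_bundle(bundle: Bundle, directory) -> Path:
    """Write the bundle as FASTA/TSV files plus a checksum manifest.

    Truth labels go to a separate TSV that the pipeline never reads.
    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    write_fasta({c.clone_id: c.cdna for c in bundle.clones}, directory / "clones.fasta")
    write_table(
        pd.DataFrame(
            [
                {
                    "clone_id": c.clone_id,
                    "orf_start": c.orf_start,
                    "orf_end": c.orf_end,
                    "plate": c.plate,
                    "well": c.well,
                    "canonical": str(c.canonical),
                }
                for c in bundle.clones
            ]
        ),
        directory / "clones.tsv",
    )
    write_fasta(
        {cid: ctg.consensus for cid, ctg in sorted(bundle.contigs.items())},
        directory / "contigs.fasta",
    )
    write_table(
        pd.DataFrame(
            [
                {
                    "contig_id": cid,
                    "est_orf_start": ctg.est_orf_start,
                    "est_orf_end": ctg.est_orf_end,
                    "atg_scores": _scores_to_str(ctg.atg_score_positions),
                    "cli_scores": _scores_to_str(ctg.cli_score_positions),
                }
                for cid, ctg in sorted(bundle.contigs.items())
            ]
        ),
        directory / "contigs.tsv",
    )
    write_table(bundle.protein_hits, directory / "protein_hits.tsv")
    write_fasta(
        {f"{r.clone_id}|{'5p' if r.end == 'five_prime' else '3p'}": r.sequence for r in bundle.reads},
        directory / "reads.fasta",
    )
    write_table(bundle.gene_table, directory / "genes.tsv")
    write_table(
        pd.DataFrame(bundle.ortholog_map, columns=["human_gene_id", "orf_id"]),
        directory / "orthologs.tsv",
    )
    write_table(
        pd.DataFrame(bundle.phenotype_table, columns=["human_gene_id", "phenotype_id"]),
        directory / "phenotypes.tsv",
    )
    write_table(
        pd.DataFrame(bundle.complex_members, columns=["complex_id", "human_gene_id"]),
        directory / "complexes.tsv",
    )
    if bundle.proteins:
        write_fasta(bundle.proteins, directory / "proteins.fasta")
    write_table(
        pd.DataFrame(
            [
                {
                    "clone_id": t.clone_id,
                    "mode": t.mode,
                    "expected_class": t.expected_class.value,
                    "lost_residues": "" if t.lost_residues is None else t.lost_residues,
                    "reads_ok": str(t.reads_ok),
                }
                for t in bundle.truth.values()
            ]
        ),
        directory / "truth_labels.tsv",
    )

    manifest = directory / "MANIFEST.txt"
    lines = []
    for p in sorted(directory.iterdir()):
        if p.name == "MANIFEST.txt" or p.is_dir():
            continue
        lines.append(f"{p.name}\t{file_checksum(p)}\t{p.stat().st_size}")
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_bundle(directory) -> Bundle:
    """Read a written bundle back into memory (truth labels included)."""
    directory = Path(directory)
    clone_seqs = read_fasta(directory / "clones.fasta")
    clone_meta = read_table(
        directory / "clones.tsv", required=["clone_id", "orf_start", "orf_end"]
    )
    clones = [
        CloneRecord(
            clone_id=row.clone_id,
            cdna=clone_seqs[row.clone_id],
            orf_start=int(row.orf_start),
            orf_end=int(row.orf_end),
            plate=getattr(row, "plate", ""),
            well=getattr(row, "well", ""),
            canonical=getattr(row, "canonical", "True") == "True",
        )
        for row in clone_meta.itertuples()
    ]
    contig_seqs = read_fasta(directory / "contigs.fasta")
    contig_meta = read_table(
        directory / "contigs.tsv",
        required=["contig_id", "est_orf_start", "est_orf_end"],
    )
    contigs = {
        row.contig_id: EstContig(
            contig_id=row.contig_id,
            consensus=contig_seqs[row.contig_id],
            est_orf_start=int(row.est_orf_start),
            est_orf_end=int(row.est_orf_end),
            atg_score_positions=_scores_from_str(getattr(row, "atg_scores", "")),
            cli_score_positions=_scores_from_str(getattr(row, "cli_scores", "")),
        )
        for row in contig_meta.itertuples()
    }
    hits = read_table(
        directory / "protein_hits.tsv", required=["clone_id", "species", "C", "c_aa"]
    )
    reads = []
    for name, seq in read_fasta(directory / "reads.fasta").items():
        clone_id, end = name.rsplit("|", 1)
        reads.append(
            EstRead(
                clone_id=clone_id,
                end="five_prime" if end == "5p" else "three_prime",
                sequence=seq,
            )
        )
    gene_table = read_table(directory / "genes.tsv", required=["clone_id", "gene_id"])
    orth = read_table(directory / "orthologs.tsv", required=["human_gene_id", "orf_id"])
    pheno = read_table(
        directory / "phenotypes.tsv", required=["human_gene_id", "phenotype_id"]
    )
    cpx = read_table(
        directory / "complexes.tsv", required=["complex_id", "human_gene_id"]
    )
    truth_df = read_table(directory / "truth_labels.tsv", required=["clone_id", "mode"])
    truth = {
        row.clone_id: TruthRecord(
            clone_id=row.clone_id,
            mode=row.mode,
            expected_class=FullLengthClass(row.expected_class),
            lost_residues=int(row.lost_residues) if row.lost_residues else None,
            reads_ok=row.reads_ok == "True",
        )
        for row in truth_df.itertuples()
    }
    proteins = (
        read_fasta(directory / "proteins.fasta")
        if (directory / "proteins.fasta").exists()
        else {}
    )
    return Bundle(
        clones=clones,
        contigs=contigs,
        protein_hits=hits,
        reads=reads,
        gene_table=gene_table,
        ortholog_map=list(orth.itertuples(index=False, name=None)),
        phenotype_table=list(pheno.itertuples(index=False, name=None)),
        complex_members=list(cpx.itertuples(index=False, name=None)),
        truth=truth,
        proteins=proteins,
    )
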