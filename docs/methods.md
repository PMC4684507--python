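# Methods

## Problem and scope

`xorfeome` re-implements, as a reusable and fully testable pipeline, the
computational machinery used to build and audit a Gateway-cloned ORFeome
for the allotetraploid frog *Xenopus laevis*: ORF-specific attB primer
design, EST-read verification of cloning success, a rule-based seven-test
assessment of whether each reference ORF is genuinely full length,
homeolog-aware gene-coverage accounting, and propagation of human
gene–disease associations onto clones through orthology.  Wet-lab steps
(BP/LR recombination, in vitro translation, vector construction) and the
upstream computation of EST-assembly full-length scores are out of scope;
the positional start-codon (BLH/ATG) and transcription-start (EST/CLI,
"cliff") scores are consumed as annotations on the EST contigs, never
recomputed.

## Coordinate model

All coordinates are 0-based, half-open, in nucleotides on the cDNA or
contig consensus.  `orf_start` (the quantity **A**) is the first base of
the annotated start codon; `orf_end` excludes the stop codon, which
occupies `[orf_end, orf_end+3)` — the amplified Gateway insert never
contains it.  Translated-alignment geometry stores the conservation start
on the foreign protein pre-converted to nucleotide equivalents
(`c_nt = 3 × residue offset`), so the predicted start position
`P = C − c_nt` is unit-consistent and may be negative (conservation
extending 5′ of the clone itself).

## The seven full-length tests

Positive tests (evidence the annotated start is correct):

1. **ATG word** — the 12 bases at the clone's annotated start equal the
   12 bases at the best-hit EST cluster's annotated start (exact,
   case-insensitive; N never matches).
2. **Mean predicted start** — |P̄ − A| ≤ 12 bp, averaging one best hit per
   foreign species.
3. **Exact start concordance** — at least two species independently give
   P = A exactly.
4. **Positive tag match** — the 96-bp tag at the clone's start matches
   (≥ 80% identity) a contig tag labelled ORF, CONS, CLI or ATG1.

Negative tests (evidence of truncation):

5. **Upstream start present** — the ATG words differ; under the
   clone↔contig alignment the contig start maps upstream of the clone's
   start, the clone's start maps onto a downstream in-frame ATG of the
   contig ORF, and an in-frame ATG in the clone's nominal 5′ UTR aligns
   to the contig's start codon.  A cDNA that physically lacks the
   upstream sequence cannot satisfy the last condition; that case is
   test 6's job.
6. **Whole-cDNA 5′ truncation** — conservation reaches the 5′ UTR
   (C̄ < min(15, ⌈A/2⌉)) while the protein is typically longer than the
   cDNA allows (P_max < −15, or P̄ + σ_P < −15, population σ).
7. **Negative tag match** — the start tag matches a contig tag labelled
   ATG2…ATG9 (an internal in-frame ATG).

Classification: *conserved* iff test 4 passed with matched label CONS
(checked first — it overrides negatives); else *good* (p>0, n=0),
*mixed* (p>0, n>0), *bad* (p=0, n>0), *unknown* (p=0, n=0).  The five
predicates provably partition the space (exhaustively enumerated in the
tests, 384 cases).

Design choices in ambiguous corners, made once and config-exposed:

* The C̄ cutoff is `min(15, ⌈A/2⌉)`: the second term keeps a clone whose
  entire 5′ UTR is shorter than 15 nt from trivially qualifying.
  `P_max` is read as the arithmetic maximum (not maximum magnitude).
* The annotation score floor (10) applies to both BLH/ATG and EST/CLI
  scores.
* The EST/CLI window is one-sided: any transcription-start annotation at
  or upstream of ATG1 + 12 nt relabels ATG1 → CLI (transcription starts
  upstream of the ATG by construction); ORF takes precedence over CLI.
* A tag labelled plain ATG1 (no conservation or cliff support) still
  counts as positive evidence, matching the published test definition.
* Per-species deduplication of translated hits keeps the first hit per
  species in input order (inputs are expected best-first); the hit
  records carry no score field with which to re-rank.

### A note on translation invariance

Prepending d nt of 5′ sequence shifts A, C, P and P̄ by exactly d, and
tests 2 and 3 are exactly invariant under it.  Test 6 is deliberately
*not*: its conservation-start cutoff is anchored to the absolute 5′ end
of the cDNA, so padding can only switch the test off (the clone with
extra 5′ sequence is less plausibly end-truncated), never on.  The
property suite asserts exactly this monotone form.

## Alignment engine

All BLAST-like steps run through one internal affine-gap local aligner
(Bio.Align.PairwiseAligner under the hood) over an A/C/G/T/N alphabet, so
the package has no external-tool dependency and results are exactly
reproducible.  Defaults are BLASTN-like: match +2, mismatch −3, a gap of
length L costs 5 + 2L; raw scores convert to bit scores with the
Karlin–Altschul transform (λ = 0.625, K = 0.41; both configurable, as the
published workflow does not state whether its "score of 50" threshold was
raw or bit — we read it as bit score, BLAST's default reporting unit).
N scores as a mismatch against everything and never counts toward
identity.  Identity is matches over alignment columns (gap columns
included).  Database-style searches use a 12-mer exact-word prefilter
(`ContigIndex`) before running full dynamic programming; candidate hits
must clear the 50-bit floor before the identity cutoffs apply, which
screens out the short spurious local hits that any seeded search
produces between unrelated sequences.  The tests cross-check the engine
against an independent, hand-written quadratic Smith–Waterman oracle on
hundreds of random pairs.

Best-cluster matching ranks qualifying hits by ascending start coordinate
on the clone cDNA, then descending bit score, then contig id ("start
coordinate on the reference" is read as the clone side; the opposite
convention is one config switch away).  The homeolog-aware two-pass rule
tries 95% identity first, then 80% to catch the alternate homeolog.

Translated (BLASTX-like) evidence is not a six-frame database search:
geometry rows (C, c) are first-class inputs, and an auxiliary routine
derives them by aligning the three forward-frame translations of a cDNA
against a protein with BLOSUM62 (gap costs 11 + 1L) when protein
sequences are available.  Because a local alignment can extend a few
residues into non-conserved sequence by chance, C and c individually are
alignment-dependent; their difference P is the stable quantity, and the
integration test asserts agreement on P.

## Primer design

Forward cores start at the first base of the start codon; reverse cores
are reverse complements of an ORF suffix ending at the last base before
the stop codon.  Core lengths (18–30 nt window) minimise |Tm − 60 °C|
(nearest-neighbour Tm by default, Wallace rule as fallback and for
N-containing cores), ties to the shorter core.  Cores are extended with
the canonical 29-nt attB1/attB2 adapters, supplied as data so
lab-specific tails can be substituted.  The published protocol anchors
only the core start/end; length-vs-Tm optimisation is this package's
choice and is deterministic.  An exact-match PCR simulator backs the
property that every designed pair amplifies exactly the ORF — no stop
codon, no UTR.

## Verification and consolidation

A clone passes verification when at least one of its 5′/3′ end reads
aligns to *its own* reference ORF at ≥ 50 bits.  The best database-wide
hit is retained as an audit field (it flags well swaps) but does not
drive the pass rule, whose published criterion is per-ORF.  Passing
clones are consolidated into 96-well plates row-major (A01…A12, B01…),
an invented but documented convention.  Collection summaries report the
pass rate as an integer percentage (half-up) and median ORF lengths.

## Homeolog-aware coverage and disease orthology

Gene coverage is counted in diploid equivalents: an umbrella group
(curated homeolog pair) counts once.  For ORFs without curated homeology
the diploid-equivalent count is extrapolated at the curated group's
collapse rate, `round(n_uncurated × g_curated / n_curated)` (half-up; all
reported percentages in the package round half-up, one decimal for class
fractions, integer for whole-collection rates).  Pair statistics count
umbrella groups with ≥ 2 distinct gene ids as pairs and ORFs beyond one
per gene id as duplicates.

Disease links are *direct* (curated gene–phenotype rows joined through
the human–Xenopus ortholog map) or *indirect* (inherited through
co-membership in a protein complex containing a directly linked gene;
the complex's phenotype set is the union of its members' direct
phenotypes).  A gene directly linked to a phenotype never also carries
it indirectly, and indirect links deduplicate across complexes while
recording every contributing complex.  ID bridging between vocabularies
is assumed resolved upstream into the supplied join tables; no live
lookups.

## Synthetic collections

The generator emulates every pipeline input with known ground truth, one
clone per simulated gene, in six error modes mirroring the failure
geometries seen in real collections: correct starts (`good`), conserved
downstream starts (`conserved`, 1–28 residues behind the EST start with
a CONS-scored annotation; offsets drawn from {1–6, 8, 10, 14, 20, 28},
majority ≤ 10 residues), unsupported downstream starts with the true
start in the nominal 5′ UTR (`bad_downstream_atg`), whole-cDNA 5′
truncations where the upstream sequence is physically absent
(`bad_5prime_truncated`), spurious upstream in-frame ATGs from
non-canonical transcription with a correct annotation
(`upstream_noncanonical`, expected class good), and clones with no
matching cluster and no protein evidence (`unknown`).

Study conditions (defaults, chosen once): ORFs of 120–260 codons and
UTRs of 30–90 nt — desk-scale against the real collection's 75 bp–7.5 kb
ORFs with ~1 kb medians, but large relative to every test window; six
evidence species with ≥ 2 exact-start hits and ±6 nt jitter for
supported starts; annotation scores 25 (BLH/ATG) and 30 (EST/CLI)
against the floor of 10; 250-nt end reads at 1% error with 12% of clones
given junk reads, emulating the 88% cloning success rate; homeolog pairs
on 6.7% of clones at 90% identity — between the 95%/80% two-pass
cutoffs, so both passes are exercised — with half the paired clones'
own contigs withheld to force the fallback; 80% of genes given human
orthologs, 35% of those with 1–3 phenotypes, complexes of 3–6 genes.

Structural guarantees the tests rely on: ORF bodies are drawn from sense
codons excluding ATG and stops, with in-frame ATGs only at controlled
ladder positions spaced ≥ 21 nt (tags at adjacent ladder ATGs then share
at most 75/96 columns, safely below the 80% cutoff); homeolog mutation
is substitution-only at third codon positions (and UTRs), never touching
the start word or ladder codons and never creating an in-frame ATG or
stop, hitting the identity target within ±1%.  What this does *not*
emulate: realistic codon usage and GC content, indels, splice variation,
assembly errors in the contigs, or disagreement between annotation
positions and the consensus.  Passing the recovery tests therefore shows
the decision logic is faithful to its inputs, not that real collections
are this clean — on real data the published workflow's inputs carry all
of those artefacts.

Determinism: one seeded generator drives the whole bundle; fixed seeds
give byte-identical on-disk bundles (checksummed manifest).  Truth
labels are written to a separate TSV the pipeline never reads.

## Problem sizes and numerics

The recovery studies use 600 clones (100 per mode), where end-to-end
classification takes a few minutes on one CPU; the aligner/oracle
cross-check uses 500 random pairs of ≤ 60 nt, where the quadratic oracle
is exact and fast.  Degenerate inputs are handled by abstention rather
than error wherever the published tests abstain: no matching cluster or
no protein hits score 0 on the affected tests (never 1), an empty hit
list yields an absent geometry summary, and an unalignable clone/contig
pair scores 0 on the upstream-start test.  Ties are broken
deterministically everywhere (tag matching toward the more 5′ tag;
cluster ranking by start, bit score, then id; primer cores toward the
shorter length).

## Known limitations

* The aligner reports one optimal local alignment per pair (no multi-HSP
  chaining, no E-values); co-optimal tracebacks resolve deterministically
  but arbitrarily.
* Identity for the two-pass rule is measured on the best local alignment,
  which trims mismatch-dense ends and so reads slightly above the global
  identity of a homeolog pair; the 95/80 cutoffs absorb this in practice.
* The conserved override requires the matched tag label CONS exactly; a
  CLI-labelled match has no override, an ambiguity the published rule
  set leaves open (noted, not resolved).
* Whether a best database-wide hit on a *different* ORF should fail a
  clone (cross-contamination) is left as an optional strict audit rather
  than a pass-rule change.
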