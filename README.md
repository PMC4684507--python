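# xorfeome

Construction and quality-audit machinery for Gateway-cloned ORFeome
collections, modelled on the *Xenopus laevis* case: every open reading
frame (ORF) from a cDNA clone collection is PCR-amplified with
attB-tailed ORF-specific primers, verified by 5′/3′ end-read alignment,
and — because single-pass ORF predictions are wrong in roughly one clone
in ten — re-assessed for full-length status against independent EST
assemblies and cross-species protein conservation.  The package is aimed
at groups building or curating clone resources who need the whole chain
to be reproducible, scriptable and testable without proprietary data.

## What it computes

For each clone with annotated start codon position **A** (0-based, on
the cDNA), translated alignments to proteins from non-*Xenopus* species
give a conservation start **C** on the cDNA and a conservation start
*c* on the foreign protein; the predicted start-codon position is

    P = C − 3c,   P̄, σ_P averaged over one best hit per species.

Seven binary tests combine this geometry with positional 96-bp sequence
tags taken at successive in-frame ATGs of the best-matching EST cluster
(labelled ATG1…ATG9, relabelled ORF/CONS/CLI from start-codon
conservation and transcription-start annotations):

| test | fires when |
|------|------------|
| 1.p | 12-base ATG words of clone and cluster match exactly |
| 2.p | \|P̄ − A\| ≤ 12 bp |
| 3.p | ≥ 2 species give P = A exactly |
| 4.p | start tag matches a tag labelled ORF/CONS/CLI/ATG1 (≥ 80%) |
| 5.n | clone start is a downstream in-frame ATG; true start sits in its 5′ UTR |
| 6.n | conservation reaches the 5′ UTR (C̄ < min(15, ⌈A/2⌉)) and P_max < −15 or P̄+σ_P < −15 |
| 7.n | start tag matches ATG2…ATG9 |

With p positive and n negative tests: **conserved** iff 4.p passed with
label CONS (overrides negatives); else **good** (p>0, n=0), **mixed**
(p>0, n>0), **bad** (p=0, n>0), **unknown** (p=0, n=0).

Around this core sit attB primer design, EST-read verification
(bit score ≥ 50 against the clone's own reference ORF), 96-well
consolidation, homeolog-aware diploid-equivalent gene coverage for the
allotetraploid genome (two-pass 95%/80% cluster matching), and
direct/indirect human disease-gene association through orthology and
protein-complex co-membership.  A synthetic-data generator produces
complete input bundles with known ground truth in six clone error modes.

## Worked example

```
xorfeome simulate --seed 11 --out demo/bundle --clones-per-mode 3
xorfeome run --bundle demo/bundle --out demo/out
```

prints (abridged):

```
"verification":   {"n_attempted": 18, "n_passed": 17, "pct_passed": 94,
                   "median_orf_len_passed": 459.0, ...}
"classification": {"good": {"count": 6, "pct": 33.3},
                   "conserved": {"count": 3, "pct": 16.7},
                   "bad": {"count": 6, "pct": 33.3},
                   "unknown": {"count": 3, "pct": 16.7},
                   "good_or_conserved": {"count": 9, "pct": 50.0}, ...}
"coverage":       {"n_pairs": 1, "n_genes_diploid_equiv": 17,
                   "g_uncurated_est": 2, "g_total_est": 17, ...}
"disease":        {"n_clones_linked": 5, "n_phenotypes": 6, ...}
```

Of the 18 simulated clones, 17 verify (one drew failing reads); the six
clones simulated with correct starts classify good, the three with
conserved downstream starts classify conserved, the six truncation modes
classify bad, and the three clones with no supporting evidence stay
unknown.  `demo/out/` holds per-stage TSVs: `evidence.tsv` gives the
per-clone test scores and matched tag label behind each call,
`plate_map.tsv` the consolidated 96-well layout, `disease_links.tsv`
direct and indirect associations in separate columns.

The same objects are available as a library:

```python
from xorfeome import SimConfig, simulate_collection
from xorfeome.pipeline import classify_collection

bundle = simulate_collection(SimConfig(seed=11))
evidence = classify_collection(bundle)   # one row per clone
```

## Layout

```
src/xorfeome/
  model.py      domain types, coordinate conventions, invariants
  align.py      affine-gap local aligner, bit scores, word index, tag similarity
  primers.py    attB-tailed primer design and PCR simulation
  verify.py     end-read verification, consolidation, collection summary
  geometry.py   translated-alignment geometry and tests 2.p/3.p/6.n
  tags.py       96-bp tag extraction/relabelling and tests 1.p/4.p/5.n/7.n
  classify.py   five-way classification and class summaries
  coverage.py   homeolog umbrella accounting, two-pass match, coverage estimate
  disease.py    direct/indirect disease-association propagation
  simulate.py   ground-truth synthetic collections (six error modes)
  pipeline.py   stage orchestration
  cli.py, io.py command line and FASTA/TSV plumbing
```

See `docs/methods.md` for the model, parameter defaults with rationale,
what the generator does and does not emulate, and known limitations.
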