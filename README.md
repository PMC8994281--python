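# minimito

Comparative analysis of fragmented mitochondrial (mt) genomes, built
around the minichromosomal organisation of sucking lice.  The package
provides:

* **`karyotype_model`** — a data model for minichromosome karyotypes
  (ordered, oriented gene lists from the 37-gene mt vocabulary, with
  explicit missing-gene bookkeeping), a plain-text karyotype format with
  parser/writer, and packaged fixtures for five seal louse species, the
  gorilla louse and reference lineages.
* **`ancestral_inference`** — extraction of minichromosomal characters
  (oriented adjacencies and co-membership blocks with ternary
  present/absent/missing support) and ancestral karyotype inference by a
  two-clause parsimony rule: a character is ancestral if it is present
  in at least one ingroup taxon *and* in the MRCA of the enclosing
  clade, or present in every ingroup taxon in which it is scorable.
* **`event_inference`** — classification of ancestor/descendant
  karyotype differences as minichromosome **splits**, **mergers**, tRNA
  **translocations** and gene **losses**, anchored on protein-coding and
  rRNA genes, plus per-branch/per-family tallies over a Newick
  phylogeny.
* **`alignment_identity`** — affine-gap pairwise identity with
  ClustalW-style DNA scoring (IUB-like matrix, gap open 15, gap extend
  6.66), per-gene identity tables, paralog ranking by cross-taxon
  identity, and local degenerate-gene scans of non-coding sequence with
  1-based reference coordinates.
* **`motif_discovery`** — conserved AT-rich/GC-rich motif discovery in
  non-coding regions by k-mer seeding, consensus re-alignment and
  greedy column-conserved extension.
* **`synthetic_data`** — a ground-truthed simulator of karyotype
  evolution (Poisson split/merge/translocation/loss per branch) and
  sequence divergence (single-parameter substitution model, planted NCR
  motifs) whose event log replays exactly.
* **`cli`** — a `minimito` command with subcommands
  `infer-ancestral`, `events`, `identity`, `paralogs`,
  `scan-degenerate`, `motifs`, `simulate` and `run-all`.

## Command line

```sh
# ancestral karyotype of the seal lice from the packaged fixtures
minimito infer-ancestral src/minimito/fixtures/antarctophthirus_*.kt \
    src/minimito/fixtures/lepidophthirus_macrorhini.kt \
    src/minimito/fixtures/proechinophthirus_fluctus.kt \
    --mrca src/minimito/fixtures/anoplura_mrca.kt --clade sealice_mrca

# rearrangement events over the packaged phylogeny
minimito events --tree src/minimito/fixtures/anoplura.nwk \
    --karyotype src/minimito/fixtures/anoplura_mrca.kt \
    --karyotype src/minimito/fixtures/sealice_mrca.kt \
    --karyotype src/minimito/fixtures/proechinophthirus_fluctus.kt \
    --families src/minimito/fixtures/families.yaml

# the whole pipeline from a YAML config
minimito run-all --config pipeline.yaml
```

A minimal `pipeline.yaml`:

```yaml
use_packaged_fixtures: true
clade: sealice_mrca
mrca: anoplura_mrca
outdir: out/
```

## Karyotype text format

One file per taxon: `#taxon`/`#missing` headers, then one
minichromosome per line with hyphen-separated genes in coding order.  A
`!` suffix marks reverse transcription orientation; trailing digits or
`*` are paralog/variant tags (`W1`, `T*`).

```
#taxon lepidophthirus_macrorhini
#missing C F G R S1 S2 Y nad3 nad4L nad6
atp8-atp6-N
Q!-nad1!-T*!-W1
...
```

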