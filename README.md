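# stkflux

Tools for studying gene-content evolution and Ser/Thr kinase (STK) expansion
in bacterial genomes — built for comparative genomicists working on lineages
such as the *Planctomycetota*, where a handful of species carry hundreds of
eukaryotic-like Ser/Thr kinases, most of them membrane receptors with long
tandem arrays of TPR or WD40 domains.

The package implements the analysis stages that sit between standard
third-party outputs (orthology matrices, profile-search hit tables, domain
and topology predictions) and biological conclusions:

* **Compositional bias ranking (aminoGC).**  For each single-copy gene, the
  per-taxon fraction of G/C at codon positions 1–2 and its across-taxa
  standard deviation σ(aminoGC) — a protein-level proxy for GC bias that can
  distort phylogenies.  Genes are ranked by σ(aminoGC) or by dN to build
  least/most-biased k-gene concatenates, and a stationary-trimming step
  removes alignment sites until amino-acid composition is homogeneous across
  taxa (chi-square contingency test, greedy site removal).
* **Gene flux by asymmetric Wagner parsimony.**  Given a family × taxon
  count matrix and a rooted species tree, ancestral counts minimise
  Σ (g·gains + l·losses) per branch (default gain penalty g = 2, loss
  penalty l = 1), computed by an exact Sankoff dynamic programme vectorised
  across families, with per-branch gained/lost family sets and unit counts.
* **Region-based COG category assignment.**  Hits merge into regions by
  interval overlap; a region gets a category letter only with ≥5 supporting
  hits and ≤50% conflicting coverage, otherwise the markers "−" (no hits),
  "?" (competing categories) or "+" (under-supported) are emitted.
* **KDD kinase classification.**  Pkinase profile hits are stitched by model
  coordinates; a protein is a functional STK when its hits jointly cover the
  model (≥80% by default) and align the catalytic K/D/D residues (subdomains
  II, VIb, VII) at the configured model columns.
* **Domain architecture and membrane sidedness.**  Ordered token strings
  (domains + TM + signal peptide), cytoplasmic/periplasmic sidedness under
  the single-membrane convention (inside = cytoplasm; parity inference when
  only TM helices are given), tandem-array statistics, and per-clade STK
  summaries.
* **A synthetic-data generator** that produces every input above with known
  ground truth, so the whole pipeline is testable without downloads.

## Worked example

Generate a synthetic study (12 taxa, 500 families, 1,200 kinase fixtures),
reconstruct gene flux, and classify the kinases:

```bash
stkflux simulate --seed 11 --outdir sim
stkflux flux --tree sim/tree.nwk --profile sim/profile.tsv \
             --gain-penalty 2 --out-prefix flux
# INFO total cost 715.0; wrote flux.branches.tsv and flux.nodes.tsv
head -4 flux.branches.tsv
# parent  child  gained  lost  units_gained  units_lost
# N0      N1     0       29    0             29
# N1      N2     8       13    8             13
# N2      T01    9       7     9             7
```

Each row is one branch of the species tree: on the branch from node `N1` to
`N2`, 8 families were gained and 13 lost under the minimum-cost
reconstruction with a gain penalty of 2.  Node totals (families present per
ancestral node) are in `flux.nodes.tsv`.

```bash
stkflux kinscan --domtbl sim/hits.domtbl \
                --alignments sim/hit_alignments.tsv --out calls.tsv
# INFO classified 1200 proteins -> calls.tsv
head -4 calls.tsv
# protein_id                    verdict     K     D1    D2    stitched  coverage_fraction
# P_fragmented_functional_0001  functional  True  True  True  True      1.0
```

The fixture set contains 200 proteins in each of six classes; the classifier
calls 400 functional (intact or fragment-stitched K/D/D) and 800 putative
nonfunctional (a catalytic residue substituted, or a model gap over a
catalytic column) — exactly the generator's intended labels.

The same stages are importable as a library
(`stkflux.flux.wagner_reconstruct`, `stkflux.kinase.stitch_and_classify`,
…); the CLI subcommands `aminogc`, `select-datasets`, `trim`, `cogclass`,
`arch` and `summarize` cover the remaining stages.

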