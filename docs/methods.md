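# Methods

`stkflux` implements the bespoke computational stages of a comparative-genomics
workflow for studying gene-content evolution and Ser/Thr kinase (STK)
expansion in bacteria: compositional-bias gene ranking, asymmetric
Wagner-parsimony gene flux, region-based COG category assignment, catalytic
(KDD) kinase classification, and domain-architecture/membrane-topology
analysis.  This note records the models, the parameters that matter, the
numerical choices, and the limits of what the synthetic fixtures can show.

## Coordinate convention

Every consumed dialect (hmmsearch `--domtblout`, InterProScan-style TSV,
GFF3 topology, tabular homology hits) uses 1-based inclusive coordinates, and
the in-memory objects keep that convention throughout.  Using a single
convention end to end removes the I/O conversion boundary where off-by-one
errors usually live; interval arithmetic (unions, overlaps, coverage) is
written for closed intervals.

## aminoGC and compositional-bias ranking

For a gene's in-frame codon alignment, the per-taxon aminoGC is the fraction
of G/C among codon positions 1 and 2 (third positions never enter; gaps and
N are excluded from numerator and denominator, so gap density cannot
masquerade as composition).  A gene's bias score is the standard deviation of
per-taxon aminoGC, with the sample (n−1) denominator — taxa are treated as a
sample; switching to the population denominator is a one-line change in
`amino_gc`.  Taxa with zero informative position-1/2 sites are dropped from
the sd with a warning.

Gene ranking (`rank_and_select`) takes the k smallest or largest genes by
aminoGC sd or by an externally supplied per-gene mean dN (a codeml digest
read from TSV; substitution-rate estimation is out of scope).  Ties at the
k-th value break by lexicographically smaller gene id so selections are
reproducible.  Dataset overlap is plain set intersection.

## Stationary trimming

`stationary_trim` operationalises "remove sites until the retained sites are
compositionally homogeneous" as a greedy loop on the taxa × amino-acid count
table: the homogeneity statistic is the Pearson chi-square of that
contingency table, the test rejects when its chi-square p-value (df =
(T−1)(A−1), empty rows/columns dropped) falls below `alpha`, and each
iteration removes the single site whose removal most reduces the statistic
(ties toward the smaller site index).  The loop stops at homogeneity or at
`max_removed_fraction`; it errors only if every site would be removed.  This
is a contract-level reimplementation of stationary trimming, not a
bit-compatible clone of any particular trimmer, whose site order is
unspecified.

Two practical notes.  First, because the loop's stopping rule is a calibrated
test, it is idempotent whenever it terminates by acceptance: re-trimming a
trimmed alignment removes nothing.  Second, composition tests have
essentially no power on toy alignments — a couple of deviant residues per
taxon cannot reject at conventional alpha.  Demonstrations on small examples
therefore drive the loop with alpha close to 1 (demanding near-exact
homogeneity) so that the greedy site selection, which is the substance of the
contract, can be observed; production use on concatenates of thousands of
sites works at conventional alpha (default 0.05).

## Wagner-parsimony gene flux

Ancestral family counts are reconstructed per family by an exact
Sankoff-style dynamic programme over integer states 0..cap, with branch step
costs `gain_penalty` per +1 and `loss_penalty` per −1 (defaults 2 and 1; the
asymmetry makes the reconstruction reluctant to invent families).  Leaves
cost 0 at their observed count and ∞ elsewhere; an internal node's cost at
state s sums, over children, the minimum of child cost plus step cost;
multifurcations are handled natively by that sum.  The root takes the
minimum-cost state and a top-down backtrace fixes all counts.  Ties break
toward the smaller count at every choice — deterministic output with a
conservative bias against inflated ancestral genomes.  Counts are capped at
the maximum observed leaf count (states above it cannot be optimal under
positive penalties); families absent from every leaf carry no information
and are dropped with a warning.  The DP is vectorised across families with
numpy, so genome-scale matrices (tens of thousands of families) reconstruct
in seconds.

Per branch the result reports both family-level events (gained: parent 0 →
child >0; lost: parent >0 → child 0) and unit counts (every ±1 step), which
disambiguates multi-copy expansions from family-level turnover.  Rooting is
the caller's responsibility: the newick root is taken as given.

The simulator used to validate this stage evolves 0/1 presence states
root-to-leaves with at most one event per branch per family, so the event
log is unambiguous.  Branch-exact event recovery is only a meaningful score
in the low-rate regime (≈0.005 events/branch, at most ~0.25 events per
family on the default 12-taxon trees): at higher rates many families carry
several events and parsimony correctly prefers a cheaper history than the
simulated one, so "recovery" measures the simulation's identifiability, not
the reconstruction's correctness.  Even at low rates, events on the two
branches adjacent to a bifurcating root are intrinsically ambiguous (a gain
on one root child is cost-equivalent or inferior to a loss on its sibling),
which bounds recovery at roughly 1 − 1/#branches; the validation suite's
≥90% recovery threshold sits just below that bound.

## COG category assignment

Hits (pre-filtered at e ≤ 1e−5) are merged into regions by single-linkage
interval overlap (≥1 shared residue); residues covered by no hit form "−"
regions, and regions tile the protein exactly.  A region is assigned the
unique one-letter category with ≥5 supporting hits (a multi-letter category
such as "KT" supports each letter) and conflicting coverage ≤50%, where
conflict is the fraction of region residues covered by hits of another
category (a hit-count variant is available behind `conflict_mode="hits"`).
"?" marks regions where several categories qualify, or where well-supported
categories drown each other above the conflict limit; "+" marks regions
whose best-supported category has fewer than 5 hits.  All decisions are
set-based, so verdicts are independent of input row order.  A protein's
dominant category is that of its longest assigned region; a family's
category is the modal dominant category of its members (ties → "?").

## Kinase (KDD) classification

Catalytic capability of a Pkinase-domain protein requires a lysine
(subdomain II) and two aspartates (subdomains VIb and VII) at specific
profile-model columns.  Those columns live in a `KddSpec` configuration, not
in code, because model columns drift between profile releases.  The packaged
default spec (`data/kdd_spec_synthetic.yaml`) describes the synthetic
264-column model emitted by the generator (K=30, D1=125, D2=143).  For a
real PF00069 release, derive the columns by aligning a reference kinase with
experimentally known catalytic residues (human PKA Cα: K72, D166, D184) to
that release's HMM and reading off the matched columns; the spec file
documents this procedure.

A protein is *functional* when the union of its hit spans covers ≥
`min_model_coverage` of the model (default 0.8 — "essentially complete"
without demanding perfectly trimmed envelopes) AND each catalytic column is
aligned to an allowed residue by at least one hit; the per-site any-instance
rule is what stitches fragmented domains.  Only the canonical residues
satisfy a site by default (no tolerated substitutions).  A protein with
Pkinase evidence failing either criterion is *putative nonfunctional*; a
protein without Pkinase hits is not a kinase.  Verdicts are invariant to hit
order and duplication, and lowering the coverage threshold can only move
verdicts toward functional.

## Architecture and sidedness

Overlapping domain hits are resolved greedily by descending bitscore,
keeping a hit only if it overlaps every kept hit by <50% of the shorter
interval (ties break by accession then start, so resolution is
order-independent).  Tokens (grouped domains, TM, SP) are ordered by start
coordinate.  Sidedness follows the single-membrane convention: topological
"inside" = cytoplasmic, "outside" = periplasmic; TM helices are "membrane".
When a topology supplies only TM helices, sides are inferred by parity — the
N-terminus is cytoplasmic unless a signal peptide is present (the mature
chain then starts periplasmic), flipping at each helix.  Explicit labels are
validated: the two sides flanking a TM must differ.  A domain's side is the
side of the segment containing its midpoint (robust to small boundary
jitter); a domain spanning a TM helix is labelled "membrane" with a warning.

Tandem arrays are maximal runs of consecutive domain tokens of one group;
TM/SP tokens do not interrupt a run, because a repeat region flanking a
membrane helix is still one contiguous array at the sequence level and
per-protein copy counts are the quantity of interest.  Cohort statistics
report total copies, proteins containing the group, mean copies per
containing protein, and the longest run.

## The synthetic-data generator

All pipeline inputs can be generated with known ground truth from one
`SimConfig` (identical configs, including seed, give byte-identical
outputs; each generator draws from its own seed-derived stream so outputs do
not depend on call order):

* **Codon alignments** — per codon, positions 1–2 are G/C with the taxon's
  target probability, position 3 uniform; no substitution model, no
  phylogenetic correlation.  The bias gene set spreads per-gene dispersion
  uniformly on [0, 0.3] and emits a dN digest correlated with it (the
  empirical pattern that fast-evolving genes are also the most
  composition-biased).
* **Phyletic profiles** — 0/1 states evolved root-to-leaves (root presence
  0.5) with at most one gain/loss per branch per family and a complete event
  log.  Default rates 0.05/branch emulate a turnover-rich data set; see
  above for why recovery validation uses lower rates.
* **Kinase hit tables** — six fixture classes covering every classifier
  branch: intact K/D/D; alanine at exactly one catalytic column; a domain
  split into two overlapping fragments that jointly cover the model and
  jointly carry KDD; and a fragmented domain whose model gap removes
  catalytic columns.  Emitted as domtblout plus a companion alignment TSV,
  exactly as the readers expect.
* **Architecture fixtures** — proteins with optional signal peptide, 0–3 TM
  helices, and tandem arrays drawn from a palette (defaults: Pkinase ×1,
  TPR 1–15, WD40 1–19, mirroring the long bacterial receptor-kinase
  arrays); topology is emitted with explicit inside/outside labels
  consistent with the parity rule, and truth records every token's intended
  side and array length.

What passing against these fixtures does **not** show: robustness to real
profile-search artefacts (inserts in the alignment register, envelope/model
coordinate disagreement, heterogeneous bitscores), to topology predictors
that disagree with domain annotations, or to alignment error in real codon
alignments.  The generator's sequences are i.i.d. apart from the controlled
composition; no claim is made about behaviour under phylogenetic
autocorrelation of composition.

## Validation problem sizes

The shipped validation suite runs at desk scale, chosen so the full suite
completes in a few minutes on one core: the Wagner oracle enumerates all 53
rooted shapes with ≤6 leaves × all count assignments in {0,1,2} (≈55k
instances) against brute-force enumeration; flux recovery uses 5 seeds ×
500 families on 12-taxon trees; the kinase classifier is scored on 3,600
labelled proteins and 1,000 random fragment splits; topology/parity checks
run on 1,000 generated proteins.
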