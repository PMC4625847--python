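# Methods

This note documents the statistical definitions, conventions and design
choices behind `mlstpop`, in the order the pipeline applies them.

## Data model

An MLST dataset is a complete rectangular matrix: every isolate carries
exactly one gap-free, equal-length sequence fragment at every locus.
Fragments are assumed pre-aligned (they come from conserved housekeeping
genes amplified with fixed primers); sequences of unequal length can be
right-trimmed to the shortest observed (`trim_to_shortest`), but no indel
alignment is attempted. Coordinates are 0-based half-open everywhere.

`N` is accepted on input. Every statistic that compares sequences excludes
N-containing positions *pairwise*, never listwise: a site is dropped only
for the pairs in which one member has `N` there. Allele calling is the one
exception — sequences containing `N` are catalogued as distinct literal
strings, which is conservative (it can split but never merge alleles).

Reading frames of coding fragments are auto-detected per locus as the
offset (0/1/2) yielding zero internal in-frame stop codons across all
distinct sequences, ties broken toward 0. Amplified fragments rarely start
on a codon boundary, so this is inferred rather than configured.

## Typing

Distinct sequences at a locus are alleles, numbered densely 1..K in
first-observation order; the allele vector across loci is the ST. Isolates
are scanned in lexicographic ID order, so allele and ST numbers are a pure
function of the dataset content. Published ST labels from other studies are
reproducible only up to relabeling (their numbering reflects historical
processing order), so cross-study comparisons should use counts and
partitions, not labels.

## Clonal complexes and founders

With L loci, STs sharing at least `group_threshold` alleles are linked
(default L−1: single-locus variants, the eBURST convention generalized from
the classic 6-of-7 default to 7-of-8 here). Complexes are the connected
components with ≥ 2 STs, labelled CC1, CC2, … by descending isolate count
(ties: more STs, then smaller minimum ST number). The founder of a complex
is the member maximizing the within-complex SLV count — the genotype a
radial expansion would place at the hub — with ties broken by DLV count,
then isolate count, then smallest ST number; the deciding tie-break level
is reported.

The minimum spanning tree is built on the complete graph of STs weighted by
allelic distance (number of differing loci), via a Kruskal scan sorted by
(weight, tie-key). Among equal-weight edges the tie-key prefers endpoints
with larger summed SLV counts, then larger summed isolate counts, then the
lexicographically smaller ST pair. This goeBURST-inspired rule is fully
deterministic; the commercial tool that popularized profile MSTs does not
publish its tie-breaks, so topologies can differ among equal-weight trees
(total weight cannot). Edges are annotated with the conventional rendering
classes (distance 1 bold, 2 thin, 3 dotted, > 3 suppressed in display
only).

## Diversity statistics

Computed over all isolate sequences by default (an ST-deduplicated mode
exists): frequencies matter, so π over isolates weights shared genotypes
naturally.

- **Polymorphic sites**: ≥ 2 distinct non-N characters at the site.
- **π**: plain mean over unordered pairs of (differences at mutually non-N
  sites / comparable sites). No n/(n−1) small-sample correction, matching
  the "two randomly selected isolates" definition.
- **G+C%**: pooled over all non-N bases of all sequences.
- **sSNP/nSNP**: for each polymorphic site, all observed full codons
  covering it are compared; a pair differing only at that site labels the
  site synonymous (same amino acid) and/or nonsynonymous (different, or
  involving a stop). One site may carry both labels, so sSNP + nSNP can
  exceed the polymorphic-site count. Sites in incomplete terminal codons
  are skipped with a warning.
- **dN/dS**: Nei–Gojobori (1986). Potential synonymous sites per codon are
  the per-position fractions of synonymous single-base changes (changes to
  stop codons count as nonsynonymous); observed differences average equally
  over minimal mutational pathways for codons differing at 2–3 positions,
  discarding pathways through stops unless all are blocked; per-pair
  proportions p = Sd/S̄, Nd/N̄ get the Jukes–Cantor correction
  d = −(3/4)·ln(1 − 4p/3) (`dnds_correction="none"` disables it, the
  p-distance variant some tools use); dN and dS are means over pairs.
  Pairs with p ≥ 3/4 are saturated and dropped with a warning. dN = 0
  reports a ratio of 0; dS = 0 with dN > 0 reports the ratio as undefined
  rather than a number. This implementation agrees with an independent
  published implementation to 1e−9 on random codon pairs (see the test
  suite). The concatenated table row reports summed SNP counts but no
  pooled dN/dS: loci have independent reading frames, and a ratio of
  averaged rates across genes under different constraint is not
  interpretable as a single selection estimate.

## Linkage disequilibrium

For n profiles at L loci, V_D is the population variance (denominator =
number of pairs) of the n(n−1)/2 pairwise allelic mismatch counts. Under
inter-locus independence the expected variance is V_e = Σ_j h_j(1 − h_j)
with h_j = (n/(n−1))(1 − Σ_i p_ij²), the unbiased (LIAN) convention;
`h_bias="biased"` drops the n/(n−1) factor, since published values do not
always state which was used. I_A = V_D/V_e − 1 and I_A^S = I_A/(L−1).
The default unit of analysis is all isolates, with a unique-ST mode.

Significance: each locus's allele column is permuted independently across
profiles (preserving allele frequencies, destroying associations);
p = (1 + #{permuted V_D ≥ observed})/(1 + n_perm), the +1 guard avoiding
p = 0 artifacts. Default 1000 permutations, seeded.

## Phylogeny and splits

K2P distance: d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q) with P, Q the
transition/transversion proportions over mutually non-N sites; a
non-positive logarithm argument raises a saturation error naming the pair.

Neighbour joining follows Saitou–Nei with the standard Q criterion; ties
in pair selection go to the smallest taxon-index pair; negative branch
length estimates are clamped to 0 with the deficit moved to the sibling
branch. Trees are built on ST representatives (one leaf per ST), matching
standard practice for concatenated MLST phylogenies. Bootstrap support
resamples alignment columns with replacement, rebuilds K2P + NJ per
replicate, and reports the percentage of replicates containing each
internal bipartition; taxa are canonically sorted before resampling so
supports do not depend on input order. Replicate count is configurable
(pipeline default 100; 1000 is conventional when runtime is no concern).

Split decomposition (Bandelt–Dress): a bipartition A|B is a d-split when
its isolation index
α = ½·min_{i,j∈A; k,l∈B} [max(d_ik+d_jl, d_il+d_jk, d_ij+d_kl) − d_ij − d_kl]
is positive. Splits are found incrementally — adding one taxon at a time,
extending each current split both ways plus the new trivial split, and
rechecking α — which is valid because restrictions of d-splits are
d-splits; an exhaustive mode (n ≤ 12) serves as oracle. α values within
1e−9 of zero are treated as zero so the two modes resolve borderline
splits identically. Trivial splits are always retained; a display
threshold on α is exposed (default 0). The fit index is the percentage of
the total pairwise distance represented by the split metric (100 for
additive matrices). The incremental search costs O(n⁴) per candidate
split, so the pipeline restricts split decomposition to the 20 most
populous STs by default (`splits_max_taxa`); incompatible (pairwise
crossing) split pairs are counted as the recombination signal.

## Synthetic populations

The generator emulates a housekeeping-gene MLST study of a clonal
bacterium. Defaults: 186 isolates; 8 coding loci named and sized like a
typical eight-gene scheme (443–620 bp, total 4030 bp); 10 founder
lineages; mutation 1e−5 per site per generation; transition/transversion
ratio 2; recombination 0.01 per isolate per generation; 10 generations;
founders pairwise diverged at ~2% of sites with at least one difference
guaranteed per locus (so founder STs differ at every locus).

Mechanism: founders are random in-frame coding sequences with no internal
stops; the first `n_founders` isolates are exact founder copies; each later
isolate copies a uniformly chosen earlier isolate of the same lineage and
undergoes `generations` rounds of per-site mutation (substitutions drawn
transition-first at titv/(titv+1), a coding guard rejecting substitutions
that would create in-frame stops). After the population is complete,
`generations` rounds of whole-locus recombination run population-wide:
per round, each isolate with probability `recombination_rate` replaces one
uniformly chosen locus by that locus from a uniformly chosen other
isolate's current state. Recombination is whole-locus by design — MLST
linkage statistics operate at allele granularity, and whole-locus exchange
is exactly the "free recombination between alleles" regime the linkage
tests probe; intragenic breakpoints are out of scope.

Everything is driven by a single seeded RNG stream; the seed is recorded
in all outputs. Every mutation and recombination event is logged with
enough context that replaying the log from the founder sequences
reproduces the emitted dataset bit-for-bit (tested).

What the simulator does *not* emulate: selection, demography, coalescent
genealogies, intragenic recombination, sequencing error, or the base
composition and codon usage of any real genome. Passing tests on synthetic
data therefore demonstrate correctness of the statistics and the
recoverability of planted structure under the stated model — not that real
populations of any particular species satisfy that model.

### Simulation-based validation conditions

Two standing checks use fixed conditions chosen from the model's analytics:

- **Founder-partition recovery**: 60 isolates, 3 founders, mutation 5e−6
  per site per birth, one generation, no recombination. At this rate the
  expected number of mutations per birth is ≈ 0.02, so the probability
  that a single birth hits two different loci (the only event that can
  detach an isolate from its lineage's SLV chain, since every parent is in
  the sample) is ≈ 1e−4; founders differ at all 8 loci, so SLV links
  cannot bridge lineages. The SLV components then equal the planted
  partition in essentially every replicate.
- **Linkage decay**: mutation 2e−4 with 3 generations gives rich
  polymorphism and strong baseline linkage (I_A^S ≈ 0.4); sweeping
  recombination over {0, 0.1, 0.3, 0.6, 1.0} drives I_A^S toward 0, and
  the Spearman correlation between rate and I_A^S across 5 × 20 runs is
  strongly negative (ρ ≈ −0.97).

## Numerical conventions and degenerate inputs

- Allelic distances and MST weights are exact integers; all tie-breaks are
  total orders, so every pipeline output is a pure function of (input,
  seed).
- Monomorphic data: I_A is undefined (V_e = 0) and reported as such, never
  as a number; the pipeline records nulls and continues.
- A single ST degrades the MST to one node (warning), the NJ tree to a
  single-leaf newick, and the split system to the empty set.
- π pairs with zero comparable sites are excluded with a warning; if all
  pairs are excluded the statistic is an error.
- Profile export uses the PubMLST-style tab dialect (`ST`, one column per
  locus, `count`); member identities are not part of that dialect, so
  round-trip equality is defined on catalogs, profiles and counts.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute
and the end-to-end reproduction script in a few minutes on one CPU: the
study-scale run uses 186 isolates, 1000 permutations, 100 bootstrap
replicates and split decomposition on 20 taxa; oracle-equivalence checks
use ≥ 200 random instances of ≤ 20 sequences / ≤ 8 taxa / ≤ 7 STs, where
exhaustive enumeration is feasible.

## Known limitations

- eBURST founder bootstrap confidence is not implemented (founder choice
  is reported with its tie-break trace instead).
- No intragenic recombination detection, no Bayesian population structure,
  no recombination/mutation rate ratio estimation — the linkage and split
  statistics summarize recombination signal but do not estimate rates.
- The MST is one minimum-weight tree among possibly many; only its total
  weight is unique.
- NJ is distance-based; no likelihood or Bayesian tree inference.
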