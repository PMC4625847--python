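# mlstpop

Multilocus sequence typing (MLST) and clonal population structure analysis
for bacterial isolate collections, built for housekeeping-gene schemes such
as the eight-locus scheme used for *Lactobacillus plantarum* (fragments of
*clpX, groEL, murC, murE, pheS, pyrG, recA, uvrC*, 415–641 bp each).

MLST types each isolate by the combination of alleles it carries at a small
set of conserved gene fragments: every distinct nucleotide sequence at a
locus is an allele, and the vector of allele numbers across loci is the
sequence type (ST). From the ST table and the underlying sequences the
package answers the classic population-biology questions — how clonal is
the population, which genotypes founded its clonal complexes, how much
recombination blurs the clonal signal — using the field's standard
statistics:

- **Clonal complexes (eBURST rule):** STs sharing ≥ L−1 of L alleles are
  linked; connected components are complexes, and each complex's founder is
  the member with the most single-locus variants (SLVs), with documented
  tie-breaks. A minimum spanning tree over allelic distances gives the
  profile-level overview.
- **Diversity (per locus and concatenated):** polymorphic sites, nucleotide
  diversity π (mean pairwise differences per site), G+C%, synonymous and
  nonsynonymous SNP sites, and the Nei–Gojobori (1986) dN/dS with
  Jukes–Cantor correction.
- **Linkage disequilibrium:** index of association
  I_A = V_D/V_e − 1 and its standardized form I_A^S = I_A/(L−1), with a
  locus-permutation significance test. Both are ≈ 0 under free
  recombination and positive under clonality.
- **Phylogeny:** Kimura two-parameter distances, neighbour-joining trees
  with column-bootstrap support, and Bandelt–Dress split decomposition —
  incompatible splits (network boxes, isolation index α > 0) are the
  classic signature of recombination.
- **Synthetic populations:** a seeded clonal-descent simulator (point
  mutation with transition/transversion weighting, whole-locus
  recombination, planted founder lineages) with a complete, replayable
  event log, so every analysis stage can be validated against ground truth.

## Worked example

```python
import mlstpop as m

cfg = m.SimConfig(n_isolates=40, n_founders=3, mutation_rate=1e-4,
                  recombination_rate=0.05, generations=5, seed=11)
dataset, truth = m.simulate_population(cfg)
table = m.assign_profiles(dataset)
print("isolates:", dataset.n_isolates, " loci:", len(dataset.loci),
      " STs:", table.n_sts)

complexes, singletons = m.find_clonal_complexes(table)
print("clonal complexes:", len(complexes), " singletons:", len(singletons))
for cc in complexes:
    print(f"  {cc.id}: {len(cc.member_sts)} STs, {cc.n_isolates} isolates,"
          f" founder ST{cc.founder_st} ({cc.slv_counts[cc.founder_st]} SLVs)")

rows = m.diversity_report(dataset, table)
r = rows[-1]
print(f"concatenated: {r.length_bp} bp, {r.n_polymorphic_sites} polymorphic"
      f" sites, pi = {r.pi:.5f}, G+C = {r.gc_percent:.2f}%")

stats = m.permutation_test(table, n_perm=1000, seed=11)
print(f"I_A = {stats.i_a:.4f}, I_A^S = {stats.i_a_s:.4f},"
      f" p = {stats.p_value_ia:.4f}")
```

prints

```
isolates: 40  loci: 8  STs: 32
clonal complexes: 3  singletons: 23
  CC1: 5 STs, 7 isolates, founder ST5 (3 SLVs)
  CC2: 2 STs, 3 isolates, founder ST12 (1 SLVs)
  CC3: 2 STs, 2 isolates, founder ST4 (1 SLVs)
concatenated: 4030 bp, 209 polymorphic sites, pi = 0.01918, G+C = 52.00%
I_A = 3.0517, I_A^S = 0.4360, p = 0.0010
```

Forty isolates from three founder lineages resolve into 32 STs; the three
planted lineages surface as the three clonal complexes, each founder being
the ST with the most single-locus variants. I_A^S well above zero with a
permutation p of 0.001 correctly reports the population as clonal: the
modest locus-swap rate (0.05/isolate/generation) has not erased the linkage
between loci.

## Command line

Every stage is also a subcommand operating on a directory of per-locus
FASTA files (`<locus>.fasta`, record IDs = isolate IDs) plus an optional
`metadata.tsv`:

```sh
mlstpop simulate --outdir data --n-isolates 40 --n-founders 3 --seed 11
mlstpop type     --input-dir data --outdir profiles
mlstpop eburst   --input-dir data --out clonal_complexes.tsv
mlstpop linkage  --input-dir data --out linkage.json --seed 11
mlstpop all      --config run.yaml     # the full pipeline
```

`mlstpop all` writes the PubMLST-style profile table, per-locus allele
FASTAs, the clonal-complex table, the MST (GraphML/DOT), the diversity
table, the linkage JSON, the NJ tree (newick, bootstrap as internal node
labels), K2P distances (PHYLIP) and the split system (NEXUS), plus a run
manifest sufficient to reproduce the run bit-for-bit.

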