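# matsys

Budding yeast species differ widely in how their cells decide to mate. The
genotype at the mating-type (*MAT*) locus — the **a** or **α** idiomorph —
determines cell type, but whole lineages have repeatedly rebuilt the system
around it: some species are heterothallic (two stable haploid mating
types), some switch mating type by copy-and-paste between an active *MAT*
locus and silent cassettes (*HML*/*HMR*), some switch by inverting a
chromosomal segment between inverted repeats, and some carry both
idiomorphs permanently with no switching machinery at all.

`matsys` is a toolkit for the two analyses this question requires:

1. **Classification.** Given a genome assembly, infer the species'
   mating-compatibility system as one of seven categories:

   | category | meaning |
   |---|---|
   | `HET`  | heterothallic (one idiomorph, or a diploid assembly with two allelic loci) |
   | `3LOC` | three-locus switching (*MAT* + silent cassettes, direct X/Z repeats) |
   | `FF1`  | flip/flop switching by inversion, one set of inverted repeats (IRs) |
   | `FF2`  | flip/flop switching, two sets of IRs |
   | `PHC`  | primary homothallism, *MAT***a** and *MAT*α contiguous (< 20 kb) |
   | `PHN`  | primary homothallism, non-contiguous loci, no nearby repeats |
   | `NOMAT`| no recognizable *MAT* gene |

   The classifier works from translated homology search (a TBLASTN-style
   six-frame search honouring the CUG-Ser and CUG-Ala nuclear codes,
   retaining even very weak hits at E < 10), intact/fragment/pseudogene
   gene calls, inverted- and direct-repeat detection around the loci,
   telomere and rDNA context, allelism tests between opposite-idiomorph
   contigs, and the coverage signature of repeats collapsed by short-read
   assemblers (a contig at ~2× median coverage sharing exact *k*-base end
   overlaps with its neighbours).

2. **Transition inference.** Given a rooted species tree and per-species
   categories, reconstruct ancestral states by Fitch/Sankoff parsimony,
   enumerate most-parsimonious reconstructions (MPRs), resolve ties by
   explicit policies, and count transitions between systems — including
   the number of independent origins of mating-type switching (branches
   entering {FF1, FF2, 3LOC} from outside).

A seeded synthetic-genome generator plants each of the seven
configurations (IRs of controlled length and identity, telomeric tandem
arrays, rDNA arrays, assembler-collapse emulation) so that the whole
pipeline is testable without any downloads, and curated clade fixtures
(Lipomyces, Ogataea, Saccharomycetaceae, Saturnispora, the PHN clades, and
a condensed backbone of all switching clades) make the headline survey
numbers reproducible.

## Worked example

Classify a planted flip/flop genome and run the transition stage on the
Lipomyces fixture:

```python
from matsys import (PlantedGenomeSpec, generate_genome, classify_assembly,
                    clade_fixture, reconstruct_states, count_transitions)
from matsys.synthetic_data import toy_queries

asm, truth = generate_genome(PlantedGenomeSpec(category="FF1", seed=1))
call, evidence = classify_assembly(asm, toy_queries())
print(call.category, call.evidence)

fx = clade_fixture("lipomyces")
rec = reconstruct_states(fx.tree, fx.states)
print(rec.resolved[fx.tree.root.index], count_transitions(rec).counts)
```

prints

```
FF1 ['rule1:loci=2', 'rule2:both_idiomorphs', 'rule3:verdicts=non_allelic',
     'rule4:cassettes=2(intact=2,silent_frag=0)',
     'rule5:ir_families=1,collapsed_links=0,unoriented_families=0,artifact=false']
PHC {('PHC', 'PHN'): 2, ('PHC', 'HET'): 1}
```

The evidence list is the audit trail of the decision cascade: two loci
with both idiomorphs, not allelic, fewer than three cassettes, and exactly
one inverted-repeat family spanning them — the FF1 signature. The
Lipomyces reconstruction resolves the genus root to contiguous primary
homothallism (PHC) with two transitions to PHN and one reversal to
heterothallism.

The same stages are available from the shell:

```sh
matsys simulate --category FF2 --seed 7 --out scratch/ff2
matsys classify --assemblies scratch/ff2 --queries src/matsys/data/toy_queries.faa --out scratch/run
matsys transitions --tree tree.nwk --states calls.tsv --policy prefer_gains --out scratch/tr
matsys fixtures --name lipomyces
```

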