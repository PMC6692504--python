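# Methods

## Scope and model

`matsys` automates a two-stage comparative-genomic analysis of mating
compatibility in budding yeasts. Stage one assigns each genome assembly to
one of seven categories of mating-compatibility system from the content
and context of its canonical *MAT* genes (**a**1, **a**2, α1, α2). Stage
two treats the category as a seven-state character on a rooted species
tree and reconstructs its evolutionary history by parsimony. Parsimony
(rather than a likelihood model) is appropriate here because transitions
are rare relative to the number of species and there is no principled way
to weight transition probabilities between the systems a priori; branch
lengths are therefore ignored throughout.

## Translated homology search

*MAT* idiomorph proteins diverge quickly, so the search stage is built to
be permissive and to be run with several query sequences per gene. Each
contig is translated in six frames with an exact residue-to-genome
coordinate map; the CUG-Ser and CUG-Ala clades' reassignment of the CTG
codon is honoured by selectable code tables. Queries are matched by exact
4-residue seeding, seeds are clustered by diagonal, and candidate windows
are scored by Smith–Waterman local alignment (BLOSUM62, gap open 11,
extend 1, via Biopython's C aligner). Raw scores are converted to E-values
with the Karlin–Altschul form E = K·m·n·exp(−λS), K = 0.041, λ = 0.267,
n = 6 × assembly length, so the retention rule E < 10 has its familiar
meaning; all four constants are configurable. Hits of one query on one
contig and strand are chained across genomic gaps ≤ 1,500 bp before
coverage is computed, so intron- or frameshift-split HSPs are judged as
one gene. Seeded search is a heuristic: a region with no exact 4-mer match
to any query is invisible, which for strongly diverged real *MAT* genes is
mitigated by using diverse query sets, not by the bundled toy set.

## Gene calls and loci

Intactness is a total function of chained query coverage and internal stop
codons: coverage ≥ 0.80 with no stops is `intact`; ≥ 0.80 with stops is
`pseudogene`; anything else is `fragment` (typically a gene piece
duplicated into a repeat). The 0.80 bound tolerates diverged termini while
excluding repeat-embedded pieces; it is a package decision, not an
empirical constant. A single intact **a** gene (or a single α gene) is
enough to call a *MAT***a** (*MAT*α) locus — requiring both genes of a
pair would misclassify the many real loci that have lost one. Intact *MAT*
genes within 8 kb on one contig form one locus; signed distances to the
nearest intact SLA2/DIC1/APN2 calls and telomere/rDNA/contig-end context
are attached.

## Repeats, telomeres, allelism, coverage links

Repeat detection compares 50-kb windows around loci in both orientations
(24-mer seeding, diagonal clustering, edit-distance refinement with
edlib), reporting pairs ≥ 200 bp at ≥ 90% identity — brackets chosen to
span the observed real repeat scales (a 213-bp repeat at 100% down to
multi-kb IRs at 97%). Inverted pairs near loci are IR candidates (flip/flop
geometry); direct pairs are X/Z-like (copy-and-paste geometry). Telomeres
are maximal tandem arrays with unit length 5–30 bp and ≥ 3 copies starting
within 2 kb of a contig end, detected by self-periodicity so the result is
invariant to the rotation phase of the unit; the unit is reported in
canonical (lexicographically minimal) rotation. Allelism between
opposite-idiomorph loci requires near-identical (≥ 95%) shared flanks of
500 bp on *both* sides; one side shared is `ambiguous`. Collapsed-repeat
inference flags contigs at 1.6–2.6 × the length-weighted *median*
coverage (the median resists the inflated upper tail that collapsed
repeats themselves create) sharing exact k-base end overlaps (default
k = 55) with ≥ 2 other contigs. Very long (≥ 50 kb) near-perfect
(≤ 3 mismatches) IRs whose copies run out to contig ends are flagged as
likely assembler artifacts: short-read data cannot support resolving such
a repeat, so its assembled length is untrustworthy — the IR evidence is
kept but the call is marked provisional.

## Classification cascade

Rules fire in a fixed order and every gate is recorded in the evidence
trail: (1) no intact *MAT* gene → NOMAT; (2) one idiomorph → HET
(haploid); (3) both idiomorphs, all opposite pairs allelic → HET (diploid
assembly); (4) ≥ 3 cassettes, counting repeat-associated silent fragment
cassettes → 3LOC; (5) inverted-repeat evidence: one family → FF1, two or
more → FF2; (6) otherwise primary homothallism, PHC below a 20-kb gap,
PHN above it or across contigs. Repeats trump distance: a repeat-linked
pair of loci is never PHC/PHN. Three evidence types count toward rule 5:
literal inverted pairs, collapsed-coverage links, and same-strand
cross-contig repeat families flanking the loci (whose true orientation is
unknowable across a contig break) — the last excluded when a copy is a
degraded pseudogene, because a decayed duplicate marks an old
introgression (a PHN signature), not functional switching machinery.
Fragment cassettes count toward rule 4 only when the fragment covers
≥ 40% of its query and sits immediately beside an X/Z copy or inside a
collapsed repeat contig; chance alignments retained by the permissive
E-threshold stay below that bar. Calls are provisional when the repeat
topology is under-determined (loci on unlinked contigs without orientation
evidence, or artifact-flagged IRs).

## Parsimony stage

Reconstruction uses the Sankoff dynamic programme (with uniform 0/1 costs
it reduces exactly to Fitch parsimony; an arbitrary cost matrix may be
supplied). Candidate sets reported per node are MPR-membership sets
(states attaining the global minimum in at least one reconstruction),
computed by a down-pass/up-pass pair. The default resolution keeps the
parent's state whenever it is locally optimal and otherwise falls back to
a fixed priority (HET, PHC, PHN, FF1, FF2, 3LOC, NOMAT) — encoding the
repeated observation that derived systems arise from heterothallic
ancestors — and provably yields an MPR. The `prefer_gains` policy selects,
among all MPRs, one maximizing gain events (HET → non-HET), breaking ties
by fewest losses; it is implemented as a lexicographic-tuple Sankoff
recursion (lexicographic order is compatible with addition, so the
recursion stays exact at any tree size) and is the policy under which the
three-origins reading of the Ogataea flip/flop clades is selected over the
equally parsimonious one-gain-two-losses reading. MPR enumeration
backtracks over locally optimal child states (complete for tree-additive
objectives) and is guarded by a tip-count cap, raisable for condensed
clade trees. NOMAT is a seventh character state by default; a flag treats
unmapped tips as missing data instead. Transition counting emits one event
per branch with differing endpoint states; switching origins are events
entering {FF1, FF2, 3LOC} from outside.

## Synthetic genomes and fixtures

The generator plants each category's geometry into seeded 40% GC random
background DNA: cassettes built from bundled toy proteins
(reverse-translated with a fixed codon choice that avoids CTG, so planted
genes read identically under all three nuclear codes; the toy proteins
are mutually < 30% identical so query cross-hits cannot confound tests);
IRs default to 2 kb at 97% identity; invertible spans default to 14 kb —
a deliberate scale-down from the > 100-kb real flip/flop regions, since
the classifier consumes geometry, not absolute span length; telomeres use
an 11-bp unit seen at real yeast chromosome ends; the PHN genome places
the novel cassette beside an SLA2 pseudogene near a telomere array (or
beside an rDNA array in the variant); the 3LOC genome uses 700-bp X and
250-bp Z direct repeats. Collapse emulation replaces the two IR copies
with one consensus contig at 2× baseline coverage and exact k-base end
overlaps, breaking the inter-copy span so each cassette lands on its own
contig (five contigs from one). What the generator does *not* emulate:
sequencing error, real evolutionary divergence of *MAT* genes from the
queries, genome-wide repeat families, or fragmented low-coverage
assemblies — so passing tests demonstrate the correctness of the decision
logic on clean evidence, not search sensitivity on hard real genomes.

The curated clade fixtures transcribe per-clade species lists, categories
and clade memberships for the documented groups (Lipomyces, the Ogataea
genus clade, Saccharomycetaceae, Saturnispora, the twelve PHN clades, and
a condensed backbone containing every switching clade with its
heterothallic context). Where a source constrains only clade membership
and not the internal branching order, the fixture uses an arrangement
consistent with the documented transition scenario; species in large
uniform genera are represented by documented members. The backbone marks
the one provisional FF2 species, so switching origins are reported both
with (12) and without (11) it. The full 332-species data set is
deliberately not bundled; the `full` fixture tag accepts a user-supplied
transcription.

## Numerical and degenerate-input choices

Internal coordinates are 0-based half-open everywhere; conversion to
1-based inclusive happens only at the GFF3 boundary. N runs are excluded
from repeat seeding and telomere periodicity so assembly gaps cannot
create spurious repeats. Ties in gene calling resolve by highest bit
score; duplicate repeat pairs found from two windows or in mirrored order
are suppressed by containment. Empty inputs raise (`empty assembly`) or
return empty collections as documented per operation; a species with no
loci classifies NOMAT only if the search stage actually ran. All
randomness flows from explicit integer seeds; identical spec + seed gives
byte-identical assemblies and pipeline outputs.

## Problem sizes

The bundled test and acceptance runs use planted genomes of roughly
40–80 kb, 20 seeds per category in the test suite and a smaller per-seed
sample in the acceptance script, 50 random ≤ 7-tip trees against a
brute-force parsimony oracle, and the curated fixtures (9–71 tips). These
sizes were chosen as the smallest at which every decision gate and both
reconstruction policies are exercised.

## Known limitations

Cross-species synteny rescue — classifying a broken assembly by gene
order in a close relative — is not automated; such species take manual
override entries, as do any curator decisions. The E-value calibration is
the standard closed form, not simulation-calibrated for this search
space. Allelism flank comparison assumes co-oriented assemblies. Repeat
role assignment is purely geometric (orientation + proximity) and does
not attempt to identify functional X/Z boundaries. Tetrapolar systems and
silencing genetics are out of scope.
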