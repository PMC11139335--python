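# Methods

## Intron coordinates

The canonical key for an intron position is its **coding offset**: the
number of coding nucleotides strictly upstream of the intron in the
spliced CDS. Codon index and phase are derived views, never stored
independently, which removes boundary ambiguity: `phase = offset mod 3`;
for phase 0 the codon index is `offset/3` (the intron sits *between* this
codon and the next — reported as "between codon i and i+1"); for phase
1/2 it is `floor(offset/3) + 1` (the interrupted codon). Offsets at the
extreme CDS ends (`< 1` or `> L−1`) are invalid. GFF3 coordinates
(1-based inclusive) are converted on parse to 0-based half-open
intervals; all reported codon indices and alignment columns are 1-based.

Genes whose CDS length is not a multiple of 3, or that contain in-frame
internal stops, are **excluded with a warning, never repaired**: silent
repair would fabricate structures for exactly the dubious genes the
filtering stages exist to remove. When a gene has several annotated
transcripts the longest CDS is used. Only CDS features are considered;
UTR exons never contribute coordinates.

## Ortholog classes from shared positions

Introns are lifted onto a protein multiple alignment (the column of the
codon-index residue, counting non-gap characters) and partitioned by the
exact pair `(column, phase)`. Matching is exact — no sliding-tolerance
window — because positional sliding is rare and phase changes essentially
unobserved; phase is precisely what separates a phase-0 intron at the
codon-50/51 boundary from a phase-2 intron inside codon 57 one column
away. Class ids follow the `column.phase` convention (e.g. `111.1`).
A gene sharing at least one of a reference variant's classes is called a
putative ortholog; sharing some but not all is flagged per missing class
(lost introns in multi-intron variants).

Alignment production is pluggable. Real analyses should supply an
external aligned FASTA (MAFFT, CLUSTAL, ...). The internal aligner —
progressive Needleman–Wunsch/Gotoh over a growing profile, BLOSUM62, gap
open −10 / extend −1, ties broken toward the diagonal, sequences added in
lexicographic id order — exists to make simulated and fixture data
alignable deterministically. Its DP is banded (±15 columns plus the
length difference), which is exact for the near-equal-length families it
serves; it is not a general-purpose aligner.

## Protosplice scoring

New introns insert preferentially at the exonic consensus `AG|GT`. For a
candidate insertion point (the homologous coding offset in an intronless
paralog, mapped through the alignment and declared unmappable if the
target is gapped at that column), the flanking 4-mer is the 2 nt upstream
plus 2 nt downstream. Positional matches against `A,G,G,T` are counted,
and **signal** is called when either flanking dinucleotide matches
exactly (upstream `AG` or downstream `GT`). This rule reproduces the
three canonical qualitative calls: `CA|GT` → signal, `AG|GC` → signal,
`CT|GG` → none. The 2+2 window is fixed by the consensus definition; no
wider context is examined.

## Dollo reconstruction

An intron-position class (or variant gene) is modelled as a Dollo
character: gained exactly once, only lost thereafter — appropriate
because the joint event "same column, same phase, independent second
gain" is vanishingly unlikely. Under single gain the parsimony optimum is
closed-form:

- **origin** = MRCA of the species carrying the character (any deeper
  origin only adds losses);
- **losses** = maximal subtrees inside the origin clade whose sampled
  species all lack it; each counts once regardless of size. Under a
  multifurcation, each entirely-absent child subtree is one loss.

Species scored **unknown** (no annotatable homolog at all) are excluded
from the loss count and reported as "possible loss or annotation
failure"; a second pass treating unknowns as absent gives the upper
bound. Reports therefore carry both `n_losses` and `n_losses_upper` —
the "some 5 times" vs "up to six" pair. An all-absent character is an
error: there is nothing to place.

A consequence worth stating: when every carrier below one child of the
true birth node is lost, the birth node itself is unidentifiable to any
single-gain method — the MRCA of surviving carriers is the best
obtainable answer, and it is what this package returns. The parameter-
recovery suite scores origin inference against that identifiable origin.

## Fitch ancestral states, differences, concerted evolution

Single-column ancestral states use standard Fitch parsimony
(intersection-else-union bottom-up; deterministic top-down assignment
preferring the parent's state, ties to the lexicographically smallest).
Unknown tips take the full observed state set. On multifurcating nodes
children are folded pairwise in order; the minimum-mutation guarantee
(and the enumeration oracle it is tested against) applies to binary
trees. Pairwise difference enumeration reports 1-based positions and
percent identity over columns where both sequences have residues.

The concerted-evolution screen splits the alignment at an intron class
(columns ≤ the class column form exon 1; a phase-1/2 interrupted codon
goes with exon 1), builds per-exon trees, and asks per species whether
the two paralogs form a **cherry** (share a parent whose children are
exactly those two leaves) — "together" indicates homogenization by gene
conversion, "apart" ordinary orthologous descent. Support values are
ignored; the call is purely topological. The bundled neighbor-joining
utility (classic Q-criterion, ties broken by lexicographic label pair,
negative branch lengths retained) exists to build small deterministic
trees for this screen and for tests; model-based phylogenetics is out of
scope.

## Assembly-quality test

To ask whether inferred losses merely track poor assemblies, a one-tailed
Welch (unequal-variance) t-test compares loss vs non-loss species in the
direction that would indict quality: lower BUSCO completeness (`less`)
and more missing genes (`greater`). The statistic, Welch–Satterthwaite
degrees of freedom and one-tailed p come from `scipy.stats.ttest_ind`;
the test suite pins them to the textbook closed form at 1e-12. Degenerate
inputs (n < 2, both variances zero) are errors; identical groups give
t = 0, p = 0.5 exactly.

## Rescue scan

The six-frame rescue scan is a deliberately naive stand-in for a
translated homology search, used to ask whether an *unannotated* copy of
a gene hides in assembly sequence (the annotation-dropout scenario). It
translates every contig in all six frames, slides the query (callers
should pass the longest exon's peptide, ≥ 15 aa), scores ungapped
BLOSUM62 matches, suppresses hits within 30 codons of a better hit on the
same contig/strand/frame, and reports genomic intervals sorted by score.
It computes no e-values and finds no spliced matches; it is qualitative
by design.

## The simulator

`simulate_family` embodies the scenario the pipeline reconstructs.
Defaults (the study conditions; seed-deterministic throughout):

| parameter | default | meaning |
| --- | --- | --- |
| `n_species` | 32 | leaves of a simulated Yule tree (ultrametric, unit birth rate) |
| `intron_offset` | 150 | variant intron at the codon-50/51 boundary, histone-like |
| `n_codons` | 125 | ancestral protein length (H2A-sized) |
| `loss_prob_per_branch` | 0.1 | variant loss probability on each branch below the birth node |
| `substitution_rate` | 0.02 | expected substitutions/site per unit branch length |
| `variant_rate_multiplier` | 3.0 | variant lineages evolve faster, as fast-evolving variants do |
| `annotation_dropout_prob` | 0.0 | remove a variant from GFF3 but not the genome |
| `protosplice_bias` | true | place `AG\|GT` at the insertion point of the ancestral CDS |
| `intron_length` | 61 | `GT...AG` intron sequence |
| `flank` | 500 | random sequence flanking each gene's contig |

Substitutions are nucleotide-level Jukes–Cantor: each site changes with
probability ¾(1−e^(−4d/3)) for branch distance d = length × rate, with
substitutions that would create an in-frame stop resampled so every CDS
stays translatable. No indels are introduced in the default mode, so the
family's true alignment is the identity — which is what makes exact
truth-scoring of the projection and Dollo stages possible. What the
simulator therefore does *not* emulate: indel evolution and alignment
uncertainty, rate heterogeneity across sites, codon-level selection, GC
bias, fragmented assemblies, or mis-annotation subtler than whole-gene
dropout. Passing tests show the inference chain is correct when the
alignment is right; they do not certify robustness to alignment error on
real, indel-rich families.

The worked-example fixture (`make_worked_example_fixture`) is a fixed-seed
single-species emission with four genes: an intronless canonical gene
whose CDS embeds `AG|GC`, `CT|GG` and `CA|GT` at offsets 78, 170 and 150,
and three variants carrying single introns at those offsets (the 78 nt
first-exon gene on the minus strand to exercise strand handling).

## Problem sizes used in validation

The test suite validates Dollo against exhaustive single-gain
minimum-loss enumeration on every labeled topology with 4–5 leaves (all
presence patterns) plus seeded random topologies at 6–8 leaves (several
thousand cases total), Fitch against brute-force labeling enumeration on
trees up to 6 leaves and 4 states, projection properties on 1,000
randomized alignments, and parameter recovery on 50 seeded 32-species
simulations at the default loss and substitution rates. These sizes give
exhaustive coverage where enumeration is closed and dense sampling
elsewhere.

## Known limitations

- Homology search is pluggable, not reimplemented: the pipeline consumes
  precomputed tabular hits; fixture e-values are synthetic (no
  Karlin–Altschul statistics).
- The internal aligner and NJ utility are deterministic conveniences for
  test-scale data, not replacements for MAFFT/CLUSTAL or ML tree
  inference.
- Dollo reports cannot distinguish a true loss from a sequence so
  diverged that annotation and the rescue scan both miss it; the unknown
  category and the upper bound are the honest envelope, mirroring how
  fast-evolving variants blur loss calls in practice.
- No handling of trans-splicing, selenocysteine or non-standard genetic
  codes; one gene model per gene (longest CDS).
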