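# introntrace

Intron-position phylogenetic profiling for tangled gene families, built
around the histone H2A variant problem in *Caenorhabditis* nematodes.

## The problem

Histone variant genes (H2A.Z, the sperm-specific HTAS-1, the
near-core-identical HIS-35) are short, often nearly identical in protein
sequence to their multi-copy canonical paralog, and sometimes evolve so
fast that sequence trees cannot resolve their orthology. What does stay
put is **gene structure**: the position at which an intron interrupts the
coding sequence is essentially immutable — introns rarely "slide", and
never between phases. Two genes whose introns fall in the same protein
alignment column *and* the same phase almost certainly inherited that
intron from a common ancestral gene.

`introntrace` turns this observation into a pipeline:

1. **Annotate** — parse genome FASTA + GFF3, assemble each CDS, and record
   every intron as a *coding offset* (number of coding nucleotides strictly
   upstream). The derived views are the 1-based **codon index** and the
   **phase** `p = offset mod 3`: a phase-0 intron with offset 78 sits
   "between the 26th and 27th amino acid"; offset 170 is a phase-2 intron
   splitting codon 57.
2. **Filter** — reduce the candidate homolog set: drop proteins > 200 aa
   (histones are short), apply the similarity-search e-value cutoff
   (default 1e-10), and collapse records with identical protein sequence
   *and* identical intron offsets.
3. **Project & classify** — lift each intron onto a protein multiple
   alignment (external, or the built-in deterministic aligner for test
   data) and partition introns into `(column, phase)` equivalence classes.
   Genes sharing a reference variant's class are its putative orthologs.
4. **Reconstruct** — treat each intron class as a Dollo character on a
   species tree: it arises once (origin = MRCA of the species carrying it)
   and can only be lost. Independent losses are the maximal clades inside
   the origin clade with no carriers; species with no usable annotation
   ("?" species) are excluded from the count but reported in an upper
   bound — the "lost some 5 times ... up to six" style of statement.
5. **Corroborate** — score insertion sites against the protosplice
   consensus `AG|GT`; reconstruct single-column ancestral residues with
   Fitch parsimony; screen for concerted evolution by asking whether
   same-species paralogs form cherries in per-exon trees; and run
   one-tailed Welch t-tests of assembly quality (BUSCO completeness /
   missing) between loss and non-loss species to rule out the
   annotation-failure confound.

A seeded simulator (`synthetic_data`) generates the whole scenario —
canonical intronless gene, variant birth at a chosen tree node with a
novel intron (at an `AG|GT` site when requested), per-branch loss,
rate-multiplied variant divergence, annotation dropouts — and emits
FASTA/GFF3/Newick plus a truth record, so every stage is testable end to
end without any downloads.

## Worked example

The deterministic fixture reproduces the classic three-variant picture:

```bash
introntrace simulate --worked-example --out demo
introntrace annotate demo/celegans.fasta demo/celegans.gff3
```

```
>ce_h2a species=celegans introns=-
MASVVPPKFGNIRIVRLFERNWHRQKAQARKLQRRSQTLYYDVTTRTRWAVTLGTRLDVL...
>ce_his35 species=celegans introns=150:50.0
...
>ce_htas1 species=celegans introns=78:26.0
...
>ce_htz1 species=celegans introns=170:57.2
...
```

The header dialect is `introns=<coding_offset>:<codon_index>.<phase>`:
the HTAS-1-like gene has a phase-0 intron between codons 26 and 27
(offset 78), the H2A.Z-like gene a phase-2 intron inside codon 57
(offset 170), and the HIS-35-like gene a phase-0 intron between codons 50
and 51 (offset 150) — three distinct `(column, phase)` classes even
though two of them sit one residue apart.

Protosplice scoring of the HIS-35-like insertion point in the intronless
canonical gene:

```bash
introntrace protosplice core_cds.fasta --gene ce_h2a --offset 150
CA|GT	matches=2/4	signal=yes
```

A full run on a simulated 12-species family (config YAML pointing at the
genomes, the species tree, and the reference variant gene) prints the
stage bookkeeping and the reconstruction:

```
annotated_genes 22
after_length    22
after_collapse  22
intron_classes  1
orthologs       10
n_losses        1
origin          N1
```

with an ASCII history (`variant_history.txt`) marking the origin, each
independent loss (`#loss`), and per-species states `[+] [-] [?]`, plus a
comment-tagged Newick (`[&loss]`, `[&origin]`).

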