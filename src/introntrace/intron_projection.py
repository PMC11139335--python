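"""Project intron positions onto a protein alignment and form position classes.

Two genes are inferred to share an intron when their introns land in the
same alignment column *and* the same phase. Near-identical columns with
different phases stay separate: intron positions essentially never slide
between phases, so phase is the discriminator between, e.g., a phase-0
intron at the codon-50/51 boundary and a phase-2 intron inside codon 57.
The resulting equivalence classes (column, phase) are the orthology signal
used to assign variant orthologs across species.

Also here: protosplice scoring of the flanking exonic 4-mer against the
AG|GT consensus at which new introns preferentially insert, and the mapping
of a donor gene's intron offset to the homologous coding offset in an
intronless paralog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import align_progressive
from .gene_structure import AnnotatedProtein, intron_codon_phase

__all__ = [
    "AlignedFamily",
    "ProjectedIntron",
    "AlignedIntronClass",
    "OrthologAssignment",
    "ProjectionError",
    "project_introns",
    "build_classes",
    "assign_orthologs",
    "flanking_site_score",
    "homologous_offset",
    "align_family",
]


class ProjectionError(ValueError):
    pass


@dataclass
class AlignedFamily:
    """A protein multiple alignment keyed by gene id.

    ``source`` records whether the alignment came from an external aligner
    or the internal deterministic test aligner.
    """

    alignment: dict[str, str]
    source: str = "external"

    def __post_init__(self) -> None:
        lengths = {len(row) for row in self.alignment.values()}
        if len(lengths) > 1:
            raise ProjectionError(f"unequal alignment row lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.alignment.values()))) if self.alignment else 0

    def degapped(self, gene_id: str) -> str:
        return self.alignment[gene_id].replace("-", "")


@dataclass(frozen=True)
class ProjectedIntron:
    """An intron lifted into alignment coordinates (1-based column)."""

    gene_id: str
    column: int
    phase: int


@dataclass
class AlignedIntronClass:
    """Genes whose introns share an alignment column and phase."""

    class_id: str
    column: int
    phase: int
    members: frozenset[str]


@dataclass
class OrthologAssignment:
    """Ortholog calls relative to one reference gene's introns.

    ``reference_classes`` lists the class for each reference intron (in
    coding order). ``orthologs`` is the union of genes sharing at least one
    reference class; ``partial`` maps such genes to the reference classes
    they lack (the "intron 2 absent" flags).
    """

    reference_gene_id: str
    reference_classes: list[AlignedIntronClass]
    orthologs: frozenset[str]
    partial: dict[str, list[str]] = field(default_factory=dict)


def align_family(
    proteins: list[AnnotatedProtein], external: dict[str, str] | None = None
) -> AlignedFamily:
    """Wrap an external alignment, or build one with the internal aligner."""
    if external is not None:
        return AlignedFamily(alignment=dict(external), source="external")
    rows = align_progressive({p.gene_id: p.aa_sequence for p in proteins})
    return AlignedFamily(alignment=rows, source="internal")


def project_introns(
    family: AlignedFamily, proteins: list[AnnotatedProtein]
) -> list[ProjectedIntron]:
    """Lift each annotated intron to its alignment column.

    The column is the alignment position of the residue at the intron's
    ``codon_index`` (the upstream residue for phase-0 introns), found by
    counting non-gap characters along that gene's row. A mismatch between
    the degapped row and the protein sequence signals a stale alignment and
    is an error naming the gene.
    """
    out: list[ProjectedIntron] = []
    for p in proteins:
        if p.gene_id not in family.alignment:
            raise ProjectionError(f"gene {p.gene_id} missing from alignment")
        row = family.alignment[p.gene_id]
        if row.replace("-", "") != p.aa_sequence:
            raise ProjectionError(
                f"gene {p.gene_id}: alignment row does not degap to its protein "
                "(stale alignment?)"
            )
        residue_col = _residue_columns(row)
        for intron in p.introns:
            col = residue_col[intron.codon_index - 1] + 1  # 1-based
            out.append(
                ProjectedIntron(gene_id=p.gene_id, column=col, phase=intron.phase)
            )
    return out


def _residue_columns(row: str) -> list[int]:
    """0-based alignment column of each residue (non-gap) in a row."""
    return [j for j, c in enumerate(row) if c != "-"]


def build_classes(projected: list[ProjectedIntron]) -> list[AlignedIntronClass]:
    """Partition projected introns into exact (column, phase) classes.

    Class ids follow the "column.phase" convention (so a second H2A.Z
    intron at alignment column 111 in phase 1 is class "111.1").
    """
    groups: dict[tuple[int, int], set[str]] = {}
    for pi in projected:
        groups.setdefault((pi.column, pi.phase), set()).add(pi.gene_id)
    classes = []
    for (col, phase) in sorted(groups):
        classes.append(
            AlignedIntronClass(
                class_id=f"{col}.{phase}",
                column=col,
                phase=phase,
                members=frozenset(groups[(col, phase)]),
            )
        )
    return classes


def assign_orthologs(
    classes: list[AlignedIntronClass], reference_gene_id: str
) -> OrthologAssignment:
    """Call putative orthologs of a reference variant by shared intron classes.

    A gene is a putative ortholog if it shares at least one of the reference
    gene's intron classes; genes sharing some but not all are flagged with
    the missing classes (lost introns or partial structures).
    """
    ref_classes = [c for c in classes if reference_gene_id in c.members]
    if not ref_classes:
        raise ProjectionError(
            f"reference gene {reference_gene_id} has no projected introns"
        )
    ref_classes.sort(key=lambda c: (c.column, c.phase))
    orthologs: set[str] = set()
    for c in ref_classes:
        orthologs |= c.members
    partial: dict[str, list[str]] = {}
    for g in sorted(orthologs):
        missing = [c.class_id for c in ref_classes if g not in c.members]
        if missing:
            partial[g] = missing
    return OrthologAssignment(
        reference_gene_id=reference_gene_id,
        reference_classes=ref_classes,
        orthologs=frozenset(orthologs),
        partial=partial,
    )


def flanking_site_score(
    core_cds: str, insertion_offset: int
) -> tuple[str, int, bool]:
    """Score an intron insertion point against the protosplice consensus AG|GT.

    ``insertion_offset`` is the homologous coding offset in an *intronless*
    paralog; the exonic 4-mer is the 2 nt upstream + 2 nt downstream of the
    insertion point. Returns (four_mer, positional matches to AGGT, signal),
    where signal is True iff the upstream dinucleotide is exactly AG or the
    downstream dinucleotide exactly GT.
    """
    cds = core_cds.upper()
    if insertion_offset < 2 or insertion_offset > len(cds) - 2:
        raise ProjectionError(
            f"insertion offset {insertion_offset} too close to CDS ends"
        )
    four_mer = cds[insertion_offset - 2 : insertion_offset + 2]
    matches = sum(1 for a, b in zip(four_mer, "AGGT") if a == b)
    signal = four_mer[:2] == "AG" or four_mer[2:] == "GT"
    return four_mer, matches, signal


def homologous_offset(
    family: AlignedFamily, donor_gene: str, donor_offset: int, target_gene: str
) -> int | None:
    """Map a donor intron's coding offset to the homologous offset in a target.

    Goes donor codon_index -> alignment column -> target residue index ->
    target coding offset, preserving phase. Returns None ("unmappable") when
    the target has a gap at the donor's column — no guess is made.
    """
    ann = intron_codon_phase(donor_offset)
    donor_row = family.alignment[donor_gene]
    target_row = family.alignment[target_gene]
    donor_cols = _residue_columns(donor_row)
    if ann.codon_index > len(donor_cols):
        raise ProjectionError(
            f"donor offset {donor_offset} beyond {donor_gene} length"
        )
    col = donor_cols[ann.codon_index - 1]
    if target_row[col] == "-":
        return None
    target_residue_index = sum(1 for c in target_row[: col + 1] if c != "-")
    if ann.phase == 0:
        return target_residue_index * 3
    return (target_residue_index - 1) * 3 + ann.phase
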