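"""Gene models, coding coordinates and intron phase arithmetic.

The central coordinate object here is the *coding offset* of an intron: the
number of coding (CDS) nucleotides strictly upstream of the intron within the
spliced transcript. From it the 1-based codon index and the phase (0, 1 or 2)
are derived views. Phase-0 introns fall *between* codons and are reported
against the upstream codon ("between codon i and i+1" with ``codon_index = i``);
phase-1/2 introns interrupt codon ``codon_index``.

Genomic intervals are handled 0-based half-open internally; GFF3 input is
1-based inclusive and converted on parse. All reported codon indices are
1-based, matching the conventional "phase 0 intron between the 26th and 27th
amino acid" phrasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import gffutils
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "IntronAnnotation",
    "AnnotatedProtein",
    "GeneStructureError",
    "parse_gff3",
    "assemble_cds",
    "intron_codon_phase",
    "translate_cds",
    "rescue_scan",
    "annotate_gene",
    "write_annotated_fasta",
    "read_annotated_fasta",
]


class GeneStructureError(ValueError):
    """Raised for structurally invalid gene models or coordinates."""


@dataclass(frozen=True)
class IntronAnnotation:
    """One intron position in coding coordinates.

    ``coding_offset`` is the canonical key (coding nucleotides strictly
    upstream of the intron); ``codon_index``/``phase`` are derived.
    ``boundary`` is True for phase-0 introns, which sit between codons.
    """

    coding_offset: int
    codon_index: int
    phase: int
    boundary: bool

    def __post_init__(self) -> None:
        if self.coding_offset < 1:
            raise GeneStructureError(
                f"coding_offset must be >= 1, got {self.coding_offset}"
            )
        if self.phase != self.coding_offset % 3:
            raise GeneStructureError("phase inconsistent with coding_offset")


@dataclass
class GeneModel:
    """Exon/CDS layout of one protein-coding gene on a contig.

    ``cds_segments`` are 0-based half-open genomic intervals in *transcript*
    order: ascending genomic coordinates on '+', descending on '-'.
    """

    gene_id: str
    species_id: str
    contig_id: str
    strand: str
    cds_segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GeneStructureError(f"bad strand {self.strand!r}")
        segs = self.cds_segments
        if not segs:
            raise GeneStructureError(f"{self.gene_id}: no CDS segments")
        for s, e in segs:
            if e <= s:
                raise GeneStructureError(f"{self.gene_id}: empty segment {(s, e)}")
        ordered = sorted(segs)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise GeneStructureError(f"{self.gene_id}: overlapping CDS segments")
        expect = ordered if self.strand == "+" else ordered[::-1]
        if segs != expect:
            raise GeneStructureError(
                f"{self.gene_id}: segments not in transcript orientation"
            )
        if self.cds_length % 3 != 0:
            raise GeneStructureError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


@dataclass
class AnnotatedProtein:
    """A translated gene with its intron positions in coding coordinates."""

    gene_id: str
    species_id: str
    aa_sequence: str
    introns: list[IntronAnnotation] = field(default_factory=list)
    cds: str | None = None

    def __post_init__(self) -> None:
        offs = [i.coding_offset for i in self.introns]
        if offs != sorted(set(offs)):
            raise GeneStructureError(
                f"{self.gene_id}: introns must be sorted, strictly increasing"
            )


# ---------------------------------------------------------------------------
# coordinate arithmetic


def intron_codon_phase(coding_offset: int) -> IntronAnnotation:
    """Derive codon index and phase from a coding offset.

    Phase 0 (``offset % 3 == 0``): the intron sits between codon
    ``offset/3`` and the next one. Phase 1/2: it interrupts codon
    ``floor(offset/3) + 1``.
    """
    if coding_offset < 1:
        raise GeneStructureError(f"coding_offset must be >= 1, got {coding_offset}")
    phase = coding_offset % 3
    if phase == 0:
        codon_index = coding_offset // 3
    else:
        codon_index = coding_offset // 3 + 1
    return IntronAnnotation(
        coding_offset=coding_offset,
        codon_index=codon_index,
        phase=phase,
        boundary=(phase == 0),
    )


def assemble_cds(model: GeneModel, genome: Mapping[str, str]) -> tuple[str, list[int]]:
    """Concatenate CDS segments into the spliced coding sequence.

    Returns the CDS (reverse-complemented on '-') and one coding offset per
    inter-segment junction, i.e. the cumulative coding length before each
    intron.
    """
    try:
        contig = genome[model.contig_id]
    except KeyError:
        raise GeneStructureError(
            f"{model.gene_id}: contig {model.contig_id!r} missing from genome"
        ) from None
    contig = str(contig)
    parts: list[str] = []
    for s, e in model.cds_segments:
        if s < 0 or e > len(contig):
            raise GeneStructureError(
                f"{model.gene_id}: segment {(s, e)} outside contig "
                f"{model.contig_id} (length {len(contig)})"
            )
        piece = contig[s:e]
        if model.strand == "-":
            piece = str(Seq(piece).reverse_complement())
        parts.append(piece)
    offsets: list[int] = []
    cum = 0
    for piece in parts[:-1]:
        cum += len(piece)
        offsets.append(cum)
    return "".join(parts).upper(), offsets


def translate_cds(cds_sequence: str) -> str:
    """Translate a CDS with the standard code; strip the terminal stop.

    Ambiguity codes translate to 'X'. An internal stop codon is an error
    (such genes are excluded upstream rather than repaired).
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise GeneStructureError(f"CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    star = aa.find("*")
    if star != -1:
        raise GeneStructureError(f"internal stop codon at codon {star + 1}")
    return aa


def annotate_gene(model: GeneModel, genome: Mapping[str, str]) -> AnnotatedProtein:
    """Assemble, annotate introns and translate one gene model."""
    cds, offsets = assemble_cds(model, genome)
    aa = translate_cds(cds)
    introns = [intron_codon_phase(o) for o in offsets]
    for ann in introns:
        if ann.coding_offset > len(cds) - 1:
            raise GeneStructureError(
                f"{model.gene_id}: intron offset {ann.coding_offset} at CDS end"
            )
    return AnnotatedProtein(
        gene_id=model.gene_id,
        species_id=model.species_id,
        aa_sequence=aa,
        introns=introns,
        cds=cds,
    )


# ---------------------------------------------------------------------------
# GFF3 parsing


def parse_gff3(
    gff3_stream: TextIO | str,
    fasta_index: Mapping[str, str],
    species_id: str = "unknown",
) -> list[GeneModel]:
    """Build GeneModels from GFF3 CDS features.

    CDS features are grouped by their ``Parent`` attribute (a transcript or,
    in minimal files, the gene itself). When a gene has several transcripts
    the longest CDS is kept. Genes whose CDS length is not a multiple of 3
    are excluded with a warning; a CDS on a contig absent from the FASTA is
    an error naming the contig.
    """
    text = gff3_stream if isinstance(gff3_stream, str) else gff3_stream.read()
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    # parent transcript -> gene (from mRNA/transcript features), if present
    tx_gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [])
            if parents:
                tx_gene[feat.id] = parents[0]
    cds_by_parent: dict[str, list[tuple[str, str, int, int]]] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", []) or [feat.id]
        for p in parents:
            cds_by_parent.setdefault(p, []).append(
                (feat.seqid, feat.strand, feat.start - 1, feat.end)
            )

    # group transcripts by gene, keep longest CDS per gene
    by_gene: dict[str, list[tuple[str, list[tuple[str, str, int, int]]]]] = {}
    for tid, feats in cds_by_parent.items():
        gene = tx_gene.get(tid, tid)
        by_gene.setdefault(gene, []).append((tid, feats))

    models: list[GeneModel] = []
    for gene_id in sorted(by_gene):
        candidates = by_gene[gene_id]
        candidates.sort(
            key=lambda tf: (-sum(e - s for _, _, s, e in tf[1]), tf[0])
        )
        _tid, feats = candidates[0]
        contigs = {f[0] for f in feats}
        strands = {f[1] for f in feats}
        if len(contigs) != 1 or len(strands) != 1:
            log.warning("gene %s: CDS on multiple contigs/strands, excluded", gene_id)
            continue
        contig_id, strand = feats[0][0], feats[0][1]
        if contig_id not in fasta_index:
            raise GeneStructureError(
                f"gene {gene_id}: contig {contig_id!r} missing from FASTA"
            )
        segs = sorted((s, e) for _, _, s, e in feats)
        if strand == "-":
            segs = segs[::-1]
        try:
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    species_id=species_id,
                    contig_id=contig_id,
                    strand=strand,
                    cds_segments=segs,
                )
            )
        except GeneStructureError as exc:
            log.warning("gene %s excluded: %s", gene_id, exc)
    return models


# ---------------------------------------------------------------------------
# annotated-protein FASTA dialect
#
# Header: >gene_id species=<sp> introns=<offset>:<codon>.<phase>[,...]
# Intronless genes write introns=-


def write_annotated_fasta(proteins: Iterable[AnnotatedProtein], handle: TextIO) -> None:
    for p in proteins:
        if p.introns:
            tag = ",".join(
                f"{i.coding_offset}:{i.codon_index}.{i.phase}" for i in p.introns
            )
        else:
            tag = "-"
        handle.write(f">{p.gene_id} species={p.species_id} introns={tag}\n")
        handle.write(p.aa_sequence + "\n")


def read_annotated_fasta(handle: TextIO | str) -> list[AnnotatedProtein]:
    text = handle if isinstance(handle, str) else handle.read()
    out: list[AnnotatedProtein] = []
    header: str | None = None
    seq_parts: list[str] = []
    for line in text.splitlines() + [">"]:
        if line.startswith(">"):
            if header is not None:
                out.append(_protein_from_header(header, "".join(seq_parts)))
            header = line[1:].strip() or None
            seq_parts = []
        else:
            seq_parts.append(line.strip())
    return out


def _protein_from_header(header: str, seq: str) -> AnnotatedProtein:
    fields = header.split()
    gene_id = fields[0]
    species = "unknown"
    introns: list[IntronAnnotation] = []
    for f in fields[1:]:
        if f.startswith("species="):
            species = f[len("species="):]
        elif f.startswith("introns="):
            tag = f[len("introns="):]
            if tag != "-":
                for item in tag.split(","):
                    off = int(item.split(":")[0])
                    introns.append(intron_codon_phase(off))
    return AnnotatedProtein(
        gene_id=gene_id, species_id=species, aa_sequence=seq, introns=introns
    )


# ---------------------------------------------------------------------------
# naive six-frame rescue scan

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aa_pair_score(a: str, b: str) -> float:
    if a == "*" or b == "*":
        return -4.0
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return -1.0


def rescue_scan(
    query_peptide: str,
    genome: Mapping[str, str],
    min_score: float,
    window: int = 30,
) -> list[tuple[str, str, int, tuple[int, int], float]]:
    """Naive six-frame ungapped scan for a peptide in a genome.

    A qualitative stand-in for a translated homology search, used to check
    whether an unannotated copy of a gene is present in assembly sequence.
    Each contig is translated in all six frames and the query slid along the
    translation; the ungapped BLOSUM62 score is recorded at each offset.
    Overlapping hits within ``window`` codons on the same contig/strand/frame
    are suppressed, keeping the best. Hits with score >= ``min_score`` are
    returned sorted by score descending (ties broken by contig, strand,
    frame, position), with the matched genomic interval (0-based half-open).
    """
    if len(query_peptide) < 15:
        raise GeneStructureError("query peptide must be >= 15 aa")
    q = query_peptide.upper()
    qlen = len(q)
    raw: list[tuple[str, str, int, int, float]] = []
    for contig_id in sorted(genome):
        seq = str(genome[contig_id]).upper()
        for strand in "+-":
            nt = seq if strand == "+" else str(Seq(seq).reverse_complement())
            for frame in range(3):
                sub = nt[frame:]
                sub = sub[: len(sub) - len(sub) % 3]
                if len(sub) < 3 * qlen:
                    continue
                pep = str(Seq(sub).translate())
                for i in range(len(pep) - qlen + 1):
                    score = sum(
                        _aa_pair_score(q[j], pep[i + j]) for j in range(qlen)
                    )
                    if score >= min_score:
                        raw.append((contig_id, strand, frame, i, score))
    # local-maximum suppression within `window` codons
    kept: list[tuple[str, str, int, int, float]] = []
    for key in sorted({(c, s, f) for c, s, f, _, _ in raw}):
        hits = sorted(
            (h for h in raw if (h[0], h[1], h[2]) == key),
            key=lambda h: (-h[4], h[3]),
        )
        chosen: list[tuple[str, str, int, int, float]] = []
        for h in hits:
            if all(abs(h[3] - c[3]) > window for c in chosen):
                chosen.append(h)
        kept.extend(chosen)

    results = []
    for contig_id, strand, frame, i, score in kept:
        nt_start = frame + 3 * i
        nt_end = nt_start + 3 * qlen
        clen = len(str(genome[contig_id]))
        if strand == "+":
            interval = (nt_start, nt_end)
        else:
            interval = (clen - nt_end, clen - nt_start)
        results.append((contig_id, strand, frame, interval, score))
    results.sort(key=lambda r: (-r[4], r[0], r[1], r[2], r[3]))
    return results
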