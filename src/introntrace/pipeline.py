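"""End-to-end workflow: genomes + annotations -> variant gain/loss report.

Stages: parse GFF3/FASTA per species -> annotate intron positions and
translate -> filter the homolog set (e-value, length, identity collapse)
-> align (external file or internal aligner) -> project introns onto the
alignment -> build (column, phase) classes -> call orthologs of the
reference variant -> Dollo reconstruction of the variant's origin and
independent losses on the species tree -> reports. Every stage writes its
outputs to the run directory so each number in the summary can be re-derived
from stage tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import family_filter as ff
from . import gene_structure as gs
from . import intron_projection as ip
from .evo_inference import (
    ABSENT,
    PRESENT,
    UNKNOWN,
    DolloResult,
    PresencePattern,
    SpeciesTree,
    dollo_reconstruct,
    quality_loss_test,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "report_variant_history"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for one pipeline run.

    ``genomes_dir`` must hold ``<species>.fasta`` with matching
    ``<species>.gff3`` in ``gff_dir`` (same directory by default).
    """

    genomes_dir: str
    species_tree: str
    out_dir: str
    gff_dir: str | None = None
    reference_gene_id: str | None = None
    canonical_gene_id: str | None = None
    alignment: str | None = None  # aligned FASTA; internal aligner if absent
    hits_table: str | None = None  # TSV: query, subject, evalue
    quality_table: str | None = None  # TSV: species, completeness, missing
    max_aa: int = 200
    max_evalue: float = 1e-10
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def validate(self) -> None:
        if self.max_aa <= 0 or self.max_evalue <= 0:
            raise PipelineError("thresholds must be positive")
        for name in ("genomes_dir", "species_tree", "alignment", "hits_table",
                     "quality_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"{name}: path does not exist: {value}")


@dataclass
class PipelineReport:
    proteins: list[gs.AnnotatedProtein]
    homologs: ff.HomologSet
    family: ip.AlignedFamily | None
    classes: list[ip.AlignedIntronClass]
    assignment: ip.OrthologAssignment | None
    pattern: PresencePattern | None
    dollo: DolloResult | None
    counts: dict[str, int]
    quality_tests: dict[str, tuple[float, float, float]] | None = None


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full workflow; raises PipelineError naming a failed stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # -- stage: annotate ----------------------------------------------------
    try:
        proteins, species_seen = _annotate_stage(config)
    except Exception as exc:
        raise PipelineError(f"annotate stage failed: {exc}") from exc
    counts["annotated_genes"] = len(proteins)
    log.info("annotate: %d genes from %d species", len(proteins), len(species_seen))
    with open(out / "annotated_proteins.fasta", "w") as fh:
        gs.write_annotated_fasta(proteins, fh)
    _write_intron_tsv(proteins, out / "introns.tsv")

    # -- stage: filter ------------------------------------------------------
    try:
        provenance = _read_hits(config.hits_table) if config.hits_table else {}
        homologs = ff.HomologSet(records=list(proteins), provenance=provenance)
        if provenance:
            homologs = ff.evalue_filter(homologs, config.max_evalue)
        counts["after_evalue"] = len(homologs)
        homologs = ff.length_filter(homologs, config.max_aa)
        counts["after_length"] = len(homologs)
        homologs = ff.collapse_identical(homologs, level="protein")
        counts["after_collapse"] = len(homologs)
    except Exception as exc:
        raise PipelineError(f"filter stage failed: {exc}") from exc
    log.info(
        "filter: %d -> %d (e-value) -> %d (length) -> %d (collapse)",
        counts["annotated_genes"], counts["after_evalue"],
        counts["after_length"], counts["after_collapse"],
    )
    _write_members_tsv(homologs, out / "collapsed_members.tsv")

    species_of = {p.gene_id: p.species_id for p in homologs.records}

    # -- stage: align / project / classify ----------------------------------
    try:
        external = _read_alignment(config.alignment, homologs) if config.alignment else None
        family = ip.align_family(homologs.records, external=external)
        projected = ip.project_introns(family, homologs.records)
        classes = ip.build_classes(projected)
    except Exception as exc:
        raise PipelineError(f"projection stage failed: {exc}") from exc
    counts["intron_classes"] = len(classes)
    log.info("project: %d projected introns in %d classes", len(projected), len(classes))
    _write_classes_tsv(classes, out / "intron_classes.tsv")
    _write_projected_tsv(projected, out / "projected_introns.tsv")

    # -- stage: orthologs + Dollo -------------------------------------------
    assignment = None
    pattern = None
    dollo = None
    quality_tests = None
    if config.reference_gene_id is not None:
        try:
            assignment = ip.assign_orthologs(classes, config.reference_gene_id)
            tree = SpeciesTree.from_newick(Path(config.species_tree).read_text())
            pattern = presence_from_orthologs(
                tree, assignment, species_of, species_seen
            )
            dollo = dollo_reconstruct(tree, pattern)
        except Exception as exc:
            raise PipelineError(f"dollo stage failed: {exc}") from exc
        counts["orthologs"] = len(assignment.orthologs)
        counts["n_losses"] = dollo.n_losses
        log.info(
            "dollo: origin %s, %d losses (upper bound %d)",
            dollo.origin_node, dollo.n_losses, dollo.n_losses_upper,
        )
        _write_pattern_tsv(pattern, out / "presence.tsv")
        tsv, annotated_newick, ascii_tree = report_variant_history(
            dollo, tree, pattern
        )
        (out / "variant_history.tsv").write_text(tsv)
        (out / "variant_history.nwk").write_text(annotated_newick + "\n")
        (out / "variant_history.txt").write_text(ascii_tree + "\n")

        if config.quality_table is not None:
            loss_species = sorted(
                s for s in tree.leaf_ids()
                if pattern.state[s] == ABSENT
            )
            quality = pd.read_csv(config.quality_table, sep="\t")
            quality_tests = quality_loss_test(quality, loss_species)
            _write_quality_tsv(quality_tests, out / "quality_tests.tsv")

    _write_counts_tsv(counts, out / "stage_counts.tsv")
    return PipelineReport(
        proteins=proteins,
        homologs=homologs,
        family=family,
        classes=classes,
        assignment=assignment,
        pattern=pattern,
        dollo=dollo,
        counts=counts,
        quality_tests=quality_tests,
    )


def presence_from_orthologs(
    tree: SpeciesTree,
    assignment: ip.OrthologAssignment,
    species_of: dict[str, str],
    species_with_records: set[str],
) -> PresencePattern:
    """Per-species presence of the reference variant's intron class.

    A species is present if any of its genes falls in a reference class,
    absent if it contributed homologs but none carry the class, and unknown
    if no homolog of the family could be annotated there at all (the "?"
    species, where absence of evidence is not evidence of loss).
    """
    present_species = {species_of[g] for g in assignment.orthologs if g in species_of}
    state: dict[str, str] = {}
    for sp in tree.leaf_ids():
        if sp in present_species:
            state[sp] = PRESENT
        elif sp in species_with_records:
            state[sp] = ABSENT
        else:
            state[sp] = UNKNOWN
    char_id = assignment.reference_classes[0].class_id
    return PresencePattern(character_id=char_id, state=state)


def report_variant_history(
    dollo: DolloResult,
    tree: SpeciesTree,
    pattern: PresencePattern | None = None,
) -> tuple[str, str, str]:
    """Render a reconstruction as (TSV, comment-tagged Newick, ASCII tree).

    Loss edges carry a ``[&loss]`` comment in the Newick and a ``#`` hash
    mark in the ASCII sketch; unknown species render with ``?``.
    """
    rows = [
        ("character", dollo.character_id),
        ("origin_node", dollo.origin_node),
        ("n_losses", str(dollo.n_losses)),
        ("n_losses_upper", str(dollo.n_losses_upper)),
        ("loss_edges", ",".join(sorted(dollo.loss_edges)) or "-"),
        ("possible_loss_edges", ",".join(sorted(dollo.possible_loss_edges)) or "-"),
        ("ambiguous", str(dollo.ambiguous).lower()),
    ]
    tsv = "key\tvalue\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"

    def newick_of(node_id: str) -> str:
        tag = "[&loss]" if node_id in dollo.loss_edges else ""
        if node_id == dollo.origin_node:
            tag += "[&origin]"
        if tree.is_leaf(node_id):
            return f"{node_id}{tag}"
        inner = ",".join(newick_of(c) for c in tree.children(node_id))
        return f"({inner}){node_id}{tag}"

    annotated = newick_of(tree.root_id) + ";"

    lines: list[str] = []

    def sketch(node_id: str, prefix: str, is_last: bool, is_root: bool) -> None:
        connector = "" if is_root else ("`-- " if is_last else "|-- ")
        marks = ""
        if node_id in dollo.loss_edges:
            marks += " #loss"
        if node_id == dollo.origin_node:
            marks += " *origin"
        if tree.is_leaf(node_id):
            sym = ""
            if pattern is not None:
                sym = {PRESENT: " [+]", ABSENT: " [-]", UNKNOWN: " [?]"}[
                    pattern.state[node_id]
                ]
            lines.append(f"{prefix}{connector}{node_id}{sym}{marks}")
        else:
            lines.append(f"{prefix}{connector}{node_id}{marks}")
            kids = tree.children(node_id)
            ext = "" if is_root else ("    " if is_last else "|   ")
            for i, c in enumerate(kids):
                sketch(c, prefix + ext, i == len(kids) - 1, False)

    sketch(tree.root_id, "", True, True)
    return tsv, annotated, "\n".join(lines)


# ---------------------------------------------------------------------------
# stage helpers


def _annotate_stage(
    config: PipelineConfig,
) -> tuple[list[gs.AnnotatedProtein], set[str]]:
    genomes_dir = Path(config.genomes_dir)
    gff_dir = Path(config.gff_dir) if config.gff_dir else genomes_dir
    fasta_files = sorted(genomes_dir.glob("*.fasta")) + sorted(
        genomes_dir.glob("*.fa")
    )
    if not fasta_files:
        raise PipelineError(f"no FASTA files in {genomes_dir}")
    proteins: list[gs.AnnotatedProtein] = []
    species_seen: set[str] = set()
    for fasta in fasta_files:
        species = fasta.stem
        gff = gff_dir / f"{species}.gff3"
        if not gff.exists():
            raise PipelineError(f"missing annotation file {gff}")
        genome = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
        }
        models = gs.parse_gff3(gff.read_text(), genome, species_id=species)
        for model in models:
            try:
                proteins.append(gs.annotate_gene(model, genome))
                species_seen.add(species)
            except gs.GeneStructureError as exc:
                log.warning("gene %s excluded: %s", model.gene_id, exc)
        if models:
            species_seen.add(species)
    return proteins, species_seen


def _read_hits(path: str) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    # BLAST outfmt-6-like: query, subject, ..., evalue in column 10 (or a
    # minimal 3-column query/subject/evalue table)
    evalue_col = 10 if df.shape[1] >= 11 else df.shape[1] - 1
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        subject = str(row[1])
        ev = float(row[evalue_col])
        out[subject] = min(ev, out.get(subject, float("inf")))
    return out


def _read_alignment(path: str, homologs: ff.HomologSet) -> dict[str, str]:
    rows = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")
    }
    wanted = set(homologs.gene_ids())
    subset = {g: r for g, r in rows.items() if g in wanted}
    missing = wanted - set(subset)
    if missing:
        raise PipelineError(f"alignment missing genes: {sorted(missing)}")
    return subset


def _write_intron_tsv(proteins, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tspecies\tcoding_offset\tcodon_index\tphase\n")
        for p in proteins:
            for i in p.introns:
                fh.write(
                    f"{p.gene_id}\t{p.species_id}\t{i.coding_offset}\t"
                    f"{i.codon_index}\t{i.phase}\n"
                )


def _write_members_tsv(homologs: ff.HomologSet, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tmembers\n")
        for rep in sorted(homologs.collapsed_members):
            fh.write(f"{rep}\t{','.join(homologs.collapsed_members[rep])}\n")


def _write_classes_tsv(classes, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("class_id\tcolumn\tphase\tn_members\tmembers\n")
        for c in classes:
            fh.write(
                f"{c.class_id}\t{c.column}\t{c.phase}\t{len(c.members)}\t"
                f"{','.join(sorted(c.members))}\n"
            )


def _write_projected_tsv(projected, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcolumn\tphase\n")
        for p in sorted(projected, key=lambda x: (x.gene_id, x.column, x.phase)):
            fh.write(f"{p.gene_id}\t{p.column}\t{p.phase}\n")


def _write_pattern_tsv(pattern: PresencePattern, path: Path) -> None:
    sym = {PRESENT: "1", ABSENT: "0", UNKNOWN: "?"}
    with open(path, "w") as fh:
        fh.write("species\tstate\n")
        for sp in sorted(pattern.state):
            fh.write(f"{sp}\t{sym[pattern.state[sp]]}\n")


def read_pattern_tsv(path: str | Path, character_id: str = "character") -> PresencePattern:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PresencePattern.from_symbols(
        character_id, dict(zip(df["species"], df["state"]))
    )


def _write_quality_tsv(tests, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tt\tdf\tp\n")
        for metric, (t, dfree, p) in tests.items():
            fh.write(f"{metric}\t{t:.6g}\t{dfree:.6g}\t{p:.6g}\n")


def _write_counts_tsv(counts: dict[str, int], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tcount\n")
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")
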