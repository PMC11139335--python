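"""Simulate variant-histone-style gene families for end-to-end testing.

The generator embodies the evolutionary scenario the pipeline is built to
reconstruct: a multi-copy, intronless canonical gene evolves along a
species tree; at a chosen node a variant copy is born carrying a novel
intron at a chosen coding offset (inserted at an AG|GT protosplice context
when requested); each branch below the birth node loses the variant with a
fixed probability; the variant lineage evolves faster than the canonical
one by a rate multiplier; and optional annotation dropouts remove genes
from the GFF3 while leaving them in the genome (the "annotation failure"
confound). Everything is emitted as standard FASTA + GFF3 + Newick plus a
truth record, so the full pipeline can be scored against known history.

Substitutions follow Jukes–Cantor at the nucleotide level with
stop-avoidance resampling; the default mode introduces no indels, so
protein alignment of the resulting family is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationOutput",
    "simulate_family",
    "evolve_cds",
    "make_worked_example_fixture",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationConfig:
    """Conditions for one simulated gene family.

    Defaults describe a moderately diverged 32-species clade: per-branch
    variant loss probability 0.1, canonical substitution rate 0.02
    expected substitutions/site per unit branch length, and a 3x faster
    variant lineage (variant histones like the sperm-specific H2A variant
    evolve several-fold faster than core H2A). The ancestral protein is
    histone-sized (125 aa). The seed fully determines every output.
    """

    n_species: int = 32
    tree_newick: str | None = None
    birth_node: str | None = None  # default: root of the tree
    intron_offset: int = 150
    second_intron_offset: int | None = None
    loss_prob_per_branch: float = 0.1
    substitution_rate: float = 0.02
    variant_rate_multiplier: float = 3.0
    annotation_dropout_prob: float = 0.0
    protosplice_bias: bool = True
    seed: int = 0
    n_codons: int = 125  # ancestral protein length, aa (stop codon extra)
    intron_length: int = 61
    flank: int = 500

    def __post_init__(self) -> None:
        for p in (
            self.loss_prob_per_branch,
            self.annotation_dropout_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if self.variant_rate_multiplier < 1.0:
            raise ValueError("variant_rate_multiplier must be >= 1")
        cds_len = 3 * self.n_codons
        offsets = [self.intron_offset]
        if self.second_intron_offset is not None:
            offsets.append(self.second_intron_offset)
        for off in offsets:
            if not 1 <= off <= cds_len - 1:
                raise ValueError(
                    f"intron offset {off} outside ancestral CDS (1..{cds_len - 1})"
                )


@dataclass
class SimulationTruth:
    """Known history of a simulated family, for scoring reconstructions."""

    presence: dict[str, bool]
    origin_node: str
    loss_edges: list[str]
    intron_offsets: dict[str, list[int]]
    dropouts: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SimulationOutput:
    genomes: dict[str, dict[str, str]]  # species -> contig -> sequence
    gff3: dict[str, str]  # species -> GFF3 text
    newick: str
    truth: SimulationTruth
    config: SimulationConfig | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in sorted(self.genomes):
            with open(outdir / f"{sp}.fasta", "w") as fh:
                for contig in sorted(self.genomes[sp]):
                    fh.write(f">{contig}\n{self.genomes[sp][contig]}\n")
            with open(outdir / f"{sp}.gff3", "w") as fh:
                fh.write(self.gff3[sp])
        (outdir / "species_tree.nwk").write_text(self.newick + "\n")
        (outdir / "truth.json").write_text(self.truth.to_json() + "\n")


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_cds(
    sequence: str, expected_subs_per_site: float, seed: "int | np.random.Generator"
) -> str:
    """Evolve a coding sequence under Jukes–Cantor for a given distance.

    ``expected_subs_per_site`` is branch length x rate. Sites substitute
    independently with the JC transition probability
    3/4 (1 - exp(-4d/3)); substitutions that would create an in-frame stop
    codon are resampled so the CDS stays translatable. The input must be
    stop-free in frame (terminal stop handled by the caller).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    d = float(expected_subs_per_site)
    if d < 0:
        raise ValueError("negative evolutionary distance")
    seq = np.array(list(sequence.upper()))
    if d == 0:
        return sequence.upper()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    hit = rng.random(len(seq)) < p_change
    idx = np.nonzero(hit)[0]
    for i in idx:
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[rng.integers(3)]
    _fix_stops(seq, set(idx.tolist()), rng)
    return "".join(seq)


def _fix_stops(seq: np.ndarray, mutable: set[int], rng: np.random.Generator) -> None:
    """Resample mutated positions of codons that became stops (in place)."""
    for c0 in range(0, len(seq) - len(seq) % 3, 3):
        guard = 0
        while "".join(seq[c0 : c0 + 3]) in _STOPS:
            free = [i for i in range(c0, c0 + 3) if i in mutable]
            if not free:  # cannot happen for stop-free input
                raise RuntimeError("stop codon with no mutated site")
            i = free[rng.integers(len(free))]
            seq[i] = _BASES[rng.integers(4)]
            guard += 1
            if guard > 100:
                raise RuntimeError("stop-avoidance did not converge")


def _random_coding(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free coding sequence starting with ATG (no terminal stop)."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(_BASES[rng.integers(4, size=3)])
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _force_motif(coding: str, offset: int, motif: str, rng: np.random.Generator) -> str:
    """Place a motif across [offset-2, offset+2) and repair any stop codons."""
    seq = np.array(list(coding))
    frozen = set(range(offset - 2, offset + 2))
    seq[offset - 2 : offset + 2] = list(motif)
    for c0 in range(0, len(seq), 3):
        guard = 0
        while "".join(seq[c0 : c0 + 3]) in _STOPS:
            free = [i for i in range(c0, c0 + 3) if i not in frozen]
            if not free:
                raise ValueError(f"motif {motif} at {offset} forces a stop codon")
            i = free[rng.integers(len(free))]
            seq[i] = _BASES[rng.integers(4)]
            guard += 1
            if guard > 100:
                raise RuntimeError("motif stop repair did not converge")
    return "".join(seq)


# ---------------------------------------------------------------------------
# random species trees (simple Yule birth process)


def _yule_tree(n_species: int, rng: np.random.Generator) -> str:
    """Ultrametric Yule tree Newick with species sp01..spNN and labeled
    internal nodes (preorder N1, N2, ... matching SpeciesTree's assignment)."""
    if n_species < 2:
        raise ValueError("need >= 2 species")
    # each node: [children, birth_time]; leaves collect end time later
    nodes: dict[int, dict] = {0: {"children": [], "t": 0.0}}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        pick = active[rng.integers(k)]
        kids = []
        for _ in range(2):
            nodes[next_id] = {"children": [], "t": t}
            kids.append(next_id)
            next_id += 1
        nodes[pick]["children"] = kids
        active.remove(pick)
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / n_species)

    # A node's "t" is its birth time (= its parent's split time); an internal
    # node's split time is its children's birth time; leaves end at t_end.
    # Internal labels are assigned in preorder (N1 = root), matching the id
    # assignment SpeciesTree makes for unlabeled trees.
    leaf_counter = [0]
    internal_counter = [0]

    def render(nid: int) -> str:
        node = nodes[nid]
        kids = node["children"]
        if not kids:
            leaf_counter[0] += 1
            name = f"sp{leaf_counter[0]:02d}"
            return f"{name}:{t_end - node['t']:.6f}"
        internal_counter[0] += 1
        label = f"N{internal_counter[0]}"
        split_t = nodes[kids[0]]["t"]
        parts = [render(c) for c in kids]
        bl = split_t - node["t"]
        return f"({','.join(parts)}){label}:{bl:.6f}"

    root_children = nodes[0]["children"]
    internal_counter[0] += 1
    root_label = f"N{internal_counter[0]}"
    parts = [render(c) for c in root_children]
    return f"({','.join(parts)}){root_label};"


# ---------------------------------------------------------------------------
# family simulation


def simulate_family(config: SimulationConfig) -> SimulationOutput:
    """Simulate one gene family and emit genomes, annotations and truth."""
    from .evo_inference import SpeciesTree  # local import to avoid cycle

    rng = np.random.default_rng(config.seed)
    newick = config.tree_newick or _yule_tree(config.n_species, rng)
    tree = SpeciesTree.from_newick(newick)
    birth = config.birth_node or tree.root_id
    if birth not in tree.node_ids():
        raise ValueError(f"birth_node {birth!r} not in tree")

    coding = _random_coding(config.n_codons, rng)
    if config.protosplice_bias:
        coding = _force_motif(coding, config.intron_offset, "AGGT", rng)

    branch_len = _branch_lengths(tree)

    # evolve canonical and variant coding sequences down the tree
    canon_at: dict[str, str] = {tree.root_id: coding}
    variant_at: dict[str, str | None] = {}
    loss_edges: list[str] = []
    rate = config.substitution_rate
    vmult = config.variant_rate_multiplier

    for nid in tree.node_ids():  # preorder
        parent = tree.parent(nid)
        if parent is not None:
            d = branch_len[nid] * rate
            canon_at[nid] = evolve_cds(canon_at[parent], d, rng)
            pv = variant_at.get(parent)
            if pv is not None:
                if rng.random() < config.loss_prob_per_branch:
                    variant_at[nid] = None
                    loss_edges.append(nid)
                else:
                    variant_at[nid] = evolve_cds(pv, d * vmult, rng)
            else:
                variant_at[nid] = None
        if nid == birth:
            # variant born here: duplicate the canonical sequence at this node
            variant_at[nid] = canon_at[nid]

    presence = {
        leaf: variant_at.get(leaf) is not None for leaf in tree.leaf_ids()
    }
    # losses are only ever sampled on edges the variant entered alive, so
    # every recorded edge is a real, independent loss
    real_losses = loss_edges

    offsets = [config.intron_offset]
    if config.second_intron_offset is not None:
        offsets = sorted({config.intron_offset, config.second_intron_offset})

    genomes: dict[str, dict[str, str]] = {}
    gff3: dict[str, str] = {}
    intron_offsets: dict[str, list[int]] = {}
    dropouts: list[str] = []

    for sp in sorted(tree.leaf_ids()):
        contigs: dict[str, str] = {}
        lines = ["##gff-version 3"]
        canon_id = f"{sp}_h2a"
        ctg, feats = _place_gene(
            gene_id=canon_id,
            contig_id=f"{sp}_ctg1",
            coding=canon_at[sp] + "TAA",
            offsets=[],
            strand="+",
            config=config,
            rng=rng,
        )
        contigs[f"{sp}_ctg1"] = ctg
        lines.extend(feats)
        intron_offsets[canon_id] = []

        if presence[sp]:
            var_id = f"{sp}_var"
            ctg, feats = _place_gene(
                gene_id=var_id,
                contig_id=f"{sp}_ctg2",
                coding=variant_at[sp] + "TAA",
                offsets=offsets,
                strand="+",
                config=config,
                rng=rng,
            )
            contigs[f"{sp}_ctg2"] = ctg
            intron_offsets[var_id] = list(offsets)
            if rng.random() < config.annotation_dropout_prob:
                dropouts.append(sp)
            else:
                lines.extend(feats)
        genomes[sp] = contigs
        gff3[sp] = "\n".join(lines) + "\n"

    truth = SimulationTruth(
        presence=presence,
        origin_node=birth,
        loss_edges=sorted(real_losses),
        intron_offsets=intron_offsets,
        dropouts=dropouts,
    )
    return SimulationOutput(
        genomes=genomes, gff3=gff3, newick=newick, truth=truth, config=config
    )


def _branch_lengths(tree) -> dict[str, float]:
    out: dict[str, float] = {}
    for nid in tree.node_ids():
        node = tree._node_of[nid]
        out[nid] = node.edge.length if node.edge.length is not None else 1.0
    return out


def _random_flank(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(4, size=n)])


def _place_gene(
    gene_id: str,
    contig_id: str,
    coding: str,
    offsets: list[int],
    strand: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, list[str]]:
    """Lay one gene (with introns at the given coding offsets) on a contig.

    Returns the contig sequence (with >= flank nt of random sequence on both
    sides) and the gene/mRNA/CDS GFF3 lines (1-based inclusive coordinates).
    """
    pieces: list[str] = []
    exon_bounds: list[tuple[int, int]] = []  # transcript-region coords
    prev = 0
    pos = 0
    for off in offsets:
        exon = coding[prev:off]
        pieces.append(exon)
        exon_bounds.append((pos, pos + len(exon)))
        pos += len(exon)
        intron = "GT" + _random_flank(config.intron_length - 4, rng) + "AG"
        pieces.append(intron)
        pos += len(intron)
        prev = off
    exon = coding[prev:]
    pieces.append(exon)
    exon_bounds.append((pos, pos + len(exon)))
    region = "".join(pieces)
    lr = len(region)
    if strand == "-":
        region = str(Seq(region).reverse_complement())
        exon_bounds = [(lr - e, lr - s) for s, e in exon_bounds]
    flank5 = _random_flank(config.flank, rng)
    flank3 = _random_flank(config.flank, rng)
    contig = flank5 + region + flank3
    g0 = len(flank5)

    segs = sorted((g0 + s, g0 + e) for s, e in exon_bounds)
    gstart, gend = segs[0][0] + 1, segs[-1][1]
    lines = [
        f"{contig_id}\tsim\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gene_id}",
        f"{contig_id}\tsim\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\t"
        f"ID={gene_id}.t1;Parent={gene_id}",
    ]
    for s, e in segs:
        lines.append(
            f"{contig_id}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t.\t"
            f"ID={gene_id}.cds;Parent={gene_id}.t1"
        )
    return contig, lines


# ---------------------------------------------------------------------------
# the worked-example fixture


_WORKED_EXAMPLE_SEED = 20240


def make_worked_example_fixture() -> SimulationOutput:
    """Deterministic four-gene fixture mirroring the classic worked example.

    One intronless canonical H2A plus three variant genes with a single
    intron each, at coding offsets 78 (phase 0, between codons 26/27 —
    HTAS-1-like, placed on the minus strand), 170 (phase 2, inside codon 57
    — H2A.Z-like) and 150 (phase 0, between codons 50/51 — HIS-35-like).
    The canonical CDS embeds the flanking contexts AG|GC at offset 78,
    CT|GG at offset 170 and CA|GT at offset 150, so protosplice scoring on
    this fixture reproduces the three qualitative calls (signal, none,
    signal).
    """
    rng = np.random.default_rng(_WORKED_EXAMPLE_SEED)
    config = SimulationConfig(seed=_WORKED_EXAMPLE_SEED, n_codons=129, flank=500)
    coding = _random_coding(129, rng)  # 387 nt coding; 390 with stop
    coding = _force_motif(coding, 78, "AGGC", rng)
    coding = _force_motif(coding, 170, "CTGG", rng)
    coding = _force_motif(coding, 150, "CAGT", rng)

    sp = "celegans"
    spec_genes = [
        ("ce_h2a", [], "+"),
        ("ce_htas1", [78], "-"),
        ("ce_htz1", [170], "+"),
        ("ce_his35", [150], "+"),
    ]
    contigs: dict[str, str] = {}
    lines = ["##gff-version 3"]
    intron_offsets: dict[str, list[int]] = {}
    for i, (gid, offs, strand) in enumerate(spec_genes, start=1):
        gene_coding = coding if gid == "ce_h2a" else evolve_cds(coding, 0.02, rng)
        ctg, feats = _place_gene(
            gene_id=gid,
            contig_id=f"{sp}_ctg{i}",
            coding=gene_coding + "TAA",
            offsets=offs,
            strand=strand,
            config=config,
            rng=rng,
        )
        contigs[f"{sp}_ctg{i}"] = ctg
        lines.extend(feats)
        intron_offsets[gid] = list(offs)

    truth = SimulationTruth(
        presence={sp: True},
        origin_node=sp,
        loss_edges=[],
        intron_offsets=intron_offsets,
        dropouts=[],
    )
    return SimulationOutput(
        genomes={sp: contigs},
        gff3={sp: "\n".join(lines) + "\n"},
        newick=f"({sp});",
        truth=truth,
        config=config,
    )
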