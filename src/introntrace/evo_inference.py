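"""Gain/loss and ancestral-state inference on species trees.

An intron-position class (or a variant gene) is treated as a Dollo
character: it arises exactly once and can only be lost thereafter. Under
that constraint the parsimony optimum is fully determined — the origin is
the most recent common ancestor of the species carrying the character
(any deeper origin only adds losses), and the losses are the maximal
clades inside the origin clade whose sampled species all lack it. Species
scored "unknown" (no usable annotation) are excluded from the loss count
but reported separately, so results come as a point count plus an upper
bound ("some 5 times" vs "up to six").

Also provided: single-column Fitch ancestral-state reconstruction (for
questions like which residue is ancestral at an alignment position),
pairwise sequence difference enumeration, a deterministic neighbor-joining
utility for small test trees, the per-exon paralog-monophyly screen for
concerted evolution, and the Welch one-tailed t-test used to ask whether
inferred losses merely track poor genome assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .intron_projection import AlignedFamily, AlignedIntronClass

__all__ = [
    "SpeciesTree",
    "PresencePattern",
    "DolloResult",
    "FitchResult",
    "InferenceError",
    "dollo_reconstruct",
    "count_independent_losses",
    "fitch_site_ancestral",
    "pairwise_differences",
    "nj_tree",
    "paralog_monophyly_test",
    "split_alignment_by_exon",
    "welch_one_tailed_t",
    "quality_loss_test",
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
]

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"


class InferenceError(ValueError):
    pass


class SpeciesTree:
    """A rooted species (or gene) tree with stable node ids.

    Thin wrapper over a dendropy tree. Leaves are identified by their taxon
    label; internal nodes by their Newick label when present, else by an
    assigned preorder id ``N<k>`` (deterministic for a given topology).
    Multifurcations are allowed.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._id_of: dict[dendropy.Node, str] = {}
        self._node_of: dict[str, dendropy.Node] = {}
        counter = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if label is None:
                    raise InferenceError("unlabeled leaf in tree")
            else:
                label = node.label
                if label is None:
                    counter += 1
                    label = f"N{counter}"
            if label in self._node_of:
                raise InferenceError(f"duplicate node label {label!r}")
            self._id_of[node] = label
            self._node_of[label] = node

    # -- construction / serialization --------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree)

    def to_newick(self, include_internal_labels: bool = True) -> str:
        tree = self._tree
        if include_internal_labels:
            for node in tree.preorder_node_iter():
                if not node.is_leaf() and node.label is None:
                    node.label = self._id_of[node]
        return tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # -- queries ------------------------------------------------------------

    @property
    def root_id(self) -> str:
        return self._id_of[self._tree.seed_node]

    def leaf_ids(self) -> list[str]:
        return [self._id_of[n] for n in self._tree.leaf_node_iter()]

    def node_ids(self) -> list[str]:
        return [self._id_of[n] for n in self._tree.preorder_node_iter()]

    def is_leaf(self, node_id: str) -> bool:
        return self._node_of[node_id].is_leaf()

    def children(self, node_id: str) -> list[str]:
        return [self._id_of[c] for c in self._node_of[node_id].child_nodes()]

    def parent(self, node_id: str) -> str | None:
        p = self._node_of[node_id].parent_node
        return self._id_of[p] if p is not None else None

    def leaves_under(self, node_id: str) -> list[str]:
        node = self._node_of[node_id]
        if node.is_leaf():
            return [self._id_of[node]]
        return [self._id_of[n] for n in node.leaf_iter()]

    def mrca(self, leaf_ids: Iterable[str]) -> str:
        ids = list(leaf_ids)
        if not ids:
            raise InferenceError("mrca of empty set")
        paths = []
        for lid in ids:
            node = self._node_of[lid]
            path = []
            while node is not None:
                path.append(node)
                node = node.parent_node
            paths.append(path[::-1])  # root -> leaf
        mrca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return self._id_of[mrca]

    def postorder_ids(self) -> list[str]:
        return [self._id_of[n] for n in self._tree.postorder_node_iter()]

    def root_path(self, node_id: str) -> list[str]:
        """Node ids from this node up to the root (inclusive)."""
        out = [node_id]
        p = self.parent(node_id)
        while p is not None:
            out.append(p)
            p = self.parent(p)
        return out


@dataclass
class PresencePattern:
    """Per-species presence/absence of one character (intron class or gene)."""

    character_id: str
    state: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.state.values()} - {PRESENT, ABSENT, UNKNOWN}
        if bad:
            raise InferenceError(f"bad states {bad}")

    @classmethod
    def from_symbols(cls, character_id: str, symbols: Mapping[str, str]) -> "PresencePattern":
        """Build from the TSV dialect 1/0/? (also accepts +/-)."""
        trans = {"1": PRESENT, "+": PRESENT, "0": ABSENT, "-": ABSENT, "?": UNKNOWN}
        return cls(character_id, {k: trans[str(v)] for k, v in symbols.items()})


@dataclass
class DolloResult:
    """Single-gain reconstruction: origin node, loss edges, counts.

    ``loss_edges`` holds the child node id of each loss edge. ``n_losses``
    excludes unknown-only clades; ``n_losses_upper`` counts unknowns as
    losses (merging adjacent clades where that applies). ``ambiguous`` is
    True when unknown species make the two counts differ.
    """

    character_id: str
    origin_node: str
    loss_edges: frozenset[str]
    n_losses: int
    n_losses_upper: int
    possible_loss_edges: frozenset[str]
    ambiguous: bool


def dollo_reconstruct(tree: SpeciesTree, pattern: PresencePattern) -> DolloResult:
    """Reconstruct a single-gain / minimum-loss history for one character.

    Origin = MRCA of present leaves. Losses = maximal subtrees inside the
    origin clade containing no present leaf and at least one absent leaf;
    each such subtree is one independent loss regardless of how many
    species it holds. Unknown-only subtrees are reported as possible
    losses, not counted.
    """
    leaves = set(tree.leaf_ids())
    missing = leaves - set(pattern.state)
    if missing:
        raise InferenceError(f"no state for species {sorted(missing)}")
    present = sorted(s for s in leaves if pattern.state[s] == PRESENT)
    if not present:
        raise InferenceError(
            f"character {pattern.character_id}: no present species — nothing to place"
        )
    origin = tree.mrca(present)

    loss_edges: set[str] = set()
    possible: set[str] = set()

    def subtree_summary(node_id: str) -> tuple[bool, bool]:
        """(has_present, has_absent) among known leaves under node."""
        has_p = has_a = False
        for leaf in tree.leaves_under(node_id):
            st = pattern.state[leaf]
            if st == PRESENT:
                has_p = True
            elif st == ABSENT:
                has_a = True
        return has_p, has_a

    def walk(node_id: str) -> None:
        has_p, has_a = subtree_summary(node_id)
        if has_p:
            for child in tree.children(node_id):
                walk(child)
        elif has_a:
            loss_edges.add(node_id)
        else:  # unknown-only subtree
            possible.add(node_id)

    for child in tree.children(origin):
        walk(child)
    n_losses = len(loss_edges)

    # upper bound: treat unknown as absent, re-extract maximal clades
    upper_edges: set[str] = set()

    def walk_upper(node_id: str) -> None:
        has_p = any(
            pattern.state[l] == PRESENT for l in tree.leaves_under(node_id)
        )
        if has_p:
            for child in tree.children(node_id):
                walk_upper(child)
        else:
            upper_edges.add(node_id)

    for child in tree.children(origin):
        walk_upper(child)
    n_upper = len(upper_edges)

    return DolloResult(
        character_id=pattern.character_id,
        origin_node=origin,
        loss_edges=frozenset(loss_edges),
        n_losses=n_losses,
        n_losses_upper=n_upper,
        possible_loss_edges=frozenset(possible),
        ambiguous=(n_upper != n_losses),
    )


def count_independent_losses(result: DolloResult) -> int:
    """Number of independent losses: one per maximal all-absent clade."""
    return result.n_losses


# ---------------------------------------------------------------------------
# Fitch single-site ancestral states


@dataclass
class FitchResult:
    node_sets: dict[str, frozenset[str]]
    root_set: frozenset[str]
    n_changes: int
    node_assignment: dict[str, str] = field(default_factory=dict)


def fitch_site_ancestral(
    tree: SpeciesTree, tip_states: Mapping[str, str | None]
) -> FitchResult:
    """Fitch parsimony for one unordered character (e.g. one residue column).

    Tips with None/'?' are treated as the full observed state set. The
    bottom-up pass yields per-node candidate sets and the minimum mutation
    count (exact on binary trees; multifurcating nodes are folded pairwise
    in child order). A deterministic top-down pass assigns one state per
    node: the root takes the lexicographically smallest candidate, children
    inherit the parent state when possible.
    """
    observed = frozenset(
        v for v in tip_states.values() if v is not None and v != "?"
    )
    if not observed:
        raise InferenceError("no observed tip states")
    node_sets: dict[str, frozenset[str]] = {}
    changes = 0
    for nid in tree.postorder_ids():
        if tree.is_leaf(nid):
            st = tip_states.get(nid)
            node_sets[nid] = observed if st is None or st == "?" else frozenset([st])
        else:
            kids = tree.children(nid)
            acc = node_sets[kids[0]]
            for k in kids[1:]:
                inter = acc & node_sets[k]
                if inter:
                    acc = inter
                else:
                    acc = acc | node_sets[k]
                    changes += 1
            node_sets[nid] = acc
    root = tree.root_id
    assignment: dict[str, str] = {}
    for nid in tree.node_ids():  # preorder
        if nid == root:
            assignment[nid] = min(node_sets[nid])
        else:
            parent_state = assignment[tree.parent(nid)]
            assignment[nid] = (
                parent_state if parent_state in node_sets[nid] else min(node_sets[nid])
            )
    return FitchResult(
        node_sets=node_sets,
        root_set=node_sets[root],
        n_changes=changes,
        node_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# pairwise differences


def pairwise_differences(
    seq1: str, seq2: str
) -> tuple[list[tuple[int, str, str]], float]:
    """Enumerate residue differences between two aligned sequences.

    Positions are 1-based alignment coordinates. Percent identity is
    matches / aligned non-gap pairs (columns where both sequences have a
    residue); columns with a gap in either sequence are excluded from both
    the difference list and the denominator. Returns 0.0 identity when no
    columns are comparable.
    """
    if len(seq1) != len(seq2):
        raise InferenceError(
            f"aligned sequences differ in length ({len(seq1)} vs {len(seq2)})"
        )
    diffs: list[tuple[int, str, str]] = []
    matches = 0
    compared = 0
    for i, (a, b) in enumerate(zip(seq1.upper(), seq2.upper()), start=1):
        if a == "-" or b == "-":
            continue
        compared += 1
        if a == b:
            matches += 1
        else:
            diffs.append((i, a, b))
    pct = 100.0 * matches / compared if compared else 0.0
    return diffs, pct


# ---------------------------------------------------------------------------
# neighbor joining (internal small-tree utility)


def nj_tree(
    distance_matrix: "pd.DataFrame | np.ndarray",
    labels: Sequence[str] | None = None,
) -> str:
    """Neighbor joining with a fixed lexicographic tie-break; returns Newick.

    An internal utility for building small deterministic trees (e.g. for
    the per-exon concerted-evolution screen); not a substitute for
    model-based phylogenetics. Ties in the Q criterion are broken by the
    lexicographically smallest label pair, so the output is a pure function
    of the input matrix.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        d = distance_matrix.to_numpy(dtype=float)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        if labels is None:
            raise InferenceError("labels required with a bare matrix")
        labels = list(labels)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise InferenceError("distance matrix shape/label mismatch")
    if not np.allclose(d, d.T):
        raise InferenceError("distance matrix not symmetric")
    if not np.allclose(np.diag(d), 0):
        raise InferenceError("distance matrix diagonal not zero")
    if n < 3:
        raise InferenceError("need at least 3 taxa")

    # working copies; nodes carry their newick representation
    dist: dict[tuple[str, str], float] = {}
    active = list(labels)
    for i in range(n):
        for j in range(n):
            dist[(labels[i], labels[j])] = float(d[i, j])
    newick_of = {lab: lab for lab in labels}

    def dget(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(a, b)]

    joined = 0
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dget(a, b) for b in active) for a in active}
        best_pair = None
        best_q = None
        for a, b in _lex_pairs(active):
            q = (r - 2) * dget(a, b) - totals[a] - totals[b]
            if best_q is None or q < best_q - 1e-12:
                best_q, best_pair = q, (a, b)
        a, b = best_pair  # type: ignore[misc]
        va = 0.5 * dget(a, b) + (totals[a] - totals[b]) / (2 * (r - 2))
        vb = dget(a, b) - va
        joined += 1
        new = f"__nj{joined}"
        newick_of[new] = (
            f"({newick_of[a]}:{va:.10g},{newick_of[b]}:{vb:.10g})"
        )
        for c in active:
            if c in (a, b):
                continue
            dn = 0.5 * (dget(a, c) + dget(b, c) - dget(a, b))
            dist[(new, c)] = dist[(c, new)] = dn
        active = [c for c in active if c not in (a, b)] + [new]

    a, b, c = sorted(active, key=lambda x: (x.startswith("__nj"), x))
    la = 0.5 * (dget(a, b) + dget(a, c) - dget(b, c))
    lb = 0.5 * (dget(a, b) + dget(b, c) - dget(a, c))
    lc = 0.5 * (dget(a, c) + dget(b, c) - dget(a, b))
    return (
        f"({newick_of[a]}:{la:.10g},{newick_of[b]}:{lb:.10g},"
        f"{newick_of[c]}:{lc:.10g});"
    )


def _lex_pairs(items: list[str]):
    srt = sorted(items)
    for i in range(len(srt)):
        for j in range(i + 1, len(srt)):
            yield srt[i], srt[j]


# ---------------------------------------------------------------------------
# concerted evolution screen


def paralog_monophyly_test(
    gene_tree: SpeciesTree,
    species_of: Mapping[str, str],
    paralog_pairs: Mapping[str, tuple[str, str]],
) -> dict[str, str]:
    """Ask, per species, whether its two paralogs form a cherry.

    Concerted evolution (gene conversion) homogenizes same-species paralogs,
    pulling them together on gene trees; orthologous evolution keeps each
    paralog with its own ortholog clade. "together" = the pair is a cherry
    (shares a parent whose children are exactly these two leaves); "apart" =
    both present but not a cherry; "undetermined" = a member is missing.
    """
    tips = set(gene_tree.leaf_ids())
    out: dict[str, str] = {}
    for species in sorted(paralog_pairs):
        g1, g2 = paralog_pairs[species]
        if g1 not in tips or g2 not in tips:
            out[species] = "undetermined"
            continue
        p1, p2 = gene_tree.parent(g1), gene_tree.parent(g2)
        if p1 == p2 and p1 is not None and set(gene_tree.children(p1)) == {g1, g2}:
            out[species] = "together"
        else:
            out[species] = "apart"
    return out


def split_alignment_by_exon(
    family: AlignedFamily, intron_class: AlignedIntronClass
) -> tuple[AlignedFamily, AlignedFamily]:
    """Split an alignment at an intron class into exon-1 / exon-2 blocks.

    Columns up to and including the class column go to exon 1 (a phase-0
    intron sits after its upstream codon; a phase-1/2 intron's interrupted
    codon is assigned to exon 1 by convention), the rest to exon 2.
    """
    col = intron_class.column
    if col < 1 or col > family.n_columns:
        raise InferenceError(
            f"class column {col} outside alignment (1..{family.n_columns})"
        )
    exon1 = {g: row[:col] for g, row in family.alignment.items()}
    exon2 = {g: row[col:] for g, row in family.alignment.items()}
    return (
        AlignedFamily(alignment=exon1, source=family.source),
        AlignedFamily(alignment=exon2, source=family.source),
    )


# ---------------------------------------------------------------------------
# loss-vs-assembly-quality test


def welch_one_tailed_t(
    values_loss_group: Sequence[float],
    values_other_group: Sequence[float],
    alternative: str,
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, one-tailed.

    ``alternative='less'`` tests whether the loss group's mean is smaller
    (e.g. lower BUSCO completeness), ``'greater'`` the reverse. Returns
    (t, Welch–Satterthwaite df, one-tailed p).
    """
    if alternative not in {"less", "greater"}:
        raise InferenceError(f"alternative must be less/greater, got {alternative!r}")
    a = np.asarray(values_loss_group, dtype=float)
    b = np.asarray(values_other_group, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InferenceError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise InferenceError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def quality_loss_test(
    quality: pd.DataFrame,
    loss_species: Iterable[str],
    completeness_col: str = "completeness",
    missing_col: str = "missing",
    species_col: str = "species",
) -> dict[str, tuple[float, float, float]]:
    """Do species with inferred losses have poorer assemblies?

    Runs the one-tailed Welch test in the direction that would indict
    assembly quality: lower completeness ('less') and more missing genes
    ('greater') in the loss group. Returns {metric: (t, df, p)}.
    """
    loss = set(loss_species)
    in_loss = quality[species_col].isin(loss)
    if in_loss.sum() < 2 or (~in_loss).sum() < 2:
        raise InferenceError("need >= 2 species per group in quality table")
    out = {}
    out["completeness"] = welch_one_tailed_t(
        quality.loc[in_loss, completeness_col],
        quality.loc[~in_loss, completeness_col],
        alternative="less",
    )
    out["missing"] = welch_one_tailed_t(
        quality.loc[in_loss, missing_col],
        quality.loc[~in_loss, missing_col],
        alternative="greater",
    )
    return out
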