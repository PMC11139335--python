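"""Homolog-set reduction: length filter, identity collapse, e-value filter.

Histone gene families recovered by similarity search carry duplicates
(core histones are multi-copy and often identical) and spurious long hits.
This module reduces a candidate set the way a histone-family survey does:
drop proteins longer than a histone-plausible cutoff, collapse records that
are identical at the protein level *and* share the same intron positions
(distinct intron layouts are kept apart — gene structure is the signal),
and apply the similarity-search e-value cutoff.

All filters are idempotent, order-invariant (collapse representatives are
the lexicographically smallest gene id) and only ever shrink the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .gene_structure import AnnotatedProtein

log = logging.getLogger(__name__)

__all__ = ["HomologSet", "length_filter", "collapse_identical", "evalue_filter"]


@dataclass
class HomologSet:
    """A candidate homolog collection with optional search provenance.

    ``provenance`` maps gene_id -> e-value from the similarity search that
    produced the candidate (absent for records added by other routes).
    ``collapsed_members`` maps a representative gene_id -> all member ids it
    stands for (populated by :func:`collapse_identical`).
    """

    records: list[AnnotatedProtein]
    provenance: dict[str, float] = field(default_factory=dict)
    collapsed_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_ids in HomologSet")

    def __len__(self) -> int:
        return len(self.records)

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]


def length_filter(homologs: HomologSet, max_aa: int = 200) -> HomologSet:
    """Drop records whose protein is longer than ``max_aa`` residues.

    "More than ``max_aa``" is strict: a protein of exactly ``max_aa``
    residues is kept.
    """
    kept = [r for r in homologs.records if len(r.aa_sequence) <= max_aa]
    removed = [r.gene_id for r in homologs.records if len(r.aa_sequence) > max_aa]
    if removed:
        log.info("length_filter removed %d records: %s", len(removed), removed)
    return replace(
        homologs,
        records=kept,
        provenance={k: v for k, v in homologs.provenance.items()},
    )


def collapse_identical(homologs: HomologSet, level: str = "protein") -> HomologSet:
    """Collapse redundant records to one representative each.

    level='protein': records sharing both the amino-acid sequence and the
    exact intron coding offsets collapse together (identical protein with a
    *different* intron layout stays separate). level='nucleotide': one
    record per distinct CDS nucleotide sequence.

    The representative is the lexicographically smallest gene_id of the
    group; all member ids are recorded in ``collapsed_members``.
    """
    if level not in {"protein", "nucleotide"}:
        raise ValueError(f"unknown collapse level {level!r}")
    groups: dict[object, list[AnnotatedProtein]] = {}
    for r in homologs.records:
        if level == "protein":
            key: object = (r.aa_sequence, tuple(i.coding_offset for i in r.introns))
        else:
            if r.cds is None:
                key = ("__no_cds__", r.gene_id)
            else:
                key = r.cds
        groups.setdefault(key, []).append(r)

    reps: list[AnnotatedProtein] = []
    members: dict[str, list[str]] = dict(homologs.collapsed_members)
    for group in groups.values():
        group.sort(key=lambda r: r.gene_id)
        rep = group[0]
        merged: list[str] = []
        for g in group:
            merged.extend(members.pop(g.gene_id, [g.gene_id]))
        members[rep.gene_id] = sorted(merged)
        reps.append(rep)
    reps.sort(key=lambda r: r.gene_id)
    return HomologSet(
        records=reps,
        provenance=dict(homologs.provenance),
        collapsed_members=members,
    )


def evalue_filter(homologs: HomologSet, max_evalue: float = 1e-10) -> HomologSet:
    """Keep records whose search e-value is <= ``max_evalue`` (inclusive).

    Records without provenance pass with a warning: they were not produced
    by the similarity search being thresholded.
    """
    kept = []
    missing = []
    for r in homologs.records:
        ev = homologs.provenance.get(r.gene_id)
        if ev is None:
            missing.append(r.gene_id)
            kept.append(r)
        elif ev <= max_evalue:
            kept.append(r)
    if missing:
        log.warning("evalue_filter: no provenance for %s, retained", missing)
    return replace(homologs, records=kept, provenance=dict(homologs.provenance))
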