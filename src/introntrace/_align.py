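"""Deterministic progressive protein aligner for fixtures and simulations.

Alignment production in the pipeline is pluggable: real analyses should feed
an externally computed aligned FASTA (MAFFT, CLUSTAL, ...). This module is
the internal fallback — a progressive Needleman–Wunsch/Gotoh aligner with a
fixed BLOSUM62 matrix and affine gaps, adding sequences one at a time (in
lexicographic gene-id order) to a growing profile. Traceback ties break
toward the diagonal, then toward consuming the profile column, so output is
a pure function of the input sequences.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BL62 = substitution_matrices.load("BLOSUM62")
_ALPHA = "".join(_BL62.alphabet)
_IDX = {c: i for i, c in enumerate(_ALPHA)}
_S = np.array(_BL62, dtype=float)

GAP_OPEN = -10.0
GAP_EXTEND = -1.0

__all__ = ["align_progressive", "GAP_OPEN", "GAP_EXTEND"]


def _encode(seq: str) -> np.ndarray:
    x_idx = _IDX["X"]
    return np.array([_IDX.get(c, x_idx) for c in seq.upper()], dtype=int)


def _profile_freq(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies over non-gap characters (L x alphabet)."""
    length = len(rows[0])
    freq = np.zeros((length, len(_ALPHA)))
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                freq[j, _IDX.get(c, _IDX["X"])] += 1
    totals = freq.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return freq / totals


_M, _IX, _IY = 0, 1, 2  # match, gap-in-j (consume i), gap-in-i (consume j)


def _gotoh(score: np.ndarray) -> list[tuple[int, int]]:
    """Global affine-gap DP over a precomputed (n x m) match-score matrix.

    Returns the aligned path as (i, j) steps where i or j = -1 marks a gap
    in that dimension. Ties prefer the diagonal, then consuming i (the
    existing profile), then consuming j — fixed so output is deterministic.
    The DP is banded around the diagonal (band >= 15 plus the length
    difference), which is exact for the near-length-matched families this
    internal aligner serves.
    """
    n, m = score.shape
    band = abs(n - m) + 15
    neg = -1e30
    val = np.full((3, n + 1, m + 1), neg)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)  # predecessor state
    val[_M, 0, 0] = 0.0
    for i in range(1, min(n, band) + 1):
        val[_IX, i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
        ptr[_IX, i, 0] = _IX if i > 1 else _M
    for j in range(1, min(m, band) + 1):
        val[_IY, 0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
        ptr[_IY, 0, j] = _IY if j > 1 else _M
    for i in range(1, n + 1):
        si = score[i - 1]
        jlo = max(1, i - band)
        jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            # M: tie-break order M > IX > IY via strict > comparisons
            best_s, best_v = _M, val[_M, i - 1, j - 1]
            if val[_IX, i - 1, j - 1] > best_v:
                best_s, best_v = _IX, val[_IX, i - 1, j - 1]
            if val[_IY, i - 1, j - 1] > best_v:
                best_s, best_v = _IY, val[_IY, i - 1, j - 1]
            val[_M, i, j] = best_v + si[j - 1]
            ptr[_M, i, j] = best_s
            # IX: open from M or extend
            a = val[_M, i - 1, j] + GAP_OPEN
            b = val[_IX, i - 1, j] + GAP_EXTEND
            if a >= b:
                val[_IX, i, j], ptr[_IX, i, j] = a, _M
            else:
                val[_IX, i, j], ptr[_IX, i, j] = b, _IX
            # IY
            a = val[_M, i, j - 1] + GAP_OPEN
            b = val[_IY, i, j - 1] + GAP_EXTEND
            if a >= b:
                val[_IY, i, j], ptr[_IY, i, j] = a, _M
            else:
                val[_IY, i, j], ptr[_IY, i, j] = b, _IY
    state, best = _M, val[_M, n, m]
    if val[_IX, n, m] > best:
        state, best = _IX, val[_IX, n, m]
    if val[_IY, n, m] > best:
        state = _IY
    path: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == _M:
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == _IX:
            path.append((i - 1, -1))
            i -= 1
        else:
            path.append((-1, j - 1))
            j -= 1
        state = prev
    path.reverse()
    return path


def align_progressive(sequences: dict[str, str]) -> dict[str, str]:
    """Align protein sequences progressively; returns gene_id -> gapped row."""
    if not sequences:
        return {}
    order = sorted(sequences)
    if len(order) == 1:
        return {order[0]: sequences[order[0]]}
    rows: dict[str, str] = {order[0]: sequences[order[0]]}
    for gid in order[1:]:
        rows = _add_to_profile(rows, gid, sequences[gid])
    return rows


def _add_to_profile(rows: dict[str, str], gid: str, seq: str) -> dict[str, str]:
    row_list = list(rows.values())
    freq = _profile_freq(row_list)  # (Lp, A)
    enc = _encode(seq)
    score = (freq @ _S)[:, enc]  # (Lp, Ls); all-gap columns score 0
    path = _gotoh(score)
    new_rows = {g: [] for g in rows}
    new_seq: list[str] = []
    for i, j in path:
        for g, r in rows.items():
            new_rows[g].append(r[i] if i >= 0 else "-")
        new_seq.append(seq[j] if j >= 0 else "-")
    out = {g: "".join(chars) for g, chars in new_rows.items()}
    out[gid] = "".join(new_seq)
    return out
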