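"""Pairwise and progressive multiple alignment primitives.

Pairwise alignment is delegated to :class:`Bio.Align.PairwiseAligner`; the
progressive profile aligner (guide tree + profile-profile Gotoh) is built on
top of it with the family-alignment scoring scheme: match 2, mismatch -1,
gap open -5, gap extend -1 (a gap of length L costs 5 + (L-1)).
"""

from __future__ import annotations

from collections import Counter
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"

MATCH, MISMATCH = 2.0, -1.0
GAP_OPEN, GAP_EXTEND = -5.0, -1.0


@lru_cache(maxsize=None)
def blosum62() -> substitution_matrices.Array:
    return substitution_matrices.load("BLOSUM62")


def protein_local_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    """Smith-Waterman aligner with BLOSUM62 (the matrix's '*' column scores
    STOP-containing frames at -4 against every residue)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = blosum62()
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _simple_aligner(mode: str, end_gap_free: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    if end_gap_free:
        _free_end_gaps(aligner)
    return aligner


def _free_end_gaps(aligner: Align.PairwiseAligner) -> None:
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0


def global_align(a: str, b: str, end_gap_free: bool = False) -> tuple[str, str]:
    """Needleman-Wunsch; returns the two gapped rows of the best alignment."""
    aligner = _simple_aligner("global", end_gap_free)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: identical columns / alignment length with
    terminal gap columns excluded (internal gaps count in the denominator)."""
    if a == b:
        return 1.0
    ra, rb = global_align(a, b)
    # trim columns where either row has a terminal gap
    n = len(ra)
    start = 0
    while start < n and (ra[start] == GAP or rb[start] == GAP):
        start += 1
    end = n
    while end > start and (ra[end - 1] == GAP or rb[end - 1] == GAP):
        end -= 1
    # terminal-gap runs only: a terminal gap run belongs to exactly one row
    lead = _terminal_gap_len(ra, rb, head=True)
    tail = _terminal_gap_len(ra, rb, head=False)
    lo, hi = lead, n - tail
    if hi <= lo:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if ra[i] == rb[i] and ra[i] != GAP)
    return matches / (hi - lo)


def _terminal_gap_len(ra: str, rb: str, head: bool) -> int:
    it = range(len(ra)) if head else range(len(ra) - 1, -1, -1)
    k = 0
    for i in it:
        if ra[i] == GAP or rb[i] == GAP:
            k += 1
        else:
            break
    return k


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

def _p_distance(a: str, b: str) -> float:
    ra, rb = global_align(a, b)
    comp = [(x, y) for x, y in zip(ra, rb) if x != GAP and y != GAP]
    if not comp:
        return 1.0
    return sum(1 for x, y in comp if x != y) / len(comp)


def _upgma_order(dist: np.ndarray) -> list[tuple]:
    """UPGMA merge schedule; returns a nested-tuple guide tree of leaf indices.

    Ties broken by the smallest (i, j) pair for determinism.
    """
    n = dist.shape[0]
    active = {i: (i,) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]
    next_id = n
    while len(active) > 1:
        (i, j) = min(d, key=lambda k: (d[k], k))
        new = active[i] + active[j]
        del d[(i, j)]
        si, sj = sizes[i], sizes[j]
        for k in list(active):
            if k in (i, j):
                continue
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j], sizes[i], sizes[j]
        active[next_id] = new
        sizes[next_id] = si + sj
        next_id += 1
    return active[max(active)]


def _column_counts(rows: list[str]) -> list[Counter]:
    return [Counter(c for c in col if c != GAP) for col in zip(*rows)]


def _col_score(ca: Counter, cb: Counter, na: int, nb: int) -> float:
    if not ca or not cb:
        return 0.0
    s = 0.0
    for x, cx in ca.items():
        for y, cy in cb.items():
            s += cx * cy * (MATCH if x == y else MISMATCH)
    return s / (na * nb)


def _profile_pair_align(rows_a: list[str], rows_b: list[str]) -> list[str]:
    """Profile-profile global alignment (Gotoh affine gaps)."""
    cols_a, cols_b = _column_counts(rows_a), _column_counts(rows_b)
    na, nb = len(rows_a), len(rows_b)
    m, n = len(cols_a), len(cols_b)
    NEG = -1e30
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in B (consume A column)
    Y = np.full((m + 1, n + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, n + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    ptrM = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrX = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrY = np.zeros((m + 1, n + 1), dtype=np.int8)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = _col_score(cols_a[i - 1], cols_b[j - 1], na, nb)
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + s
            ptrM[i, j] = k
            ox = (M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND)
            kx = int(np.argmax(ox))
            X[i, j] = ox[kx]
            ptrX[i, j] = kx
            oy = (M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND)
            ky = int(np.argmax(oy))
            Y[i, j] = oy[ky]
            ptrY[i, j] = ky
    # traceback
    states = (M, X, Y)
    state = int(np.argmax([M[m, n], X[m, n], Y[m, n]]))
    i, j = m, n
    path = []  # 0 diag, 1 consume A, 2 consume B
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:  # only possible at origin
                state = 1 if i > 0 else 2
                continue
            path.append(0)
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            path.append(1)
            state = 0 if (i >= 1 and ptrX[i, j] == 0) else 1
            i -= 1
        else:
            path.append(2)
            state = 0 if (j >= 1 and ptrY[i, j] == 0) else 2
            j -= 1
    path.reverse()
    out_a = [[] for _ in range(na)]
    out_b = [[] for _ in range(nb)]
    ia = ib = 0
    for step in path:
        if step == 0:
            for r in range(na):
                out_a[r].append(rows_a[r][ia])
            for r in range(nb):
                out_b[r].append(rows_b[r][ib])
            ia += 1
            ib += 1
        elif step == 1:
            for r in range(na):
                out_a[r].append(rows_a[r][ia])
            for r in range(nb):
                out_b[r].append(GAP)
            ia += 1
        else:
            for r in range(na):
                out_a[r].append(GAP)
            for r in range(nb):
                out_b[r].append(rows_b[r][ib])
            ib += 1
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def progressive_align(seqs: list[str]) -> list[str]:
    """Progressive multiple alignment.

    Guide tree: UPGMA on pairwise NW p-distances. Merge: profile-profile
    Gotoh. Output rows follow the input order; identical inputs in a
    different order give an alignment with the same column multiset.
    """
    if not seqs:
        return []
    if len(seqs) == 1:
        return list(seqs)
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i], i))
    canon = [seqs[i] for i in order]
    n = len(canon)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _p_distance(canon[i], canon[j])
    tree = _upgma_order(dist)

    def merge(node) -> tuple[list[int], list[str]]:
        if isinstance(node, int):
            return [node], [canon[node]]
        # nested tuple of leaves: rebuild structure by splitting at UPGMA shape
        # _upgma_order returns flat tuples concatenated; align incrementally
        ids: list[int] = []
        rows: list[str] = []
        for leaf in node:
            if not rows:
                ids, rows = [leaf], [canon[leaf]]
            else:
                rows = _profile_pair_align(rows, [canon[leaf]])
                ids = ids + [leaf]
        return ids, rows

    ids, rows = merge(tree)
    # map back: canon index -> original index
    out = [""] * len(seqs)
    for canon_idx, row in zip(ids, rows):
        out[order[canon_idx]] = row
    return out
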