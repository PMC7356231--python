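"""Phylogenetics and counting-based per-site selection testing.

Distances use the Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); trees are
built with Saitou-Nei neighbor joining (deterministic tie-breaks). The
per-site selection test is a SLAC-style counting test: Nei-Gojobori
fractional synonymous/nonsynonymous site and path counts, substitution
events from Fitch parsimony ancestral states, and a two-tailed binomial test
of the observed nonsynonymous fraction per codon column against its neutral
expectation q = N/(N+S), at the 0.1 significance threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import binom

from ._seq import DNA, STOP_CODONS, translate_cds

SATURATION_P = 0.75
DEFAULT_P_THRESHOLD = 0.1

SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(DNA, repeat=3)
    if "".join(c) not in STOP_CODONS
)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def jc_distance(seq_a: str, seq_b: str) -> tuple[float, bool]:
    """Jukes-Cantor distance with pairwise deletion of gap columns.

    Returns (distance, saturated); p >= 0.75 is flagged saturated and the
    distance set to inf.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    pairs = [(a, b) for a, b in zip(seq_a.upper(), seq_b.upper())
             if a in DNA and b in DNA]
    if not pairs:
        raise ValueError("no comparable (gap-free) columns")
    p = sum(1 for a, b in pairs if a != b) / len(pairs)
    if p >= SATURATION_P:
        return math.inf, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


#: Finite stand-in distance for saturated pairs when building trees.
SATURATION_CEILING = 5.0


@dataclass
class DistanceMatrix:
    taxa: tuple
    matrix: np.ndarray  # symmetric, zero diagonal
    saturated: np.ndarray | None = None  # boolean mask of capped entries

    @classmethod
    def from_alignment(cls, names: list[str], rows: list[str]) -> "DistanceMatrix":
        n = len(names)
        m = np.zeros((n, n))
        sat = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                d, is_sat = jc_distance(rows[i], rows[j])
                if is_sat:
                    d = SATURATION_CEILING
                    sat[i, j] = sat[j, i] = True
                m[i, j] = m[j, i] = d
        return cls(tuple(names), m, sat)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    children: list = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._nwk() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.6f}"


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch estimates clamped to 0.

    Ties in the Q matrix are broken toward the lexicographically smallest
    (taxon, taxon) name pair, making the topology deterministic.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    d = dm.matrix.astype(float).copy()
    active = list(range(n))
    labels = {i: dm.taxa[i] for i in range(n)}

    while len(active) > 3:
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        m = len(active)
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[i, j] - r[i] - r[j]
            key = (round(q, 12), tuple(sorted((labels[i], labels[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        k = len(nodes)
        nodes.append(parent)
        labels[k] = min(labels[i], labels[j])
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        active = [x for x in active if x not in (i, j)] + [k]

    # join the last three on a central node
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for x, lx in ((a, la), (b, lb), (c, lc)):
        nodes[x].length = max(0.0, lx)
    order = sorted((a, b, c), key=lambda x: labels[x])
    return TreeNode(children=[nodes[x] for x in order])


# ---------------------------------------------------------------------------
# Nei-Gojobori counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (N, S) sites of a sense codon.

    Per position, the synonymous fraction is computed over the single-nt
    mutations that do not create a STOP; N + S = 3 for codons with no
    STOP-adjacent mutations, less otherwise (the STOP-creating mutations are
    excluded from the denominator position-wise).
    """
    codon = codon.upper()
    if codon in STOP_CODONS or any(b not in DNA for b in codon):
        raise ValueError(f"not a sense codon: {codon}")
    aa = translate_cds(codon)
    S = 0.0
    valid_positions = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in DNA:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            valid += 1
            if translate_cds(mut) == aa:
                syn += 1
        if valid:
            S += syn / valid
            valid_positions += 1.0
    N = valid_positions - S
    return N, S


@lru_cache(maxsize=None)
def ng_path_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (nonsyn, syn) step counts over all minimal single-nt mutation
    paths between two sense codons; paths through STOPs are excluded."""
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or any(b not in DNA for b in c):
            raise ValueError(f"not a sense codon: {c}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur = codon_a
        n = s = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_cds(nxt) == translate_cds(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            totals.append((n, s))
    if not totals:  # every path passes a STOP: fall back to raw differences
        return float(len(diff)), 0.0
    n_avg = sum(t[0] for t in totals) / len(totals)
    s_avg = sum(t[1] for t in totals) / len(totals)
    return n_avg, s_avg


# ---------------------------------------------------------------------------
# Fitch parsimony events
# ---------------------------------------------------------------------------

def _fitch_site(root: TreeNode, states: dict[str, str]) -> dict[int, str]:
    """Two-pass Fitch for one nucleotide site; returns {id(node): state}.

    Ambiguous leaf characters get the full base set. Up-pass ties resolve
    toward the parent state, the root to the lexicographically smallest."""
    sets: dict[int, frozenset] = {}

    def down(node: TreeNode) -> frozenset:
        if not node.children:
            b = states[node.name]
            s = frozenset(b) if b in DNA else frozenset(DNA)
        else:
            child_sets = [down(c) for c in node.children]
            inter = frozenset.intersection(*child_sets)
            s = inter if inter else frozenset.union(*child_sets)
        sets[id(node)] = s
        return s

    down(root)
    assign: dict[int, str] = {}

    def up(node: TreeNode, parent_state: str | None):
        s = sets[id(node)]
        if parent_state is not None and parent_state in s:
            state = parent_state
        else:
            state = min(s)
        assign[id(node)] = state
        for c in node.children:
            up(c, state)

    up(root, None)
    return assign


def fitch_events(tree: TreeNode, names: list[str], rows: list[str]):
    """Per-codon-column substitution events from Fitch ancestral states.

    Returns a list (one entry per codon column) of (n, s) event totals
    summed over branches, via ng_path_counts on reconstructed parent/child
    codons. Branches whose reconstructed endpoint codon is a STOP or
    contains a gap/ambiguity are skipped for that column.
    """
    leaf_names = {lf.name for lf in tree.leaves()}
    if leaf_names != set(names):
        raise ValueError("tree leaves do not match alignment names")
    length = len(rows[0])
    if any(len(r) != length for r in rows) or length % 3:
        raise ValueError("alignment rows must share a codon-multiple length")
    seqs = dict(zip(names, rows))
    n_cols = length // 3
    # reconstruct per nucleotide site
    site_assign = []
    for site in range(length):
        states = {nm: seqs[nm][site].upper() for nm in names}
        site_assign.append(_fitch_site(tree, states))

    results = [[0.0, 0.0] for _ in range(n_cols)]

    def walk(node: TreeNode, parent: TreeNode | None):
        if parent is not None:
            for ci in range(n_cols):
                pa = "".join(site_assign[3 * ci + k][id(parent)] for k in range(3))
                ch = "".join(site_assign[3 * ci + k][id(node)] for k in range(3))
                if pa == ch:
                    continue
                if pa in STOP_CODONS or ch in STOP_CODONS:
                    continue
                if any(b not in DNA for b in pa + ch):
                    continue
                n, s = ng_path_counts(pa, ch)
                results[ci][0] += n
                results[ci][1] += s
        for c in node.children:
            walk(c, node)

    walk(tree, None)
    return [(n, s) for n, s in results]


# ---------------------------------------------------------------------------
# SLAC-style site test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSelection:
    column: int
    n_obs: float
    s_obs: float
    n_sites: float
    s_sites: float
    dnds_sign: int       # +1, -1 or 0
    p_value: float
    call: str            # positive | negative | neutral


def _column_expected_fraction(codons: list[str]) -> tuple[float, float]:
    """Mean (N, S) sites over the observed sense codons of one column."""
    Ns, Ss = [], []
    for c in codons:
        if c in STOP_CODONS or any(b not in DNA for b in c):
            continue
        N, S = ng_site_counts(c)
        Ns.append(N)
        Ss.append(S)
    if not Ns:
        return 0.0, 0.0
    return float(np.mean(Ns)), float(np.mean(Ss))


def slac_site_test(events: list[tuple], names: list[str], rows: list[str],
                   p_threshold: float = DEFAULT_P_THRESHOLD) -> list[SiteSelection]:
    """Two-tailed binomial test per codon column.

    q = N/(N+S) from the column's codons; the observed nonsynonymous count
    (rounded) out of the rounded total events is tested against q; two-
    tailed p = min(1, 2*min(upper tail, lower tail)).
    """
    n_cols = len(events)
    out = []
    for ci in range(n_cols):
        n_obs, s_obs = events[ci]
        codons = [r[3 * ci:3 * ci + 3].upper() for r in rows]
        N, S = _column_expected_fraction(codons)
        total = n_obs + s_obs
        if total <= 0 or N + S <= 0:
            out.append(SiteSelection(ci, n_obs, s_obs, N, S, 0, 1.0, "neutral"))
            continue
        q = N / (N + S)
        k = int(round(total))
        x = int(round(n_obs))
        x = min(x, k)
        upper = float(binom.sf(x - 1, k, q))  # P(X >= x)
        lower = float(binom.cdf(x, k, q))     # P(X <= x)
        p = min(1.0, 2.0 * min(upper, lower))
        frac = n_obs / total
        if p < p_threshold and frac > q:
            call, sign = "positive", 1
        elif p < p_threshold and frac < q:
            call, sign = "negative", -1
        else:
            call, sign = "neutral", 1 if frac > q else (-1 if frac < q else 0)
        out.append(SiteSelection(ci, n_obs, s_obs, N, S, sign, p, call))
    return out


def site_selection_analysis(names: list[str], rows: list[str],
                            p_threshold: float = DEFAULT_P_THRESHOLD):
    """Full per-site pipeline: JC distances -> NJ tree -> Fitch events ->
    SLAC binomial calls. Returns (tree, [SiteSelection])."""
    dm = DistanceMatrix.from_alignment(names, rows)
    tree = nj_tree(dm)
    events = fitch_events(tree, names, rows)
    return tree, slac_site_test(events, names, rows, p_threshold)
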