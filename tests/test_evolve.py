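"""Distances, neighbor joining, counting machinery, parsimony, site test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampfam._seq import DNA, STOP_CODONS, translate_cds
from ampfam.evolve import (
    DistanceMatrix,
    SENSE_CODONS,
    TreeNode,
    _fitch_site,
    fitch_events,
    jc_distance,
    ng_path_counts,
    ng_site_counts,
    nj_tree,
    slac_site_test,
)

codon_st = st.sampled_from(SENSE_CODONS)


class TestJC:
    def test_identical_zero(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == (0.0, False)

    def test_closed_form_p_01(self):
        a, b = "A" * 9 + "C", "A" * 9 + "G"
        d, sat = jc_distance(a, b)
        assert d == pytest.approx(0.10732, abs=1e-5)
        assert not sat

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = "".join(rng.choice(list(DNA), 30))
            b = "".join(rng.choice(list(DNA), 30))
            assert jc_distance(a, b) == jc_distance(b, a)

    def test_saturation_flag(self):
        d, sat = jc_distance("AAAA", "CCCC")
        assert sat and math.isinf(d)

    def test_gap_columns_pairwise_deleted(self):
        d, _ = jc_distance("AC-T", "ACG-")
        assert d == 0.0

    def test_all_gap_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            jc_distance("--", "AA")


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("a", "b", "c"),
                            np.array([[0, .2, .3], [.2, 0, .4], [.3, .4, 0]]))
        tree = nj_tree(dm)
        lengths = {lf.name: lf.length for lf in tree.leaves()}
        assert lengths == pytest.approx({"a": 0.05, "b": 0.15, "c": 0.25})

    @staticmethod
    def _tree_distances(tree):
        """Leaf-to-leaf path lengths of a TreeNode tree."""
        paths = {}

        def walk(node, acc):
            acc = acc + [node]
            if not node.children:
                paths[node.name] = acc
            for c in node.children:
                walk(c, acc)

        walk(tree, [])
        out = {}
        for x, y in itertools.combinations(sorted(paths), 2):
            px, py = paths[x], paths[y]
            shared = 0
            for a, b in zip(px, py):
                if a is b:
                    shared += 1
                else:
                    break
            d = sum(n.length for n in px[shared:]) + sum(n.length for n in py[shared:])
            out[(x, y)] = d
        return out

    def test_additive_five_taxon_exact_recovery(self):
        # known tree: ((a:.1,b:.2):.05,(c:.3,d:.1):.15,e:.4)
        a = TreeNode("a", 0.1)
        b = TreeNode("b", 0.2)
        c = TreeNode("c", 0.3)
        d = TreeNode("d", 0.1)
        e = TreeNode("e", 0.4)
        ab = TreeNode("", 0.05, [a, b])
        cd = TreeNode("", 0.15, [c, d])
        true = TreeNode("", 0.0, [ab, cd, e])
        want = self._tree_distances(true)
        taxa = ("a", "b", "c", "d", "e")
        m = np.zeros((5, 5))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i < j:
                    m[i, j] = m[j, i] = want[(x, y)]
        got = self._tree_distances(nj_tree(DistanceMatrix(taxa, m)))
        for pair, dist in want.items():
            assert got[pair] == pytest.approx(dist, abs=1e-9)

    def test_permutation_invariance_of_topology(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list(DNA), 60)) for _ in range(6)]
        names = [f"t{i}" for i in range(6)]
        base = self._tree_distances(nj_tree(DistanceMatrix.from_alignment(names, rows)))
        perm = [3, 1, 5, 0, 2, 4]
        shuf = self._tree_distances(nj_tree(DistanceMatrix.from_alignment(
            [names[i] for i in perm], [rows[i] for i in perm])))
        for pair, dist in base.items():
            assert shuf[pair] == pytest.approx(dist, abs=1e-9)

    def test_agrees_with_skbio_nj(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(9)
        rows = ["".join(rng.choice(list(DNA), 90)) for _ in range(6)]
        names = [f"t{i}" for i in range(6)]
        dm = DistanceMatrix.from_alignment(names, rows)
        ours = self._tree_distances(nj_tree(dm))
        sk_tree = sk_nj(SkDM(dm.matrix, ids=list(names)))
        for (x, y), d in ours.items():
            assert sk_tree.find(x).distance(sk_tree.find(y)) == pytest.approx(d, abs=1e-6)

    def test_fewer_than_three_taxa_raises(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


class TestSiteCounts:
    def test_known_codons(self):
        assert ng_site_counts("TTT") == pytest.approx((8 / 3, 1 / 3))
        assert ng_site_counts("ATG") == pytest.approx((3.0, 0.0))

    @given(codon_st)
    @settings(max_examples=61, deadline=None)
    def test_against_enumeration_oracle(self, codon):
        # independent oracle: enumerate the 9 single-nt mutations directly
        aa = translate_cds(codon)
        S = 0.0
        valid_pos = 0
        for pos in range(3):
            muts = [codon[:pos] + b + codon[pos + 1:]
                    for b in DNA if b != codon[pos]]
            muts = [m for m in muts if m not in STOP_CODONS]
            if muts:
                valid_pos += 1
                S += sum(translate_cds(m) == aa for m in muts) / len(muts)
        N, S_got = ng_site_counts(codon)
        assert (N, S_got) == pytest.approx((valid_pos - S, S))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng_site_counts("TAA")


class TestPathCounts:
    def test_two_step_example(self):
        assert ng_path_counts("TTT", "GTA") == pytest.approx((1.5, 0.5))

    def test_single_synonymous_step(self):
        assert ng_path_counts("TTT", "TTC") == (0.0, 1.0)

    def test_identical_codons(self):
        assert ng_path_counts("AAA", "AAA") == (0.0, 0.0)

    @given(codon_st, codon_st)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_hamming_total(self, a, b):
        n1, s1 = ng_path_counts(a, b)
        n2, s2 = ng_path_counts(b, a)
        assert (n1, s1) == pytest.approx((n2, s2))
        hamming = sum(x != y for x, y in zip(a, b))
        # total steps equal the codon Hamming distance unless a STOP pruned
        # some paths; pruning never changes the per-path step count
        assert n1 + s1 == pytest.approx(hamming)

    def test_three_step_against_enumeration_oracle(self):
        a, b = "TTT", "GCA"
        paths = []
        for order in itertools.permutations(range(3)):
            cur, n, s, ok = a, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS:
                    ok = False
                    break
                if translate_cds(nxt) == translate_cds(cur):
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                paths.append((n, s))
        want = (sum(p[0] for p in paths) / len(paths),
                sum(p[1] for p in paths) / len(paths))
        assert ng_path_counts(a, b) == pytest.approx(want)


class TestFitch:
    def _star3(self):
        a = TreeNode("a")
        b = TreeNode("b")
        c = TreeNode("c")
        return TreeNode("", 0.0, [TreeNode("", 0.0, [a, b]), c])

    def test_two_same_one_different_single_event(self):
        tree = self._star3()
        events = fitch_events(tree, ["a", "b", "c"], ["AAA", "AAA", "AAG"])
        n, s = events[0]
        assert n + s == pytest.approx(1.0)
        assert s == pytest.approx(1.0)  # AAA->AAG is synonymous (Lys)

    def test_invariant_column_no_events(self):
        tree = self._star3()
        events = fitch_events(tree, ["a", "b", "c"], ["TGT", "TGT", "TGT"])
        assert events[0] == (0.0, 0.0)

    def test_events_reach_parsimony_minimum_on_small_trees(self):
        # exhaustive oracle over internal-state assignments, 4 leaves
        rng = np.random.default_rng(11)
        leaves = [TreeNode(n) for n in "abcd"]
        inner1 = TreeNode("", 0.0, leaves[:2])
        inner2 = TreeNode("", 0.0, leaves[2:])
        tree = TreeNode("", 0.0, [inner1, inner2])
        for _ in range(20):
            states = {n: rng.choice(list(DNA)) for n in "abcd"}
            assign = _fitch_site(tree, states)
            fitch_changes = 0

            def count(node, parent_state):
                nonlocal fitch_changes
                s = assign[id(node)]
                if parent_state is not None and s != parent_state:
                    fitch_changes += 1
                for ch in node.children:
                    count(ch, s)

            count(tree, None)
            best = min(
                (int(i1 != states["a"]) + int(i1 != states["b"])
                 + int(i2 != states["c"]) + int(i2 != states["d"])
                 + int(r != i1) + int(r != i2))
                for i1 in DNA for i2 in DNA for r in DNA)
            assert fitch_changes == best

    def test_leaf_mismatch_raises(self):
        tree = self._star3()
        with pytest.raises(ValueError, match="leaves"):
            fitch_events(tree, ["a", "b", "x"], ["AAA"] * 3)


class TestSlacTest:
    def test_binomial_doubling_rule(self):
        # single column, n=5, s=0 observed, against rows whose codons give q
        tree_rows = ["AAA"] * 4
        sites = slac_site_test([(5.0, 0.0)], ["a", "b", "c", "d"], tree_rows)
        s = sites[0]
        q = s.n_sites / (s.n_sites + s.s_sites)
        upper = q ** 5
        assert s.p_value == pytest.approx(min(1.0, 2 * upper), rel=1e-9)

    def test_zero_events_neutral(self):
        sites = slac_site_test([(0.0, 0.0)], ["a", "b"], ["TGT", "TGT"])
        assert sites[0].call == "neutral"
        assert sites[0].p_value == 1.0

    def test_strong_synonymous_excess_called_negative(self):
        sites = slac_site_test([(0.0, 6.0)], ["a", "b"], ["AAA", "AAA"])
        assert sites[0].call == "negative"
        assert sites[0].p_value < 0.1
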