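"""Dereplication, classification, alignment, clustering, consensus, PAV."""

import numpy as np
import pytest

from ampfam._seq import back_translate, translate_cds
from ampfam.alignment import pairwise_identity
from ampfam.catalog import (
    CysProfile,
    GeneVariant,
    align_family,
    build_pav,
    classify_variant,
    cluster_greedy,
    consensus,
    dereplicate,
    pav_stats,
)
from ampfam.mine import GeneLocus
from ampfam.simulate import ANCESTRAL_MATURE, CYS_INDICES


def _locus(cds, ind):
    return GeneLocus(ind, f"ctg_{ind}", "+", 0, len(cds), cds, "", False, 100.0, 1.0)


def _variant(peptide=None, cds=None, carriers=("A",)):
    if cds is None:
        cds = back_translate(peptide)
    return GeneVariant("v0", cds, translate_cds(cds), tuple(carriers))


BASE = back_translate(ANCESTRAL_MATURE)


class TestDereplicate:
    def test_identical_cds_merged_with_carrier_union(self):
        loci = [_locus(BASE, i) for i in ("I0", "I1", "I2")]
        variants = dereplicate(loci)
        assert len(variants) == 1
        assert variants[0].carriers == ("I0", "I1", "I2")

    def test_single_nt_difference_kept_separate(self):
        other = "A" + BASE[1:] if BASE[0] != "A" else "C" + BASE[1:]
        variants = dereplicate([_locus(BASE, "I0"), _locus(other, "I0")])
        assert len(variants) == 2

    def test_empty_input(self):
        assert dereplicate([]) == []

    def test_id_order_deterministic(self):
        a, b = BASE, BASE[:-3]  # shorter sorts later
        variants = dereplicate([_locus(b, "I0"), _locus(a, "I1")])
        assert [v.cds for v in variants] == [a, b]


class TestClassify:
    def test_full_cysteine_array_is_conventional(self):
        assert classify_variant(_variant(ANCESTRAL_MATURE)) == "conventional"

    def test_internal_stop_is_pseudogene(self):
        cds = BASE[:36] + "TAA" + BASE[39:]
        assert classify_variant(_variant(cds=cds)) == "pseudogene"

    def test_stop_overrides_cysteine_loss(self):
        pep = list(ANCESTRAL_MATURE)
        pep[CYS_INDICES[0]] = "S"
        cds = back_translate("".join(pep))
        cds = cds[:36] + "TAA" + cds[39:]
        assert classify_variant(_variant(cds=cds)) == "pseudogene"

    def test_cys1_cys5_loss_is_pseudomyticin(self):
        pep = list(ANCESTRAL_MATURE)
        pep[CYS_INDICES[0]] = "S"
        pep[CYS_INDICES[4]] = "S"
        assert classify_variant(_variant("".join(pep))) == "pseudomyticin"

    def test_other_cys_loss_is_atypical(self):
        pep = list(ANCESTRAL_MATURE)
        pep[CYS_INDICES[1]] = "S"
        assert classify_variant(_variant("".join(pep))) == "atypical"

    def test_short_cds_raises(self):
        with pytest.raises(ValueError, match="60 nt"):
            classify_variant(_variant(cds="ATG" * 10))


class TestAlignFamily:
    def test_identical_sequences_no_gaps(self):
        rows = align_family([BASE, BASE, BASE])
        assert rows == [BASE, BASE, BASE]

    def test_clean_codon_deletion_one_gap_block(self):
        deleted = BASE[:30] + BASE[33:]
        rows = align_family([BASE, deleted])
        assert len(rows[0]) == len(BASE)
        assert rows[0] == BASE
        assert rows[1].count("-") == 3
        assert "---" in rows[1]

    def test_gaps_in_codon_multiples(self, small_family):
        _, _, truth = small_family
        seqs = sorted(set(truth.cds))[:10]
        rows = align_family(seqs)
        for r in rows:
            n = 0
            for ch in r + "X":  # sentinel flushes the final run
                if ch == "-":
                    n += 1
                else:
                    if n:
                        assert n % 3 == 0
                    n = 0

    def test_column_count_invariant_to_input_order(self, small_family):
        _, _, truth = small_family
        seqs = sorted(set(truth.cds))[:8]
        a = align_family(seqs)
        b = align_family(seqs[::-1])
        assert len(a[0]) == len(b[0])
        assert sorted(a) == sorted(b)

    def test_single_sequence_trivial(self):
        assert align_family([BASE]) == [BASE]


class TestClusterGreedy:
    def test_identical_pair_one_cluster(self):
        vs = dereplicate([_locus(BASE, "I0"), _locus(BASE, "I1")])
        assert len(cluster_greedy(vs)) == 1

    def test_ninety_percent_identity_two_clusters(self):
        rng = np.random.default_rng(3)
        other = list(BASE)
        # ~10% diverged partner
        idx = rng.choice(len(BASE), size=13, replace=False)
        for i in idx:
            other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
        other = "".join(other)
        assert pairwise_identity(BASE, other) < 0.95
        vs = dereplicate([_locus(BASE, "I0"), _locus(other, "I0")])
        assert len(cluster_greedy(vs, 0.95)) == 2

    def test_partition_property(self, small_family):
        _, _, truth = small_family
        vs = dereplicate([_locus(c, "I0") for c in set(truth.cds)])
        clusters = cluster_greedy(vs)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(v.variant_id for v in vs)

    def test_threshold_monotonicity(self, small_family):
        _, _, truth = small_family
        vs = dereplicate([_locus(c, "I0") for c in set(truth.cds)])
        counts = [len(cluster_greedy(vs, t)) for t in (1.0, 0.95, 0.8, 0.5)]
        assert counts == sorted(counts, reverse=True)

    def test_members_meet_identity_floor(self, small_family):
        _, _, truth = small_family
        vs = dereplicate([_locus(c, "I0") for c in set(truth.cds)])
        by_id = {v.variant_id: v for v in vs}
        for c in cluster_greedy(vs, 0.95):
            rep = by_id[c.representative].cds
            for m in c.members:
                assert pairwise_identity(rep, by_id[m].cds) >= 0.95

    def test_greedy_matches_stepwise_oracle(self, small_family):
        # replay the documented assignment rule with an independent loop
        _, _, truth = small_family
        vs = dereplicate([_locus(c, "I0") for c in sorted(set(truth.cds))[:10]])
        got = {c.representative: set(c.members) for c in cluster_greedy(vs, 0.95)}
        by_id = {v.variant_id: v for v in vs}
        reps: list[str] = []
        oracle: dict[str, set] = {}
        for v in sorted(vs, key=lambda v: (-len(v.cds), v.cds)):
            scored = sorted(
                ((pairwise_identity(by_id[r].cds, v.cds), r) for r in reps),
                key=lambda t: -t[0])
            if scored and scored[0][0] >= 0.95:
                oracle[scored[0][1]].add(v.variant_id)
            else:
                reps.append(v.variant_id)
                oracle[v.variant_id] = {v.variant_id}
        assert got == oracle


class TestConsensus:
    def _cluster(self, cdss):
        # distinct member variants (consensus votes once per member)
        from ampfam.catalog import Cluster
        vs = [GeneVariant(f"v{i}", c, translate_cds(c), (f"I{i}",))
              for i, c in enumerate(cdss)]
        return vs, Cluster("cl0", vs[0].variant_id,
                           tuple(v.variant_id for v in vs), 0.0)

    def test_majority_codon_wins(self):
        # second codon column {TTT, TTC, TTC} -> TTC
        vs, cl = self._cluster(["AAATTT", "AAGTTC", "AAATTC"])
        out = consensus(cl, vs)
        assert out.consensus_cds == "AAATTC"

    def test_tie_gives_ambiguous_codon_and_x(self):
        vs, cl = self._cluster(["AAATTT", "AAATTC"])
        out = consensus(cl, vs)
        assert out.consensus_cds == "AAANNN"
        assert out.consensus_peptide == "KX"

    def test_two_two_tie_is_ambiguous(self):
        vs, cl = self._cluster(["AAATTT", "AAGTTT", "AAATTC", "AAGTTC"])
        out = consensus(cl, vs)
        assert out.consensus_cds == "NNNNNN"

    def test_single_member_identity(self):
        vs, cl = self._cluster([BASE])
        out = consensus(cl, vs)
        assert out.consensus_cds == BASE

    def test_stop_codon_rendered_star(self):
        vs, cl = self._cluster(["AAATAA", "ACATAA", "AAATAA"])
        out = consensus(cl, vs)
        assert out.consensus_peptide == "K*"

    def test_empty_cluster_raises(self):
        from ampfam.catalog import Cluster
        with pytest.raises(ValueError, match="empty"):
            consensus(Cluster("c", "x", (), 0.95), [])


class TestPAV:
    def _toy(self):
        vs = [
            GeneVariant("v0", "AAATTT", "KF", ("I0", "I1", "I2")),
            GeneVariant("v1", "AAATTC", "KF", ("I1",)),
        ]
        return vs

    def test_row_frequency_and_private(self):
        vs = self._toy()
        vmat, _ = build_pav(vs, [], ["I0", "I1", "I2"])
        assert vmat.loc["v0"].sum() == 3
        stats = pav_stats(vmat)
        assert stats["n_private"] == 1
        assert stats["n_universal"] == 1
        assert list(vmat.index) == ["v0", "v1"]  # sorted by frequency

    def test_cluster_presence_is_union(self):
        from ampfam.catalog import Cluster
        vs = self._toy()
        cl = [Cluster("cl0", "v0", ("v0", "v1"), 0.95)]
        _, cmat = build_pav(vs, cl, ["I0", "I1", "I2"])
        assert cmat.loc["cl0"].all()

    def test_unknown_individual_raises(self):
        with pytest.raises(KeyError, match="unknown"):
            build_pav(self._toy(), [], ["I0", "I1"])

    def test_all_true_matrix_stats(self):
        vs = [GeneVariant(f"v{i}", "AAA", "K", ("I0", "I1", "I2", "I3"))
              for i in range(3)]
        vmat, _ = build_pav(vs, [], ["I0", "I1", "I2", "I3"])
        stats = pav_stats(vmat)
        assert stats["mean_per_individual"] == 3.0
        assert stats["n_universal"] == 3

    def test_identity_matrix_all_private(self):
        vs = [GeneVariant(f"v{i}", "AAA", "K", (f"I{i}",)) for i in range(4)]
        vmat, _ = build_pav(vs, [], [f"I{i}" for i in range(4)])
        stats = pav_stats(vmat)
        assert stats["mean_per_individual"] == 1.0
        assert stats["n_private"] == 4

    def test_matrix_matches_truth(self, small_family):
        _, _, truth = small_family
        loci = [_locus(r.cds, r.individual) for r in truth.itertuples()]
        vs = dereplicate(loci)
        individuals = sorted(truth.individual.unique())
        vmat, _ = build_pav(vs, [], individuals)
        for v in vs:
            expected = set(truth[truth.cds == v.cds].individual)
            assert set(vmat.columns[vmat.loc[v.variant_id]]) == expected
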