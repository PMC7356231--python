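"""Variant cataloguing: dereplication, ORF/cysteine classification,
family alignment, greedy identity clustering with codon consensus, and
presence/absence variation (PAV) matrices.

Classes follow the field's nomenclature for this AMP family:
``conventional`` (all 8 reference cysteines), ``pseudogene`` (in-frame STOP
before the final codon; overrides every other rule), ``pseudomyticin``
(exactly Cys1 and Cys5 missing) and ``atypical`` (any other cysteine
pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from ._seq import has_internal_stop, translate_cds
from .alignment import GAP, blosum62, pairwise_identity, progressive_align
from .mine import GeneLocus
from .simulate import ANCESTRAL_MATURE, CYS_INDICES

CLASSES = ("conventional", "pseudogene", "pseudomyticin", "atypical")


@dataclass
class GeneVariant:
    variant_id: str
    cds: str
    peptide: str
    carriers: tuple          # sorted individual ids
    class_label: str = ""


@dataclass
class Cluster:
    cluster_id: str
    representative: str      # variant id
    members: tuple           # variant ids
    threshold: float
    consensus_cds: str = ""
    consensus_peptide: str = ""


@dataclass(frozen=True)
class CysProfile:
    """Reference mature peptide and the 0-based positions of its 8 Cys."""
    reference: str = ANCESTRAL_MATURE
    cys_positions: tuple = CYS_INDICES


def dereplicate(loci: list[GeneLocus]) -> list[GeneVariant]:
    """Merge exactly identical CDSs into variants carrying the union of
    individuals; ids assigned by (length desc, lexicographic)."""
    by_cds: dict[str, set] = {}
    for locus in loci:
        by_cds.setdefault(locus.cds, set()).add(locus.individual)
    ordered = sorted(by_cds, key=lambda s: (-len(s), s))
    return [GeneVariant(f"var{i:03d}", cds, translate_cds(cds),
                        tuple(sorted(by_cds[cds])))
            for i, cds in enumerate(ordered)]


def _protein_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = blosum62()
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    from .alignment import _free_end_gaps
    _free_end_gaps(aligner)
    return aligner


def classify_variant(variant: GeneVariant, profile: CysProfile = CysProfile()) -> str:
    """STOP check first (pseudogene overrides all); then cysteine occupancy
    after global alignment of the translated peptide to the reference."""
    if len(variant.cds) < 60:
        raise ValueError(f"{variant.variant_id}: CDS shorter than 60 nt")
    if has_internal_stop(variant.cds):
        return "pseudogene"
    pep = variant.peptide.rstrip("*")
    aligner = _protein_global_aligner()
    aln = aligner.align(pep.replace("*", "X"), profile.reference)[0]
    row_pep, row_ref = str(aln[0]), str(aln[1])
    # map reference positions -> peptide residue in that column
    ref_i = 0
    occupied = {}
    for col in range(len(row_ref)):
        if row_ref[col] != GAP:
            if ref_i in profile.cys_positions:
                occupied[ref_i] = row_pep[col]
            ref_i += 1
    missing = {i for i in profile.cys_positions if occupied.get(i) != "C"}
    if not missing:
        return "conventional"
    cys1, cys5 = profile.cys_positions[0], profile.cys_positions[4]
    if missing == {cys1, cys5}:
        return "pseudomyticin"
    return "atypical"


def classify_all(variants: list[GeneVariant],
                 profile: CysProfile = CysProfile()) -> list[GeneVariant]:
    for v in variants:
        v.class_label = classify_variant(v, profile)
    return variants


def align_family(sequences: list[str], codon_aware: bool = True) -> list[str]:
    """Progressive multiple alignment of the family.

    With ``codon_aware`` the CDSs are aligned at the peptide level (internal
    STOPs as '*') and expanded back to codons, so gaps come in multiples of
    three; otherwise plain nucleotide alignment.
    """
    if not sequences:
        return []
    if len(sequences) == 1:
        return list(sequences)
    if not codon_aware:
        return progressive_align(sequences)
    peps = [translate_cds(s) for s in sequences]
    pep_rows = progressive_align(peps)
    out = []
    for cds, row in zip(sequences, pep_rows):
        codons = [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        it = iter(codons)
        out.append("".join("---" if c == GAP else next(it) for c in row))
    return out


def cluster_greedy(variants: list[GeneVariant], threshold: float = 0.95) -> list[Cluster]:
    """Greedy incremental clustering at a pairwise-identity floor.

    Variants are visited by (length desc, lexicographic); each joins the
    best-identity existing representative at identity >= threshold, else
    founds a new cluster. Identity = identical columns / global-alignment
    length with terminal gaps excluded.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0,1]")
    order = sorted(variants, key=lambda v: (-len(v.cds), v.cds))
    clusters: list[dict] = []
    for v in order:
        best, best_ident = None, -1.0
        for c in clusters:
            ident = pairwise_identity(c["rep_cds"], v.cds)
            if ident > best_ident:
                best, best_ident = c, ident
        if best is not None and best_ident >= threshold:
            best["members"].append(v.variant_id)
        else:
            clusters.append({"rep": v.variant_id, "rep_cds": v.cds,
                             "members": [v.variant_id]})
    return [Cluster(f"cl{i:03d}", c["rep"], tuple(c["members"]), threshold)
            for i, c in enumerate(clusters)]


def consensus(cluster: Cluster, variants: list[GeneVariant],
              alignment: dict[str, str] | None = None) -> Cluster:
    """Per-codon-column strict-plurality consensus of the cluster members.

    Ties give the ambiguous codon 'NNN' (peptide 'X'); all-gap codon
    columns are dropped; STOP consensus codons translate to '*'.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    by_id = {v.variant_id: v for v in variants}
    member_cds = [by_id[m].cds for m in cluster.members]
    if alignment is not None:
        rows = [alignment[m] for m in cluster.members]
    elif len(member_cds) == 1:
        rows = member_cds
    else:
        rows = align_family(member_cds, codon_aware=True)
    ncols = len(rows[0]) // 3
    cons = []
    for ci in range(ncols):
        codons = [r[3 * ci:3 * ci + 3] for r in rows]
        codons = [c for c in codons if c != "---"]
        if not codons:
            continue
        counts: dict[str, int] = {}
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            cons.append("NNN")  # no strict plurality -> ambiguous
        else:
            cons.append(ranked[0][0])
    cds = "".join(cons)
    return Cluster(cluster.cluster_id, cluster.representative, cluster.members,
                   cluster.threshold, cds, translate_cds(cds))


def build_pav(variants: list[GeneVariant], clusters: list[Cluster],
              individuals: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant-level and cluster-level boolean PAV matrices.

    Rows ordered by descending carrier frequency; cluster presence is the
    union of member presence. Unknown carrier ids raise.
    """
    known = set(individuals)
    for v in variants:
        bad = set(v.carriers) - known
        if bad:
            raise KeyError(f"{v.variant_id} carried by unknown individuals {sorted(bad)}")
    vmat = pd.DataFrame(False, index=[v.variant_id for v in variants],
                        columns=list(individuals))
    for v in variants:
        vmat.loc[v.variant_id, list(v.carriers)] = True
    by_id = {v.variant_id: v for v in variants}
    cmat = pd.DataFrame(False, index=[c.cluster_id for c in clusters],
                        columns=list(individuals))
    for c in clusters:
        carriers = set()
        for m in c.members:
            carriers |= set(by_id[m].carriers)
        cmat.loc[c.cluster_id, sorted(carriers)] = True
    order = lambda m: m.loc[m.sum(axis=1).sort_values(ascending=False, kind="stable").index]
    return order(vmat), order(cmat)


def pav_stats(pav: pd.DataFrame) -> dict:
    """Summary statistics of a boolean PAV matrix."""
    if pav.empty:
        raise ValueError("empty PAV matrix")
    n_ind = pav.shape[1]
    row_counts = pav.sum(axis=1)
    private = row_counts == 1
    occupancy = (row_counts / n_ind)
    return {
        "mean_per_individual": float(pav.sum(axis=0).mean()),
        "mean_private_per_individual": float(pav.loc[private].sum(axis=0).mean()) if private.any() else 0.0,
        "occupancy": occupancy.to_dict(),
        "n_universal": int((row_counts == n_ind).sum()),
        "n_private": int(private.sum()),
    }
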