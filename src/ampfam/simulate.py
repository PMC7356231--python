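"""Synthetic AMP gene-family generator with known ground truth.

Emulates the statistical structure of a hypervariable, multi-copy
antimicrobial-peptide family observed across resequenced individuals of one
species: per-gene presence/absence variation, private variants, 8-cysteine
mature peptides with a frozen cysteine array, pseudogenes (in-frame STOPs),
Cys1/Cys5-loss variants, per-codon-site selection pressure (omega), ordered
promoter motifs at nearly invariable positions in a 500-bp upstream region,
tissue-restricted expression and optional RNA edits.

All coordinates are 0-based half-open on the forward strand; a fixed seed
makes every output byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import DNA, STOP_CODONS, back_translate, revcomp, translate_cds

#: Designed 42-residue, 8-cysteine mature peptide ending in the conserved
#: arginine that marks the precursor cleavage point. Its composition was
#: chosen so that the conventional-family isoelectric point falls in the
#: weakly cationic 7-8 range typical of this peptide family.
ANCESTRAL_MATURE = "HPHVCTSYKGSCKFACGTACSQMFDCNRKCVCYGNCEKGRSR"

#: 0-based indices of the eight cysteines on the mature peptide.
CYS_INDICES = tuple(i for i, aa in enumerate(ANCESTRAL_MATURE) if aa == "C")

_FROZEN = set(CYS_INDICES) | {len(ANCESTRAL_MATURE) - 1}  # Cys array + C-term Arg
_PURIFYING = (6, 9, 13, 17, 21, 27, 33, 39)
_DIVERSIFYING = (8, 24, 28)


def default_omega() -> np.ndarray:
    """Per-codon nonsynonymous scaling: 0 at the frozen cysteine array and
    C-terminal Arg, 0.05 at eight purifying sites, 5.0 at three
    hypervariable sites, 1.0 elsewhere."""
    omega = np.ones(len(ANCESTRAL_MATURE))
    for i in _FROZEN:
        omega[i] = 0.0
    for i in _PURIFYING:
        omega[i] = 0.05
    for i in _DIVERSIFYING:
        omega[i] = 5.0
    return omega


DEFAULT_MOTIFS = (("CAACCACAAT", 10), ("TATTACGCAA", 10))


@dataclass(frozen=True)
class FamilyParams:
    """Study conditions for one synthetic family run.

    Defaults mirror the observed family structure: 16 individuals, a
    16-gene ancestral family at presence probability 0.70 (each individual
    carries ~11 copies, ~6 of them private once lineage substitutions are
    applied), ~7.5% pseudogenes and ~15% Cys1/Cys5-loss copies, and 500-bp
    promoters with two ordered planted motifs at nearly fixed offsets.
    """

    n_individuals: int = 16
    n_ancestral_genes: int = 16
    presence_prob: float = 0.70
    private_gene_rate: float = 0.0
    ancestral_divergence: float = 0.12
    sub_rate: float = 0.0075
    omega_by_site: tuple = field(default_factory=lambda: tuple(default_omega()))
    pseudogene_prob: float = 0.075
    cysloss_prob: float = 0.15
    expression_prob: float = 0.65
    promoter_motifs: tuple = DEFAULT_MOTIFS
    promoter_len: int = 500
    motif_jitter: int = 2
    contig_len: int = 2500
    tandem_fraction: float = 0.0
    edit_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("presence_prob", "pseudogene_prob", "cysloss_prob",
                     "expression_prob", "tandem_fraction", "edit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.pseudogene_prob + self.cysloss_prob > 1.0:
            raise ValueError("pseudogene_prob + cysloss_prob exceeds 1")
        if len(self.omega_by_site) != len(ANCESTRAL_MATURE):
            raise ValueError("omega_by_site length must equal mature-peptide codon count")
        for consensus, width in self.promoter_motifs:
            if not 6 <= width <= 30 or len(consensus) != width:
                raise ValueError("motif widths must lie in [6,30] and match consensus length")
        gene_len = 3 * len(ANCESTRAL_MATURE)
        if self.contig_len < self.promoter_len + gene_len + 20:
            raise ValueError(
                f"contig_len={self.contig_len} too small to host promoter+gene "
                f"({self.promoter_len + gene_len + 20} required)")


TRUTH_COLUMNS = [
    "individual", "copy_id", "contig", "strand", "exon3_start", "exon3_end",
    "class_label", "source_gene", "cds", "promoter_start", "promoter_end",
    "motif_offsets", "expressed", "edited_positions",
]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def mutate_cds(cds: str, rate: float, omega, rng: np.random.Generator) -> str:
    """Codon-level substitution process.

    Per nucleotide site a candidate substitution is proposed with
    probability `rate`; synonymous candidates are accepted with probability
    min(1, 1/omega), nonsynonymous with min(1, omega). Frozen codons
    (omega = 0) never substitute; candidates creating a STOP are rejected
    (pseudogene STOPs are planted explicitly, not drifted into).
    """
    codons = [list(cds[i:i + 3]) for i in range(0, len(cds), 3)]
    for ci, codon in enumerate(codons):
        w = omega[ci] if ci < len(omega) else 1.0
        if w == 0.0:
            continue
        for pos in range(3):
            if rng.random() >= rate:
                continue
            old = "".join(codon)
            alt = DNA[(DNA.index(codon[pos]) + 1 + rng.integers(0, 3)) % 4]
            cand = codon.copy()
            cand[pos] = alt
            new = "".join(cand)
            if new in STOP_CODONS:
                continue
            syn = translate_cds(new) == translate_cds(old)
            p_accept = min(1.0, 1.0 / w) if syn else min(1.0, w)
            if rng.random() < p_accept:
                codon[pos] = alt
    return "".join("".join(c) for c in codons)


def _plant_pseudogene(cds: str, rng: np.random.Generator) -> str:
    n_codons = len(cds) // 3
    ci = int(rng.integers(n_codons // 4, 3 * n_codons // 4))
    return cds[:3 * ci] + "TAA" + cds[3 * ci + 3:]


def _plant_cysloss(cds: str) -> str:
    """Replace Cys1 and Cys5 codons (TGT/TGC -> AGT/AGC, Ser)."""
    out = list(cds)
    for which in (0, 4):
        ci = CYS_INDICES[which]
        out[3 * ci] = "A"
    return "".join(out)


def _build_promoter(params: FamilyParams, rng: np.random.Generator):
    """500-bp background with the ordered motifs planted at nearly fixed
    offsets (jitter +/- motif_jitter). Returns (sequence, offsets)."""
    seq = list(_random_dna(rng, params.promoter_len))
    n = len(params.promoter_motifs)
    offsets = []
    slot = params.promoter_len // (n + 1)
    for k, (consensus, width) in enumerate(params.promoter_motifs):
        base = (k + 1) * slot - width // 2
        off = base + int(rng.integers(-params.motif_jitter, params.motif_jitter + 1))
        off = max(0, min(params.promoter_len - width, off))
        seq[off:off + width] = list(consensus)
        offsets.append(off)
    return "".join(seq), offsets


def simulate_family(params: FamilyParams):
    """Generate per-individual genomes and the truth table.

    Returns (genomes, truth) where genomes maps individual id ->
    {contig id: sequence} and truth is a DataFrame with one row per planted
    gene copy (TRUTH_COLUMNS).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    base_cds = back_translate(ANCESTRAL_MATURE)
    omega = np.asarray(params.omega_by_site, dtype=float)
    ancestors = [mutate_cds(base_cds, params.ancestral_divergence, omega, rng)
                 for _ in range(params.n_ancestral_genes)]

    genomes: dict[str, dict[str, str]] = {}
    rows = []
    gene_len = 3 * len(ANCESTRAL_MATURE)
    for ind_i in range(params.n_individuals):
        ind = f"IND{ind_i:02d}"
        contigs: dict[str, str] = {}
        copies = []  # (source_gene_label, cds)
        for g, anc in enumerate(ancestors):
            if rng.random() < params.presence_prob:
                copies.append((f"G{g:02d}", mutate_cds(anc, params.sub_rate, omega, rng)))
        n_private = rng.poisson(params.private_gene_rate)
        for p in range(n_private):
            src = int(rng.integers(0, max(1, params.n_ancestral_genes)))
            anc = ancestors[src] if ancestors else base_cds
            copies.append((f"G{src:02d}p{p}",
                           mutate_cds(anc, max(0.03, 2 * params.sub_rate), omega, rng)))
        for c, (src, cds) in enumerate(copies):
            u = rng.random()
            if u < params.pseudogene_prob:
                cds, label = _plant_pseudogene(cds, rng), "pseudogene"
            elif u < params.pseudogene_prob + params.cysloss_prob:
                cds, label = _plant_cysloss(cds), "cysloss"
            else:
                label = "conventional"
            promoter, motif_offs = _build_promoter(params, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            block = promoter + cds
            margin = params.contig_len - len(block) - 20
            insert_at = 10 + int(rng.integers(0, max(1, margin)))
            contig_seq = _random_dna(rng, params.contig_len)
            planted = block if strand == "+" else revcomp(block)
            contig_seq = contig_seq[:insert_at] + planted + contig_seq[insert_at + len(block):]
            contig = f"{ind}_ctg{c:03d}"
            contigs[contig] = contig_seq
            if strand == "+":
                e3s = insert_at + len(promoter)
                e3e = e3s + gene_len
                ps, pe = insert_at, insert_at + len(promoter)
            else:
                e3s = insert_at + len(block) - len(promoter) - gene_len
                e3e = e3s + gene_len
                ps, pe = e3e, e3e + len(promoter)
            rows.append({
                "individual": ind,
                "copy_id": f"{ind}_c{c:03d}",
                "contig": contig,
                "strand": strand,
                "exon3_start": e3s,
                "exon3_end": e3e,
                "class_label": label,
                "source_gene": src,
                "cds": cds,
                "promoter_start": ps,
                "promoter_end": pe,
                "motif_offsets": json.dumps(motif_offs),
                "expressed": bool(rng.random() < params.expression_prob),
                "edited_positions": json.dumps([]),
            })
        genomes[ind] = contigs
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return genomes, truth


def simulate_transcriptome(genome: dict[str, str], truth: pd.DataFrame,
                           expressed_flags: dict[str, bool], edit_rate: float,
                           seed: int):
    """Build a transcript multi-FASTA for one individual.

    One contig per expressed copy (the sense-strand exon-3 sequence), with
    per-position substitution edits applied at `edit_rate` and recorded back
    into the returned truth table. Flags referencing unknown copies raise.
    """
    rng = np.random.default_rng(seed)
    known = set(truth["copy_id"])
    unknown = set(expressed_flags) - known
    if unknown:
        raise KeyError(f"expression flags reference unknown copies: {sorted(unknown)}")
    truth = truth.copy()
    transcripts: dict[str, str] = {}
    for idx, row in truth.iterrows():
        flag = expressed_flags.get(row["copy_id"], False)
        truth.at[idx, "expressed"] = bool(flag)
        if not flag:
            continue
        seq = list(row["cds"])
        edited = []
        for i, b in enumerate(seq):
            if rng.random() < edit_rate:
                seq[i] = DNA[(DNA.index(b) + 1 + rng.integers(0, 3)) % 4]
                edited.append(i)
        transcripts[f"tx_{row['copy_id']}"] = "".join(seq)
        truth.at[idx, "edited_positions"] = json.dumps(edited)
    return transcripts, truth


def simulate_reads(sequence: str, read_length: int, coverage: float, seed: int):
    """Error-free reads: exact substrings of the (possibly reverse
    complemented) sequence at roughly uniform depth ~ `coverage`."""
    if read_length > len(sequence):
        raise ValueError("read_length exceeds sequence length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * len(sequence) / read_length))
    reads = []
    hi = len(sequence) - read_length
    for r in range(n_reads):
        start = int(rng.integers(0, hi + 1))
        frag = sequence[start:start + read_length]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append((f"read{r:06d}", frag))
    return reads


#: Per-branch nucleotide substitution rate for the selection-test scenario;
#: set by pilot power analysis so purifying columns accumulate enough
#: synonymous events for the counting test to resolve them.
DEFAULT_BRANCH_RATE = 0.1


def simulate_selection_alignment(n_seqs: int, omega_by_site, branch_rate: float,
                                 seed: int) -> list[str]:
    """Gap-free codon alignment evolved down a balanced binary tree.

    Each branch applies the omega-aware substitution process at
    `branch_rate` per nucleotide site; leaves inherit the cumulative
    substitutions of their path, giving the tree structure a parsimony
    reconstruction can exploit.
    """
    rng = np.random.default_rng(seed)
    omega = np.asarray(omega_by_site, dtype=float)
    root = back_translate(ANCESTRAL_MATURE)

    def grow(cds: str, n: int) -> list[str]:
        if n == 1:
            return [mutate_cds(cds, branch_rate, omega, rng)]
        left = grow(mutate_cds(cds, branch_rate, omega, rng), n // 2)
        right = grow(mutate_cds(cds, branch_rate, omega, rng), n - n // 2)
        return left + right

    return grow(root, n_seqs)


def clustering_scenario_params(seed: int) -> FamilyParams:
    """Conditions under which greedy 95%-identity clusters must coincide
    with the planted gene family: realized inter-gene divergence well above
    10% (divergence proposals 0.30) and within-gene variation below ~3%
    (lineage rate 0.003, no class planting that adds fixed differences)."""
    return FamilyParams(ancestral_divergence=0.30, sub_rate=0.003,
                        pseudogene_prob=0.0, cysloss_prob=0.0, seed=seed)


def truth_to_bed(truth: pd.DataFrame) -> str:
    """BED6 of exon-3 intervals (0-based half-open, strand column)."""
    lines = []
    for _, r in truth.iterrows():
        lines.append(f"{r['contig']}\t{r['exon3_start']}\t{r['exon3_end']}"
                     f"\t{r['copy_id']}\t0\t{r['strand']}")
    return "\n".join(lines) + ("\n" if lines else "")


def params_to_config(params: FamilyParams) -> str:
    """Flat key=value echo of the parameters."""
    lines = []
    for name in params.__dataclass_fields__:
        v = getattr(params, name)
        if isinstance(v, tuple):
            v = json.dumps(list(v))
        lines.append(f"{name}={v}")
    return "\n".join(lines) + "\n"


def with_seed(params: FamilyParams, seed: int) -> FamilyParams:
    return replace(params, seed=seed)
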