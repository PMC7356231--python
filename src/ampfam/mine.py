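"""Gene-family locus mining by six-frame translated local alignment.

A mature-peptide query is Smith-Waterman-aligned (BLOSUM62, gap open 11,
extend 1) against all six reading frames of every contig; hits above a raw
score threshold are mapped back to forward-strand nucleotide space, merged,
extended to the full query span, and their exon-3 CDS plus <=500-bp upstream
promoter extracted. STOP codons in translated frames hit the BLOSUM62 '*'
column (score -4), so pseudogenised copies are still recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp, translate_cds
from .alignment import protein_local_aligner

#: Identity floor standing in for manual hit curation.
DEFAULT_IDENTITY_MIN = 0.40
DEFAULT_SCORE_MIN = 60.0


@dataclass(frozen=True)
class LocusHit:
    contig: str
    strand: str           # '+' or '-'
    frame: int            # +1..+3 / -1..-3 (BLAST convention)
    start: int            # forward-strand, 0-based half-open
    end: int
    score: float
    identity: float       # identical residues / aligned columns vs query
    query_span: tuple     # aligned [qstart, qend) on the query


@dataclass(frozen=True)
class GeneLocus:
    individual: str
    contig: str
    strand: str
    start: int
    end: int
    cds: str              # sense-strand exon-3 CDS
    promoter: str         # sense-strand upstream slice, possibly empty
    promoter_truncated: bool
    score: float
    identity: float


def _frame_hits(pep: str, query: str, aligner, score_min: float, max_hits: int = 32):
    """Iterated best-local-hit extraction with '*' masking between rounds so
    multiple gene copies in one frame are all reported."""
    hits = []
    masked = pep
    for _ in range(max_hits):
        if not masked:
            break
        alns = aligner.align(masked, query)
        try:
            aln = alns[0]
        except IndexError:
            break
        if aln.score < score_min:
            break
        t0, t1 = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
        q0, q1 = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
        matches = cols = 0
        for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
            for k in range(te - ts):
                cols += 1
                if masked[ts + k] == query[qs + k]:
                    matches += 1
        identity = matches / cols if cols else 0.0
        hits.append((t0, t1, q0, q1, float(aln.score), identity))
        masked = masked[:t0] + "*" * (t1 - t0) + masked[t1:]
    return hits


def translated_search(contigs: dict[str, str], query_peptide: str,
                      score_min: float = DEFAULT_SCORE_MIN,
                      identity_min: float = DEFAULT_IDENTITY_MIN) -> list[LocusHit]:
    """Six-frame translated search of `query_peptide` in every contig.

    Same-frame overlapping hits are merged to their union; across frames an
    overlapping lower-scoring hit is dropped. Hits are extended to cover the
    full query span (clipped at contig edges, kept on the codon lattice).
    """
    if len(query_peptide) < 10:
        raise ValueError("query peptide shorter than 10 aa")
    if score_min <= 0:
        raise ValueError("score_min must be positive")
    aligner = protein_local_aligner()
    raw: list[LocusHit] = []
    for name, seq in contigs.items():
        seq = seq.upper()
        if any(b not in "ACGTN" for b in seq):
            raise ValueError(f"contig {name} contains non-IUPAC characters")
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for f in range(3):
                pep = translate_cds(s[f:])
                if not pep:
                    continue
                for (t0, t1, q0, q1, score, ident) in _frame_hits(
                        pep, query_peptide, aligner, score_min):
                    # extend to the full query span, on this frame's lattice
                    a0 = max(0, t0 - q0)
                    a1 = min(len(pep), t1 + (len(query_peptide) - q1))
                    nt0, nt1 = f + 3 * a0, f + 3 * a1
                    if strand == "+":
                        start, end = nt0, nt1
                        frame = f + 1
                    else:
                        start, end = L - nt1, L - nt0
                        frame = -(f + 1)
                    raw.append(LocusHit(name, strand, frame, start, end,
                                        score, ident, (q0, q1)))
    merged = _merge_hits(raw)
    return [h for h in merged if h.identity >= identity_min]


def _overlaps(a: LocusHit, b: LocusHit) -> bool:
    return a.contig == b.contig and a.start < b.end and b.start < a.end


def _merge_hits(hits: list[LocusHit]) -> list[LocusHit]:
    # union-merge same contig/strand/frame
    by_key: dict[tuple, list[LocusHit]] = {}
    for h in hits:
        by_key.setdefault((h.contig, h.strand, h.frame), []).append(h)
    pooled: list[LocusHit] = []
    for key, group in by_key.items():
        group.sort(key=lambda h: h.start)
        cur = group[0]
        for h in group[1:]:
            if h.start < cur.end:  # overlap: union, keep best score/identity
                cur = LocusHit(cur.contig, cur.strand, cur.frame,
                               min(cur.start, h.start), max(cur.end, h.end),
                               max(cur.score, h.score),
                               max(cur.identity, h.identity), cur.query_span)
            else:
                pooled.append(cur)
                cur = h
        pooled.append(cur)
    # across frames/strands: drop overlapping lower-score hits
    pooled.sort(key=lambda h: (-h.score, h.contig, h.start))
    kept: list[LocusHit] = []
    for h in pooled:
        if not any(_overlaps(h, k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start))
    return kept


def extract_locus(contig_name: str, contig_seq: str, hit: LocusHit,
                  promoter_len: int = 500, individual: str = "") -> GeneLocus:
    """Extract the sense-strand CDS and its upstream promoter for one hit."""
    if hit.end > len(contig_seq) or hit.start < 0:
        raise ValueError("hit lies outside the contig")
    start, end = hit.start, hit.end
    end -= (end - start) % 3  # codon boundary
    region = contig_seq[start:end]
    cds = region if hit.strand == "+" else revcomp(region)
    if hit.strand == "+":
        p0 = max(0, start - promoter_len)
        promoter = contig_seq[p0:start]
        truncated = start < promoter_len
    else:
        p1 = min(len(contig_seq), end + promoter_len)
        promoter = revcomp(contig_seq[end:p1])
        truncated = len(contig_seq) - end < promoter_len
    return GeneLocus(individual, contig_name, hit.strand, start, end,
                     cds, promoter, truncated, hit.score, hit.identity)


def extract_promoter(locus: GeneLocus) -> str:
    """The stored upstream slice; its last base abuts the gene start."""
    return locus.promoter


def mine_genome(contigs: dict[str, str], query_peptide: str, individual: str = "",
                score_min: float = DEFAULT_SCORE_MIN, promoter_len: int = 500,
                identity_min: float = DEFAULT_IDENTITY_MIN) -> list[GeneLocus]:
    """Convenience: translated_search + extract_locus over one assembly."""
    hits = translated_search(contigs, query_peptide, score_min, identity_min)
    return [extract_locus(h.contig, contigs[h.contig], h, promoter_len, individual)
            for h in hits]


def find_gt_ag_introns(seq: str, min_len: int = 40, max_len: int = 5000) -> list[tuple]:
    """Candidate GT..AG intron intervals (0-based half-open), a plain
    splice-site scan used by the optional intron-aware extraction mode."""
    out = []
    for i in range(len(seq) - 3):
        if seq[i:i + 2] == "GT":
            lo = i + min_len
            hi = min(len(seq), i + max_len)
            for j in range(lo, hi):
                if seq[j - 2:j] == "AG":
                    out.append((i, j))
                    break
    return out
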