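"""Expression evidence and RNA-editing assessment.

Expression: a cluster's mature-region sequence is locally aligned to every
transcriptome contig; best identity strictly above 0.95 counts as evidence
of expression, while contigs below 0.95 identity to *every* cluster are
novel-cluster candidates (a contig at exactly the boundary is neither:
absent but not novel). Editing: genome reads are mapped to transcript
sequences allowing only perfect full-length matches; positions covered by
no such read are candidate genome/transcript mismatches, and a direct
pairwise alignment of the paired genomic and transcript sequences
corroborates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from ._seq import revcomp
from .alignment import GAP, global_align

DEFAULT_ID_THRESHOLD = 0.95


@dataclass
class ExpressionEvidence:
    expressed: dict            # (cluster id, transcriptome id) -> bool
    best_identity: dict        # (cluster id, transcriptome id) -> float
    novel_candidates: dict     # transcriptome id -> list of contig ids
    boundary_cases: list = field(default_factory=list)  # identity == threshold


@dataclass
class CoverageProfile:
    reference_id: str
    counts: list               # per-position perfect-match read depth
    zero_intervals: list       # maximal disjoint 0-based half-open intervals


def _nt_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def _best_local_identity(query: str, target: str) -> float:
    """Identical positions of the best local alignment / query length,
    maximised over both target strands."""
    aligner = _nt_local_aligner()
    best = 0.0
    for t in (target, revcomp(target)):
        alns = aligner.align(t, query)
        try:
            aln = alns[0]
        except IndexError:
            continue
        matches = 0
        for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
            matches += sum(1 for k in range(te - ts) if t[ts + k] == query[qs + k])
        best = max(best, matches / len(query))
    return best


def expression_evidence(cluster_seqs: dict[str, str],
                        transcriptomes: dict[str, dict[str, str]],
                        id_threshold: float = DEFAULT_ID_THRESHOLD) -> ExpressionEvidence:
    """Score each cluster against each transcriptome assembly.

    `cluster_seqs` maps cluster id -> mature-region sequence; each
    transcriptome is {contig id: sequence}. Expressed iff best identity is
    strictly > id_threshold; a contig below the threshold against all
    clusters is a novel-cluster candidate.
    """
    expressed: dict = {}
    best_identity: dict = {}
    novel: dict = {}
    boundary: list = []
    for tx_id, contigs in transcriptomes.items():
        contig_best = {cid: 0.0 for cid in contigs}
        for cl_id, query in cluster_seqs.items():
            best = 0.0
            for cid, contig in contigs.items():
                ident = _best_local_identity(query, contig)
                contig_best[cid] = max(contig_best[cid], ident)
                best = max(best, ident)
            expressed[(cl_id, tx_id)] = best > id_threshold
            best_identity[(cl_id, tx_id)] = best
            if best == id_threshold:
                boundary.append((cl_id, tx_id))
        novel[tx_id] = sorted(cid for cid, b in contig_best.items()
                              if b < id_threshold)
    return ExpressionEvidence(expressed, best_identity, novel, boundary)


def perfect_coverage(reference: str, reads: list[tuple]) -> CoverageProfile:
    """Per-position depth of reads matching the reference exactly over
    their full length (both strands); zero-depth positions form the
    candidate-mismatch intervals."""
    counts = [0] * len(reference)
    for _, read in reads:
        for frag in (read, revcomp(read)):
            start = reference.find(frag)
            while start != -1:
                for i in range(start, start + len(frag)):
                    counts[i] += 1
                start = reference.find(frag, start + 1)
            if frag == revcomp(frag):  # palindromic: avoid double count
                break
    intervals = []
    i = 0
    n = len(counts)
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0:
                j += 1
            intervals.append((i, j))
            i = j
        else:
            i += 1
    return CoverageProfile("", counts, intervals)


@dataclass
class EditReport:
    per_pair: dict             # copy id -> {mismatches, corroborated, coverage_zero}
    not_expressed: list
    n_corroborated: int
    verdict: str               # "no discrepancies" or "edits detected"


def edit_candidates(genomic: dict[str, str], transcripts: dict[str, str],
                    reads_by_copy: dict[str, list]) -> EditReport:
    """Compare paired genomic and transcript sequences of one individual.

    For each pair: (a) mismatch positions (transcript coordinates) from a
    global pairwise alignment; (b) zero-coverage corroboration from
    perfect-match genome-read mapping onto the transcript. A genomic copy
    with no transcript is reported not expressed and excluded.
    """
    unknown = set(transcripts) - set(genomic)
    if unknown:
        raise KeyError(f"transcripts without genomic partner: {sorted(unknown)}")
    per_pair = {}
    not_expressed = []
    total = 0
    for copy_id, gseq in genomic.items():
        tseq = transcripts.get(copy_id)
        if tseq is None:
            not_expressed.append(copy_id)
            continue
        rg, rt = global_align(gseq, tseq)
        mismatches = []
        t_pos = 0
        for a, b in zip(rg, rt):
            if b != GAP:
                if a != GAP and a != b:
                    mismatches.append(t_pos)
                t_pos += 1
        cov = perfect_coverage(tseq, reads_by_copy.get(copy_id, []))
        zero = set()
        for s, e in cov.zero_intervals:
            zero.update(range(s, e))
        corroborated = [p for p in mismatches if p in zero] if reads_by_copy.get(copy_id) else mismatches
        per_pair[copy_id] = {
            "mismatches": mismatches,
            "corroborated": corroborated,
            "zero_intervals": cov.zero_intervals,
        }
        total += len(corroborated)
    verdict = "no discrepancies" if total == 0 else "edits detected"
    return EditReport(per_pair, sorted(not_expressed), total, verdict)
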