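"""End-to-end orchestration: simulate -> mine -> catalog -> {biophys,
selection, promoter, expression/editing} -> machine-readable run report.

Every stage writes its text outputs (FASTA/TSV/BED/newick/JSON) under the
run directory, and every number in the report is recomputable from those
persisted outputs. All randomness derives from the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import biophys, catalog, evolve, expressedit, mine, promoter, simulate
from .io import write_fasta, write_text

log = logging.getLogger("ampfam")


@dataclass
class RunConfig:
    """Pipeline thresholds (defaults are the analysis' canonical values)
    plus stage toggles and the master seed."""

    cluster_identity: float = 0.95
    expression_identity: float = 0.95
    novel_divergence: float = 0.05
    selection_p: float = 0.1
    promoter_len: int = 500
    sliding_window: int = 15
    motif_wmin: int = 6
    motif_wmax: int = 30
    scan_accuracy: float = 0.70
    n_motifs: int = 10
    score_min: float = mine.DEFAULT_SCORE_MIN
    pka_set: str = "IPC_protein"
    seed: int = 0
    stages: tuple = ("simulate", "mine", "catalog", "biophys", "select",
                     "promoter", "express")

    def to_flat(self) -> str:
        lines = []
        for k, v in asdict(self).items():
            if isinstance(v, tuple):
                v = ",".join(v)
            lines.append(f"{k}={v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_flat(cls, text: str) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            k = k.strip()
            if k not in cls.__dataclass_fields__:
                raise KeyError(f"unknown config key {k}")
            default = getattr(cls(), k)
            if isinstance(default, tuple):
                kwargs[k] = tuple(v.split(","))
            elif isinstance(default, bool):
                kwargs[k] = v.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[k] = int(v)
            elif isinstance(default, float):
                kwargs[k] = float(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


def _stage(report: dict, name: str, t0: float, n_in: int, n_out: int) -> None:
    elapsed = time.perf_counter() - t0
    report["stages"][name] = {"inputs": n_in, "outputs": n_out,
                              "seconds": round(elapsed, 3)}
    log.info("stage %-9s in=%-5d out=%-5d %.2fs", name, n_in, n_out, elapsed)


def run_pipeline(config: RunConfig, outdir,
                 family_params: simulate.FamilyParams | None = None) -> dict:
    """Run the enabled stages in dependency order; returns the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}, "counts": {}}
    report["config"]["stages"] = list(config.stages)

    params = family_params or simulate.FamilyParams(seed=config.seed)
    params = simulate.with_seed(params, config.seed)

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    genomes, truth = simulate.simulate_family(params)
    for ind, contigs in genomes.items():
        write_fasta(contigs, outdir / "genomes" / f"{ind}.fasta")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_text(simulate.truth_to_bed(truth), outdir / "truth.bed")
    write_text(simulate.params_to_config(params), outdir / "params.cfg")
    _stage(report, "simulate", t0, params.n_individuals, len(truth))
    report["counts"]["planted_copies"] = int(len(truth))

    # --- mine ---------------------------------------------------------------
    t0 = time.perf_counter()
    query = simulate.ANCESTRAL_MATURE
    loci: list[mine.GeneLocus] = []
    for ind, contigs in genomes.items():
        loci.extend(mine.mine_genome(contigs, query, individual=ind,
                                     score_min=config.score_min,
                                     promoter_len=config.promoter_len))
    pd.DataFrame([{
        "individual": l.individual, "contig": l.contig, "strand": l.strand,
        "start": l.start, "end": l.end, "score": l.score,
        "identity": round(l.identity, 4), "promoter_truncated": l.promoter_truncated,
    } for l in loci]).to_csv(outdir / "loci.tsv", sep="\t", index=False)
    write_fasta({f"{l.individual}_{l.contig}_{l.start}": l.cds for l in loci},
                outdir / "loci_cds.fasta")
    _stage(report, "mine", t0, len(truth), len(loci))
    report["counts"]["mined_loci"] = len(loci)

    # --- catalog ------------------------------------------------------------
    t0 = time.perf_counter()
    variants = catalog.classify_all(catalog.dereplicate(loci))
    clusters = catalog.cluster_greedy(variants, config.cluster_identity)
    clusters = [catalog.consensus(c, variants) for c in clusters]
    individuals = sorted(genomes)
    vpav, cpav = catalog.build_pav(variants, clusters, individuals)
    stats = catalog.pav_stats(vpav)
    pd.DataFrame([{
        "variant_id": v.variant_id, "class": v.class_label,
        "n_carriers": len(v.carriers), "carriers": ",".join(v.carriers),
        "peptide": v.peptide, "cds": v.cds,
    } for v in variants]).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "cluster_id": c.cluster_id, "representative": c.representative,
        "n_members": len(c.members), "members": ",".join(c.members),
    } for c in clusters]).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    write_fasta({c.cluster_id: c.consensus_cds for c in clusters},
                outdir / "consensus_nt.fasta")
    write_fasta({c.cluster_id: c.consensus_peptide for c in clusters},
                outdir / "consensus_aa.fasta")
    vpav.astype(int).to_csv(outdir / "pav_variants.tsv", sep="\t")
    cpav.astype(int).to_csv(outdir / "pav_clusters.tsv", sep="\t")
    class_counts = pd.Series([v.class_label for v in variants]).value_counts().to_dict()
    report["counts"].update({
        "variants": len(variants),
        "classes": {k: int(v) for k, v in class_counts.items()},
        "clusters": len(clusters),
        "mean_variants_per_individual": stats["mean_per_individual"],
        "mean_private_per_individual": stats["mean_private_per_individual"],
        "universal_clusters": catalog.pav_stats(cpav)["n_universal"] if len(clusters) else 0,
    })
    with open(outdir / "pav_stats.json", "w") as fh:
        json.dump({k: v for k, v in stats.items() if k != "occupancy"}, fh, indent=2)
    _stage(report, "catalog", t0, len(loci), len(variants))

    # --- biophys ------------------------------------------------------------
    if "biophys" in config.stages:
        t0 = time.perf_counter()
        pka = biophys.IPC_PROTEIN if config.pka_set == "IPC_protein" else biophys.IPC_PEPTIDE
        rows = []
        for v in variants:
            if v.class_label != "conventional":
                continue
            pep = biophys.mature_peptide(v.peptide, simulate.ANCESTRAL_MATURE)
            prof = biophys.profile_peptide(pep, pka)
            rows.append({"variant_id": v.variant_id, "mature": pep,
                         "pI": round(prof["pI"], 3),
                         "charge_at_7_4": round(prof["charge_at_7_4"], 3),
                         "mw": round(prof["mw"], 1)})
        bio = pd.DataFrame(rows)
        bio.to_csv(outdir / "biophys.tsv", sep="\t", index=False)
        report["counts"]["conventional_mature_peptides"] = int(bio["mature"].nunique()) if len(bio) else 0
        if len(bio):
            report["counts"]["pi_range"] = [float(bio.pI.min()), float(bio.pI.max())]
            report["counts"]["charge_range"] = [float(bio.charge_at_7_4.min()),
                                                float(bio.charge_at_7_4.max())]
        _stage(report, "biophys", t0, len(variants), len(rows))

    # --- selection ----------------------------------------------------------
    aligned_conv = None
    if "select" in config.stages:
        t0 = time.perf_counter()
        conv = [v for v in variants if v.class_label == "conventional"]
        if len(conv) >= 3:
            rows_nt = catalog.align_family([v.cds for v in conv], codon_aware=True)
            names = [v.variant_id for v in conv]
            aligned_conv = dict(zip(names, rows_nt))
            tree, sites = evolve.site_selection_analysis(names, rows_nt,
                                                         config.selection_p)
            write_text(tree.newick(), outdir / "tree.nwk")
            pd.DataFrame([{
                "column": s.column, "n": round(s.n_obs, 3), "s": round(s.s_obs, 3),
                "N": round(s.n_sites, 3), "S": round(s.s_sites, 3),
                "p": s.p_value, "call": s.call,
            } for s in sites]).to_csv(outdir / "selection_sites.tsv", sep="\t", index=False)
            report["counts"]["positive_sites"] = sum(1 for s in sites if s.call == "positive")
            report["counts"]["negative_sites"] = sum(1 for s in sites if s.call == "negative")
            _stage(report, "select", t0, len(conv), len(sites))

    # --- promoter -----------------------------------------------------------
    if "promoter" in config.stages:
        t0 = time.perf_counter()
        # one promoter per cluster (the representative's locus), mirroring a
        # per-cluster promoter panel; full-length promoters only
        rep_of = {c.representative: c.cluster_id for c in clusters}
        panel: dict[str, str] = {}
        cds_to_var = {v.cds: v.variant_id for v in variants}
        for l in loci:
            vid = cds_to_var.get(l.cds)
            if vid in rep_of and not l.promoter_truncated and rep_of[vid] not in panel:
                panel[rep_of[vid]] = l.promoter
        motifs = []
        if len(panel) >= 2:
            motifs = promoter.discover_motifs(list(panel.values()),
                                              n_motifs=config.n_motifs,
                                              wmin=config.motif_wmin,
                                              wmax=config.motif_wmax,
                                              seed=config.seed)
            write_text("".join(_meme_block(i, m) for i, m in enumerate(motifs)),
                       outdir / "motifs.txt")
            if motifs:
                reports = promoter.promoter_reports(panel, motifs)
                pd.DataFrame([{
                    "promoter": r.promoter_id,
                    "combined_p": r.combined_p,
                    "hits": ";".join(f"m{mi}@{off}" for mi, off, _, _ in r.motif_hits),
                } for r in reports]).to_csv(outdir / "promoter_report.tsv", sep="\t", index=False)
        report["counts"]["motifs"] = len(motifs)
        _stage(report, "promoter", t0, len(panel), len(motifs))

    # --- expression / editing ----------------------------------------------
    if "express" in config.stages:
        t0 = time.perf_counter()
        cluster_seqs = {c.cluster_id: c.consensus_cds.replace("N", "") for c in clusters}
        transcriptomes = {}
        truth_now = truth
        for ind in individuals:
            flags = {r.copy_id: bool(r.expressed)
                     for r in truth[truth.individual == ind].itertuples()}
            tx, truth_now = simulate.simulate_transcriptome(
                genomes[ind], truth_now, flags, params.edit_rate,
                seed=config.seed + 1000 + individuals.index(ind))
            transcriptomes[ind] = tx
            write_fasta(tx, outdir / "transcriptomes" / f"{ind}.fasta")
        ev = expressedit.expression_evidence(cluster_seqs, transcriptomes,
                                             config.expression_identity)
        emat = pd.DataFrame(
            [[int(ev.expressed[(c, t)]) for t in individuals] for c in cluster_seqs],
            index=list(cluster_seqs), columns=individuals)
        emat.to_csv(outdir / "expression.tsv", sep="\t")
        report["counts"]["expressed_cluster_calls"] = int(emat.values.sum())
        report["counts"]["novel_candidates"] = int(sum(len(v) for v in ev.novel_candidates.values()))
        _stage(report, "express", t0, len(cluster_seqs), int(emat.values.sum()))

    report["tool_version"] = _version()
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _meme_block(i: int, m) -> str:
    lines = [f"MOTIF m{i} {m.consensus}",
             f"letter-probability matrix: alength= 4 w= {m.width} "
             f"nsites= {m.n_expected_sites:.1f}"]
    for row in m.pwm:
        lines.append("  " + "  ".join(f"{p:.6f}" for p in row))
    return "\n".join(lines) + "\n\n"


def _version() -> str:
    from importlib.metadata import version
    try:
        return version("ampfam")
    except Exception:  # pragma: no cover
        return "unknown"
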