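"""End-to-end pipeline: simulate -> annotate -> bsj -> express -> target
-> network.

Each stage reads its inputs from and writes its outputs to a single
output directory, so stages can run individually (via the CLI) or
together via :func:`run_pipeline`, which also writes a ``manifest.json``
with a SHA-256 hash per output file for determinism checks. One
structured log line per stage reports the headline counts.

Configuration is a flat YAML mapping; every analysis threshold is
surfaced as a named key with the study default.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, bsj, express, network, simdata, target
from .iolib import (ConfigError, CountTable, GenomeSequence, circ_id,
                    read_bed, read_counts, read_fasta, read_gff3,
                    read_reads_fasta, read_transcripts_gff3, write_bed,
                    write_counts, write_edge_list, write_fasta, write_gff3,
                    write_transcripts_gff3)

logger = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")

#: every tunable threshold, defaulting to the study's value
DEFAULT_CONFIG: dict[str, float | int] = {
    # simulation
    "n_chrom": 3, "chrom_len": 100_000, "n_genes": 24, "te_fraction": 0.05,
    "n_lncrna_per_class": 5, "n_circ": 20, "n_mirna": 24,
    "nb_dispersion": 0.05, "base_mean": 200.0, "effect_log2fc": 2.0,
    "n_replicates": 3,
    # annotation
    "min_lncrna_len": annotate.MIN_LNCRNA_LEN,
    "max_noncoding_orf": annotate.MAX_NONCODING_ORF,
    "density_window": 10_000,
    # expression
    "log2fc_threshold": express.LOG2FC_THRESHOLD,
    "p_threshold": express.P_THRESHOLD,
    "min_expressed_replicates": 2,
    # targeting
    "penalty_cutoff": target.PENALTY_CUTOFF,
    "cis_window": target.CIS_WINDOW,
    "trans_min_match": target.TRANS_MIN_MATCH,
    "trans_min_identity": target.TRANS_MIN_IDENTITY,
    # network
    "r_threshold": network.R_THRESHOLD,
    "k_modules": 4,
}

_INT_KEYS = {"n_chrom", "chrom_len", "n_genes", "n_lncrna_per_class",
             "n_circ", "n_mirna", "n_replicates", "min_lncrna_len",
             "max_noncoding_orf", "density_window",
             "min_expressed_replicates", "cis_window", "trans_min_match",
             "k_modules"}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a flat YAML config over the defaults, rejecting unknown keys
    and non-numeric values."""
    cfg = dict(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ConfigError("config must be a flat YAML mapping")
    for key, value in loaded.items():
        if key not in DEFAULT_CONFIG:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"config key {key!r} must be numeric")
        cfg[key] = int(value) if key in _INT_KEYS else float(value)
    return cfg


def _sim_config(cfg: dict, seed: int) -> simdata.SimConfig:
    return simdata.SimConfig(
        seed=seed, n_chrom=cfg["n_chrom"], chrom_len=cfg["chrom_len"],
        n_genes=cfg["n_genes"], te_fraction=cfg["te_fraction"],
        n_lncrna_per_class=cfg["n_lncrna_per_class"], n_circ=cfg["n_circ"],
        n_mirna=cfg["n_mirna"], nb_dispersion=cfg["nb_dispersion"],
        base_mean=cfg["base_mean"], effect_log2fc=cfg["effect_log2fc"],
        n_replicates=cfg["n_replicates"])


def _tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(outdir: Path, cfg: dict, seed: int) -> dict:
    """Generate the synthetic study and write every input + truth file."""
    bundle = simdata.simulate_all(_sim_config(cfg, seed))
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, outdir / "genome.fa")
    write_gff3(bundle.genes, outdir / "genes.gff3")
    write_bed([(c, s, e, f"te_{i + 1}", 0, "+")
               for i, (c, s, e) in enumerate(bundle.te)], outdir / "te.bed")
    write_transcripts_gff3(bundle.lncrnas, outdir / "lncrna.gff3")
    write_fasta(bundle.bsj_reads, outdir / "bsj_reads.fa")
    write_fasta(bundle.mirnas, outdir / "mirna.fa")
    write_fasta(bundle.smallrna_reads, outdir / "smallrna_reads.fa")
    write_fasta({tid: seq for tid, (seq, _c) in bundle.transcript_seqs.items()},
                outdir / "transcripts.fa")
    _tsv(pd.DataFrame(
        [(tid, c) for tid, (_s, c) in bundle.transcript_seqs.items()],
        columns=["transcript_id", "rna_class"]),
        outdir / "transcript_classes.tsv", index=False)
    for rna_class, table in bundle.counts.items():
        write_counts(table, outdir / f"counts_{rna_class}.tsv",
                     outdir / "design.tsv")
    t = bundle.truth
    _tsv(pd.Series(t.lncrna_class_truth, name="class").rename_axis(
        "transcript_id").to_frame(), outdir / "truth_lncrna_class.tsv")
    _tsv(pd.DataFrame.from_dict(t.circ_truth, orient="index").rename_axis(
        "circ_id"), outdir / "truth_circ.tsv")
    _tsv(pd.Series(t.inheritance_truth, name="state").rename_axis(
        "feature_id").to_frame(), outdir / "truth_inheritance.tsv")
    _tsv(pd.Series(t.pattern_truth, name="pattern").rename_axis(
        "feature_id").to_frame(), outdir / "truth_pattern.tsv")
    _tsv(pd.DataFrame(sorted(t.target_truth), columns=["mirna", "target"]),
         outdir / "truth_targets.tsv", index=False)
    _tsv(pd.Series(t.aseg_truth, name="bias").rename_axis(
        "gene_id").to_frame(), outdir / "aseg.tsv")
    counts = {"genes": len(bundle.genes), "lncrna_loci": len(bundle.lncrnas),
              "bsj_reads": len(bundle.bsj_reads),
              "smallrna_reads": len(bundle.smallrna_reads)}
    logger.info("simulate: %s", counts)
    return counts


def stage_annotate(outdir: Path, cfg: dict) -> dict:
    genome = read_fasta(outdir / "genome.fa")
    genes = read_gff3(outdir / "genes.gff3")
    te = [(c, s, e) for c, s, e, *_ in read_bed(outdir / "te.bed")]
    lncrnas = read_transcripts_gff3(outdir / "lncrna.gff3")
    kept = annotate.screen_lncrna_candidates(
        lncrnas, genome, min_len=cfg["min_lncrna_len"],
        max_orf=cfg["max_noncoding_orf"])
    classes = annotate.classify_lncrna_positions(kept, genes)
    _tsv(classes, outdir / "lncrna_classes.tsv")
    stats = pd.DataFrame(
        [vars(annotate.feature_stats(t, genome, te)) for t in lncrnas]
    ).set_index("transcript_id")
    stats["meta_feature"] = [
        annotate.assign_meta_feature(t.chrom, t.start, t.end, genes,
                                     [], te) for t in lncrnas]
    _tsv(stats, outdir / "lncrna_stats.tsv")
    density = annotate.window_density(
        [(g.chrom, g.start) for g in genes], genome.chrom_lengths(),
        window=cfg["density_window"])
    _tsv(density, outdir / "gene_density.tsv", index=False)
    counts = {"lncrna_screened": len(kept),
              **classes["class"].value_counts().to_dict()}
    logger.info("annotate: %s", counts)
    return counts


def stage_bsj(outdir: Path, cfg: dict) -> dict:
    genome = read_fasta(outdir / "genome.fa")
    reads = read_reads_fasta(outdir / "bsj_reads.fa")
    index = bsj.build_index(genome)
    grouped, screened = bsj.detect_from_reads(reads, index)
    rows = []
    for c in grouped:
        rules = bsj.screen_rules(c)
        rows.append({"circ_id": c.circ_id, "chrom": c.chrom,
                     "acceptor": c.acceptor, "donor": c.donor,
                     "strand": c.strand, "signal": c.splice_signal,
                     "support": c.support_reads, "mismatches": c.mismatches,
                     "ambiguity": c.breakpoint_ambiguity,
                     "margin": c.score_margin, **rules,
                     "passed": all(rules.values())})
    _tsv(pd.DataFrame(rows), outdir / "bsj_candidates.tsv", index=False)
    srpbm = bsj.quantify_junction(screened, total_mapped_reads=len(reads))
    _tsv(pd.Series(srpbm, name="srpbm").rename_axis("circ_id").to_frame(),
         outdir / "circ_srpbm.tsv")
    counts = {"grouped": len(grouped), "screened": len(screened)}
    logger.info("bsj: %s", counts)
    return counts


def stage_express(outdir: Path, cfg: dict) -> dict:
    counts_out = {}
    for rna_class in RNA_CLASSES:
        table = read_counts(outdir / f"counts_{rna_class}.tsv",
                            outdir / "design.tsv")
        res = express.inheritance_analysis(table)
        for pair in ("MP", "HM", "HP"):
            _tsv(res[pair], outdir / f"de_{rna_class}_{pair}.tsv")
        _tsv(res["inheritance"], outdir / f"inheritance_{rna_class}.tsv")
        norm = express.normalized_counts(table, res["size_factors"])
        presence = express.classify_presence(
            norm, table.design,
            min_expressed_replicates=cfg["min_expressed_replicates"])
        _tsv(presence, outdir / f"presence_{rna_class}.tsv")
        counts_out[rna_class] = {
            "n_DE_HM": int(res["HM"]["significant"].sum()),
            "n_DE_HP": int(res["HP"]["significant"].sum()),
            "n_DE_MP": int(res["MP"]["significant"].sum()),
            "n_nonadditive": int(res["mpv"]["nonadditive"].sum()),
        }
    logger.info("express: %s", counts_out)
    return counts_out


def stage_target(outdir: Path, cfg: dict) -> dict:
    mirnas = read_reads_fasta(outdir / "mirna.fa")
    seqs = read_reads_fasta(outdir / "transcripts.fa")
    classes = pd.read_csv(outdir / "transcript_classes.tsv", sep="\t",
                          index_col="transcript_id")["rna_class"]
    transcripts = {tid: (seq, str(classes.get(tid, "unknown")))
                   for tid, seq in seqs.items()}
    pairs: list[target.TargetPair] = []
    for mid, mseq in mirnas.items():
        pairs.extend(target.scan_targets(mid, mseq, transcripts,
                                         cutoff=cfg["penalty_cutoff"]))
    genes = read_gff3(outdir / "genes.gff3")
    lncrnas = read_transcripts_gff3(outdir / "lncrna.gff3")
    genome = read_fasta(outdir / "genome.fa")
    mrna_seqs = {tid: s for tid, (s, c) in transcripts.items() if c == "mRNA"}
    for t in lncrnas:
        pairs.extend(target.cis_targets(t, genes, window=cfg["cis_window"]))
        pairs.extend(target.trans_targets(
            t.transcript_id, t.sequence(genome), mrna_seqs,
            min_match=cfg["trans_min_match"],
            min_identity=cfg["trans_min_identity"]))
    _tsv(target.target_pairs_frame(pairs), outdir / "target_pairs.tsv",
         index=False)
    # circRNA host genes from the screened junction table
    cand = pd.read_csv(outdir / "bsj_candidates.tsv", sep="\t")
    hosts = []
    for _, row in cand[cand["passed"]].iterrows():
        c = bsj.BsjCandidate(row["chrom"], int(row["acceptor"]),
                             int(row["donor"]), row["strand"], row["signal"],
                             0, 1, 1, 0, 0)
        hosts.append(target.assign_host_gene(c, genes))
    _tsv(pd.DataFrame([(h.circ_id, h.host_gene_id) for h in hosts],
                      columns=["circ_id", "host_gene"]),
         outdir / "circ_hosts.tsv", index=False)
    counts = {"target_pairs": len(pairs), "hosts": len(hosts)}
    logger.info("target: %s", counts)
    return counts


def _load_pairs(outdir: Path) -> list[target.TargetPair]:
    df = pd.read_csv(outdir / "target_pairs.tsv", sep="\t")
    return [target.TargetPair(r.regulator, r.regulator_class, r.target,
                              r.target_class, r.mode, float(r.score),
                              int(r.position))
            for r in df.itertuples()]


def stage_network(outdir: Path, cfg: dict) -> dict:
    decalls = {rc: {pair: pd.read_csv(outdir / f"de_{rc}_{pair}.tsv",
                                      sep="\t", index_col="feature_id")
                    for pair in ("MP", "HM", "HP")}
               for rc in RNA_CLASSES}
    de_sets = network.build_de_sets(decalls)
    _tsv(network.de_set_summary(de_sets), outdir / "de_summary.tsv",
         index=False)
    pairs = _load_pairs(outdir)
    edges = network.regulator_target_network(de_sets, pairs)
    write_edge_list(edges, outdir / "de_network_edges.tsv")
    triads = network.build_cerna_triads(de_sets, pairs)
    _tsv(network.triads_frame(triads), outdir / "cerna_triads.tsv",
         index=False)
    aseg = pd.read_csv(outdir / "aseg.tsv", sep="\t",
                       index_col="gene_id")["bias"].to_dict()
    hosts_df = pd.read_csv(outdir / "circ_hosts.tsv", sep="\t")
    hosts = [target.HostAssignment(r.circ_id, r.host_gene)
             for r in hosts_df.itertuples()]
    _tsv(network.aseg_join(aseg, pairs, hosts), outdir / "aseg_edges.tsv",
         index=False)
    # correlation of non-additive ncRNAs with DE-gene modules
    import numpy as np
    mrna = read_counts(outdir / "counts_mRNA.tsv", outdir / "design.tsv")
    mrna_norm = np.log2(express.normalized_counts(mrna) + 1.0)
    deg = sorted(de_sets.de_hp.get("mRNA", set()))
    modules_summary = {}
    if len(deg) >= cfg["k_modules"]:
        inh_frames = []
        nc_frames = []
        for rc in ("lncRNA", "circRNA", "miRNA"):
            inh = pd.read_csv(outdir / f"inheritance_{rc}.tsv", sep="\t",
                              index_col=0)
            nonadd = inh.index[inh["nonadditive"].astype(bool)]
            if len(nonadd) == 0:
                continue
            tab = read_counts(outdir / f"counts_{rc}.tsv", outdir / "design.tsv")
            nc = np.log2(express.normalized_counts(tab) + 1.0).loc[nonadd]
            nc_frames.append(nc)
            inh_frames.append(inh)
        if nc_frames:
            nc_all = pd.concat(nc_frames)
            assign, profiles, calls = network.correlation_modules(
                nc_all, mrna_norm.loc[deg],
                r_threshold=cfg["r_threshold"], k_modules=cfg["k_modules"])
            _tsv(assign.rename("module").rename_axis("gene_id").to_frame(),
                 outdir / "modules.tsv")
            _tsv(calls, outdir / "module_calls.tsv", index=False)
            modules_summary = assign.value_counts().to_dict()
    # circRNA-host correlation over variety means
    srpbm = pd.read_csv(outdir / "circ_srpbm.tsv", sep="\t", index_col=0)
    circ_tab = read_counts(outdir / "counts_circRNA.tsv", outdir / "design.tsv")
    circ_means = express.variety_means(circ_tab)
    host_means = express.variety_means(mrna)
    circ_to_host = {r.circ_id: r.host_gene for r in hosts_df.itertuples()
                    if r.host_gene != "intergenic"}
    per, pooled = network.circ_host_correlation(
        circ_means.loc[circ_means.index.intersection(list(circ_to_host))],
        host_means, circ_to_host)
    _tsv(per, outdir / "circ_host_correlation.tsv", index=False)
    counts = {"de_edges": len(edges), "triads": len(triads),
              "modules": modules_summary,
              "circ_host_pooled_r": pooled if pooled is None else round(pooled, 4),
              "srpbm_rows": len(srpbm)}
    logger.info("network: %s", counts)
    return counts


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

STAGES = ("simulate", "annotate", "bsj", "express", "target", "network")


def run_pipeline(outdir: str | Path, seed: int,
                 config_path: str | Path | None = None,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order and write ``manifest.json``."""
    outdir = Path(outdir)
    cfg = load_config(config_path)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    report: dict = {"seed": seed, "stages": {}}
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "simulate":
            report["stages"][stage] = stage_simulate(outdir, cfg, seed)
        else:
            report["stages"][stage] = globals()[f"stage_{stage}"](outdir, cfg)
    report["files"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
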