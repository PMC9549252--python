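"""Synthetic trio data with recorded ground truth.

Generates every input the pipeline consumes — a multi-chromosome mini
genome with genic/intergenic/TE structure, lncRNA loci of the four
positional classes, back-splice reads with per-rule decoys, 18-30 nt
small-RNA reads peaking at 21 and 24 nt, planted miRNA target sites and
negative-binomial count tables with planted inheritance states and
presence patterns — so that every downstream classifier can be scored
against a known answer.

Counts are drawn per sample from NB(mean * size_factor, dispersion) with
per-sample size factors log-uniform in [0.7, 1.4] (so normalization is
non-trivial). For planted states with unequal parents the two parental
means sit at base * 2^(+-effect_log2fc): the parents are separated by
twice the planted hybrid effect, so each non-equivalent state deviates
from its reference level by about ``effect_log2fc`` units of log2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iolib import (ConfigError, CountTable, GeneModel, GenomeSequence,
                    TranscriptRecord, circ_id, revcomp)

READ_LEN = 150
_BASES = np.array(list("ACGT"))

#: the ten plantable fine states plus "equivalent"
PLANTABLE_STATES = (
    "additive-high", "additive-low",
    "ELD-M-high", "ELD-M-low", "ELD-P-high", "ELD-P-low",
    "transgressive-up-M", "transgressive-up-P",
    "transgressive-down-M", "transgressive-down-P",
    "equivalent",
)

MIRNA_LENGTH_WEIGHTS = {     # planted small-RNA length mix, peaks at 21/24
    18: 0.03, 19: 0.04, 20: 0.08, 21: 0.30, 22: 0.10, 23: 0.05, 24: 0.25,
    25: 0.05, 26: 0.03, 27: 0.02, 28: 0.02, 29: 0.015, 30: 0.015,
}


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom: int = 3
    chrom_len: int = 100_000
    n_genes: int = 24
    te_fraction: float = 0.05
    n_lncrna_per_class: int = 5
    n_circ: int = 20
    n_mirna: int = 24
    nb_dispersion: float = 0.05
    base_mean: float = 200.0
    effect_log2fc: float = 2.0
    n_replicates: int = 3
    # gene geometry
    exon_len_range: tuple[int, int] = (150, 400)
    intron_len_range: tuple[int, int] = (300, 700)
    n_exons_range: tuple[int, int] = (1, 12)
    gene_spacing: int = 1500
    plus_strand_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.effect_log2fc <= 0:
            raise ConfigError("effect_log2fc must be > 0")
        for name in ("n_chrom", "chrom_len", "n_genes", "n_lncrna_per_class",
                     "n_circ", "n_mirna", "n_replicates"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.te_fraction < 1:
            raise ConfigError("te_fraction must be in [0, 1)")
        if self.exon_len_range[0] < 150:
            raise ConfigError("exons must be at least 150 nt (one read span)")
        if self.intron_len_range[0] < 20:
            raise ConfigError("introns must be at least 20 nt")
        if not 0 <= self.plus_strand_fraction <= 1:
            raise ConfigError("plus_strand_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    lncrna_class_truth: dict[str, str] = field(default_factory=dict)
    circ_truth: dict[str, dict] = field(default_factory=dict)
    inheritance_truth: dict[str, str] = field(default_factory=dict)
    pattern_truth: dict[str, int] = field(default_factory=dict)
    target_truth: set[tuple[str, str]] = field(default_factory=set)
    target_decoys: set[tuple[str, str]] = field(default_factory=set)
    aseg_truth: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=n)])


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None,
                    ) -> tuple[GenomeSequence, list[GeneModel],
                               list[tuple[str, int, int]]]:
    """Random genome with non-overlapping multi-exon genes and TE tracts.

    Genes carry 1-12 exons; intron boundaries get canonical splice
    dinucleotides written into the sequence (GT..AG in the gene's strand
    orientation). TE intervals tile ~``te_fraction`` of each chromosome.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms = {f"chr{i + 1}": _random_seq(rng, cfg.chrom_len)
              for i in range(cfg.n_chrom)}
    names = list(chroms)
    genes: list[GeneModel] = []
    per_chrom = _split_across(cfg.n_genes, cfg.n_chrom)
    for ci, name in enumerate(names):
        seq = chroms[name]
        cursor = cfg.gene_spacing
        e_lo, e_hi = cfg.exon_len_range
        i_lo, i_hi = cfg.intron_len_range
        n_lo, n_hi = cfg.n_exons_range
        for gi in range(per_chrom[ci]):
            n_exons = int(rng.integers(n_lo, n_hi + 1))
            exon_lens = rng.integers(e_lo, e_hi + 1, size=n_exons)
            intron_lens = rng.integers(i_lo, i_hi + 1,
                                       size=max(n_exons - 1, 0))
            glen = int(exon_lens.sum() + intron_lens.sum())
            if cursor + glen + cfg.gene_spacing > cfg.chrom_len:
                raise ConfigError(
                    f"chrom_len={cfg.chrom_len} too small for requested genes")
            start = cursor
            exons = []
            pos = start
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            strand = "+" if rng.random() < cfg.plus_strand_fraction else "-"
            gene = GeneModel(f"gene_{name}_{gi + 1}", name, start, pos,
                             strand, exons)
            _write_splice_signals(seq, gene)
            genes.append(gene)
            cursor = pos + cfg.gene_spacing + int(rng.integers(0, cfg.gene_spacing))
    te: list[tuple[str, int, int]] = []
    if cfg.te_fraction > 0:
        for name in names:
            covered = 0
            goal = cfg.te_fraction * cfg.chrom_len
            attempts = 0
            while covered < goal and attempts < 10_000:
                attempts += 1
                tlen = int(rng.integers(100, 500))
                s = int(rng.integers(0, cfg.chrom_len - tlen))
                if any(c == name and s < e2 and s2 < s + tlen
                       for c, s2, e2 in te):
                    continue
                te.append((name, s, s + tlen))
                covered += tlen
        te.sort()
    genome = GenomeSequence({n: "".join(s) for n, s in chroms.items()})
    return genome, genes, te


def _split_across(total: int, bins: int) -> list[int]:
    base, extra = divmod(total, max(bins, 1))
    return [base + (1 if i < extra else 0) for i in range(bins)]


def _write_splice_signals(seq: list[str], gene: GeneModel) -> None:
    for i_s, i_e in gene.introns():
        if gene.strand == "+":
            seq[i_s], seq[i_s + 1] = "G", "T"
            seq[i_e - 2], seq[i_e - 1] = "A", "G"
        else:
            seq[i_s], seq[i_s + 1] = "C", "T"
            seq[i_e - 2], seq[i_e - 1] = "A", "C"


# ---------------------------------------------------------------------------
# lncRNA loci
# ---------------------------------------------------------------------------

def plant_lncrna_loci(cfg: SimConfig, genome: GenomeSequence,
                      genes: list[GeneModel],
                      rng: np.random.Generator | None = None,
                      ) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Plant ``n_lncrna_per_class`` loci per positional class.

    Lengths are drawn mostly in 200-400 nt. lincRNAs land in intergenic
    gaps at least 1 bp away from every gene; antisense/sense loci overlap
    a gene's first exon on the opposite/same strand; intronic loci sit
    fully inside a sufficiently long intron.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    txs: list[TranscriptRecord] = []
    truth: dict[str, str] = {}
    n = cfg.n_lncrna_per_class

    def lnc_len() -> int:
        if rng.random() < 0.9:
            return int(rng.integers(210, 401))
        return int(rng.integers(401, 801))

    # --- lincRNA: intergenic gaps, >=1 bp margin from genes
    gaps = _intergenic_gaps(genome, genes, margin=200)
    placed = 0
    for chrom, g_s, g_e in gaps:
        if placed >= n:
            break
        length = lnc_len()
        if g_e - g_s < length + 2:
            continue
        start = g_s + int(rng.integers(1, g_e - g_s - length))
        tid = f"linc_{placed + 1}"
        txs.append(TranscriptRecord(tid, chrom, start, start + length,
                                    "+" if rng.random() < 0.5 else "-",
                                    [(start, start + length)], "lncRNA"))
        truth[tid] = "lincRNA"
        placed += 1
    if placed < n:
        raise ConfigError("no intergenic room left for lincRNA loci")

    # --- antisense / sense: overlap a gene's first exon
    overlap_genes = [g for g in genes]
    if len(overlap_genes) < 2 * n:
        raise ConfigError("not enough genes for antisense/sense loci")
    for idx in range(n):
        for kind, offset in (("antisense", 0), ("sense", n)):
            g = overlap_genes[(idx + offset) % len(overlap_genes)]
            length = lnc_len()
            e_s, e_e = g.exons[0]
            start = max(e_s - length // 3, 0)
            strand = _flip(g.strand) if kind == "antisense" else g.strand
            tid = f"{kind}_{idx + 1}"
            txs.append(TranscriptRecord(tid, g.chrom, start, start + length,
                                        strand, [(start, start + length)],
                                        "lncRNA"))
            truth[tid] = kind

    # --- intronic: fully inside one intron, >=1 bp from the exon edges
    placed = 0
    for g in genes:
        if placed >= n:
            break
        for i_s, i_e in g.introns():
            if placed >= n:
                break
            room = i_e - i_s - 2
            if room < 205:
                continue
            length = min(lnc_len(), room)
            start = i_s + 1 + int(rng.integers(0, room - length + 1))
            tid = f"intronic_{placed + 1}"
            txs.append(TranscriptRecord(tid, g.chrom, start, start + length,
                                        "+" if rng.random() < 0.5 else "-",
                                        [(start, start + length)], "lncRNA"))
            truth[tid] = "intronic"
            placed += 1
    if placed < n:
        raise ConfigError("not enough long introns for intronic loci")
    return txs, truth


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _intergenic_gaps(genome: GenomeSequence, genes: list[GeneModel],
                     margin: int) -> list[tuple[str, int, int]]:
    gaps = []
    for chrom, length in genome.chrom_lengths().items():
        spans = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
        prev = 0
        for s, e in spans + [(length, length)]:
            if s - prev > 2 * margin:
                gaps.append((chrom, prev + margin, s - margin))
            prev = max(prev, e)
    return gaps


# ---------------------------------------------------------------------------
# back-splice reads
# ---------------------------------------------------------------------------

def simulate_bsj_reads(cfg: SimConfig, genome: GenomeSequence,
                       genes: list[GeneModel],
                       rng: np.random.Generator | None = None,
                       ) -> tuple[dict[str, str], dict[str, dict], GenomeSequence]:
    """Planted back-splice reads plus one decoy per screening rule.

    Every planted positive junction puts its acceptor at the start of an
    internal exon (AG upstream from the preceding intron) and its donor
    at the end of an internal exon (GT downstream), with the junction-
    adjacent bases adjusted so the breakpoint is unique. Decoys cover:
    non-GT/AG flanks (rule 1), double splice-consistent breakpoints
    (rule 2), three-mismatch reads (rule 3), >=3-way breakpoint ambiguity
    (rule 4), single-read support (rule 5) and a near-perfect second
    genomic placement (rule 6) — plus colinear reads that must yield no
    candidate at all. The genome is returned with the (exonic) base edits
    applied.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    seqs = {c: list(s) for c, s in genome.sequences.items()}
    sites = _junction_sites(genes, cfg.n_circ + 6)
    if len(sites) < cfg.n_circ + 6:
        raise ConfigError("not enough multi-exon plus-strand genes "
                          "for the requested junctions")
    reads: dict[str, str] = {}
    truth: dict[str, dict] = {}

    def span_read(chrom: str, a: int, d: int, l1: int) -> str:
        g = seqs[chrom]
        return "".join(g[d - l1:d]) + "".join(g[a:a + READ_LEN - l1])

    def add_junction(kind: str, chrom: str, a: int, d: int, n_reads: int,
                     mutate_read=None) -> None:
        cid = circ_id(chrom, d, a)
        truth[cid] = {"chrom": chrom, "acceptor": a, "donor": d,
                      "n_reads": n_reads, "kind": kind}
        for r in range(n_reads):
            l1 = int(rng.integers(30, 121))
            seq = span_read(chrom, a, d, l1)
            if mutate_read is not None:
                seq = mutate_read(seq)
            reads[f"{kind}_{cid}_r{r + 1}"] = seq

    k = 0
    for i in range(cfg.n_circ):
        chrom, a, d = sites[k]; k += 1
        _tidy_junction(seqs[chrom], a, d)
        add_junction("positive", chrom, a, d, n_reads=2 + i % 3)

    # rule 1: non-GT/AG flanks (shift the donor into the exon body)
    chrom, a, d = sites[k]; k += 1
    d1 = d - 5
    _tidy_junction(seqs[chrom], a, d1, signal=False)
    add_junction("decoy_rule1", chrom, a, d1, n_reads=3)

    # rule 2: two splice-consistent equally-scoring breakpoints
    chrom, a, d = sites[k]; k += 1
    _tidy_junction(seqs[chrom], a, d)
    g = seqs[chrom]
    g[a], g[a + 1], g[a + 2], g[a + 3] = "G", "T", "A", "G"
    g[d + 2], g[d + 3], g[d + 4], g[d + 5] = "A", "G", "G", "T"
    add_junction("decoy_rule2", chrom, a, d, n_reads=2)

    # rule 3: three mismatches per read (outside the anchors)
    chrom, a, d = sites[k]; k += 1
    _tidy_junction(seqs[chrom], a, d)

    def mutate3(seq: str) -> str:
        s = list(seq)
        for pos in (25, 75, 125):
            s[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
        return "".join(s)

    add_junction("decoy_rule3", chrom, a, d, n_reads=2, mutate_read=mutate3)

    # rule 4: three equally-scoring breakpoints (one splice-consistent)
    chrom, a, d = sites[k]; k += 1
    _tidy_junction(seqs[chrom], a, d)
    g = seqs[chrom]
    g[a], g[a + 1] = "G", "T"        # mirrors the GT after the donor
    g[d + 2], g[d + 3] = "X", "X"    # placeholder; fixed below
    g[d + 2], g[d + 3] = _noncanonical_pair(g[a + 2], g[a + 3])
    add_junction("decoy_rule4", chrom, a, d, n_reads=2)

    # rule 5: single supporting read
    chrom, a, d = sites[k]; k += 1
    _tidy_junction(seqs[chrom], a, d)
    add_junction("decoy_rule5", chrom, a, d, n_reads=1)

    # rule 6: a second, nearly-as-good placement of the junction flanks
    chrom, a, d = sites[k]; k += 1
    _tidy_junction(seqs[chrom], a, d)
    other = [c for c in seqs if c != chrom][0] if len(seqs) > 1 else chrom
    og = seqs[other]
    x = len(og) - 1200
    tail_copy = seqs[chrom][a:a + 130]
    head_copy = seqs[chrom][d - 130:d]
    og[x:x + 130] = tail_copy
    og[x + 400:x + 530] = head_copy
    og[x + 60] = _flip_base(og[x + 60])              # 1 mismatch in each copy
    og[x + 400 + 60] = _flip_base(og[x + 400 + 60])
    add_junction("decoy_rule6", chrom, a, d, n_reads=2)

    # colinear reads: contiguous genome, must produce no candidate
    for i in range(3):
        chrom = list(seqs)[i % len(seqs)]
        s = int(rng.integers(0, len(seqs[chrom]) - READ_LEN))
        reads[f"linear_r{i + 1}"] = "".join(seqs[chrom][s:s + READ_LEN])

    new_genome = GenomeSequence({c: "".join(s) for c, s in seqs.items()})
    return reads, truth, new_genome


def _junction_sites(genes: list[GeneModel], n_needed: int,
                    min_span: int = READ_LEN) -> list[tuple[str, int, int]]:
    """(chrom, acceptor, donor) sites on internal exons of plus-strand
    genes, so AG precedes the acceptor and GT follows the donor on the
    plus strand. Every internal exon of span >= one read length yields a
    single-exon circle site; sites are interleaved across genes."""
    per_gene: list[list[tuple[str, int, int]]] = []
    for g in genes:
        if g.strand != "+" or len(g.exons) < 3:
            continue
        gsites = []
        for i in range(1, len(g.exons) - 1):
            a, d = g.exons[i]
            if d - a >= min_span:
                gsites.append((g.chrom, a, d))
        if gsites:
            per_gene.append(gsites)
    sites: list[tuple[str, int, int]] = []
    depth = 0
    while len(sites) < n_needed and any(depth < len(s) for s in per_gene):
        for gsites in per_gene:
            if depth < len(gsites):
                sites.append(gsites[depth])
        depth += 1
    return sites[:n_needed]


def _tidy_junction(seq: list[str], a: int, d: int, signal: bool = True) -> None:
    """Make the junction unique: GT/AG flanks (unless ``signal`` is off)
    and junction-adjacent bases that forbid breakpoint sliding
    (seq[a] != seq[d], seq[a-1] != seq[d-1])."""
    if signal:
        seq[d], seq[d + 1] = "G", "T"
        seq[a - 2], seq[a - 1] = "A", "G"
    else:
        if seq[d] == "G" and seq[d + 1] == "T":
            seq[d] = "C"
        if seq[a - 2] == "A" and seq[a - 1] == "G":
            seq[a - 2] = "T"
    if seq[a] == seq[d]:
        seq[a] = "T" if seq[d] != "T" else "C"
    if seq[a - 1] == seq[d - 1]:
        seq[d - 1] = "C" if seq[a - 1] != "C" else "A"


def _noncanonical_pair(b2: str, b3: str) -> tuple[str, str]:
    """Bases for (d+2, d+3) equal to (a+2, a+3) unless that would create a
    second GT donor signal right after the first."""
    return (b2, b3) if (b2, b3) != ("G", "T") else ("G", "A")


def _flip_base(b: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[b]


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

def simulate_mirna(cfg: SimConfig, rng: np.random.Generator | None = None,
                   ) -> dict[str, str]:
    """Mature miRNA sequences, 18-30 nt with the 21/24 nt peaks."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    lengths = np.array(list(MIRNA_LENGTH_WEIGHTS))
    probs = np.array(list(MIRNA_LENGTH_WEIGHTS.values()))
    probs = probs / probs.sum()
    out = {}
    for i in range(cfg.n_mirna):
        n = int(rng.choice(lengths, p=probs))
        out[f"mir_{i + 1}"] = "".join(_random_seq(rng, n))
    return out


def simulate_smallrna_reads(cfg: SimConfig, mirnas: dict[str, str],
                            rng: np.random.Generator | None = None,
                            reads_per_mirna: int = 20) -> dict[str, str]:
    """Small-RNA read set: copies of the mature sequences plus QC decoys
    (too short, too long, N-rich) that the 18-30 nt / <=10% N filter must
    remove."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 4)
    reads = {}
    i = 0
    for mid, seq in mirnas.items():
        for _ in range(int(rng.integers(2, reads_per_mirna))):
            i += 1
            reads[f"sr_{i}_{mid}"] = seq
    reads["qc_too_short"] = "".join(_random_seq(rng, 16))
    reads["qc_too_long"] = "".join(_random_seq(rng, 34))
    n_rich = _random_seq(rng, 22)
    n_rich[:5] = ["N"] * 5
    reads["qc_n_rich"] = "".join(n_rich)
    return reads


def plant_target_sites(cfg: SimConfig, mirnas: dict[str, str],
                       transcripts: dict[str, tuple[str, str]],
                       rng: np.random.Generator | None = None,
                       ) -> tuple[dict[str, tuple[str, str]],
                                  set[tuple[str, str]], set[tuple[str, str]]]:
    """Embed perfect complementary sites and scrambled decoys.

    Returns the edited transcript map, the set of planted (miRNA, target)
    pairs and the set of decoy pairs (scrambled embedding; must score
    past the cutoff).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 5)
    edited = dict(transcripts)
    planted: set[tuple[str, str]] = set()
    decoys: set[tuple[str, str]] = set()
    mrna_ids = [t for t, (_s, c) in edited.items() if c == "mRNA"]
    ncrna_ids = [t for t, (_s, c) in edited.items() if c != "mRNA"]
    all_ids = list(edited)
    mids = list(mirnas)
    occupied: dict[str, list[tuple[int, int]]] = {}

    def _free_pos(tid: str, length: int) -> int | None:
        seq_len = len(edited[tid][0])
        if seq_len <= length:
            return None
        for _ in range(50):
            pos = int(rng.integers(0, seq_len - length))
            if all(pos >= e or pos + length <= s
                   for s, e in occupied.get(tid, ())):
                occupied.setdefault(tid, []).append((pos, pos + length))
                return pos
        return None

    def embed(mid: str, tid: str, site: str) -> None:
        pos = _free_pos(tid, len(site))
        if pos is None:
            return
        seq, tclass = edited[tid]
        edited[tid] = (seq[:pos] + site + seq[pos + len(site):], tclass)
        planted.add((mid, tid))

    for idx, mid in enumerate(mids):
        site = revcomp(mirnas[mid].replace("U", "T"))
        # each miRNA gets one mRNA target and (where available) one
        # non-coding sponge, so ceRNA triads can form downstream
        if mrna_ids:
            embed(mid, mrna_ids[idx % len(mrna_ids)], site)
        if ncrna_ids:
            embed(mid, ncrna_ids[idx % len(ncrna_ids)], site)
        # scrambled decoy into a transcript this miRNA does not target
        d_tid = all_ids[idx % len(all_ids)]
        if (mid, d_tid) in planted:
            continue
        scr = list(site)
        rng.shuffle(scr)
        if "".join(scr) == site:
            scr = scr[::-1]
        d_pos = _free_pos(d_tid, len(site))
        if d_pos is None:
            continue
        d_seq, d_class = edited[d_tid]
        edited[d_tid] = (d_seq[:d_pos] + "".join(scr) + d_seq[d_pos + len(site):],
                         d_class)
        decoys.add((mid, d_tid))
    return edited, planted, decoys


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _state_means(state: str, base: float, e: float) -> tuple[float, float, float]:
    """(maternal, hybrid, paternal) means for one planted state."""
    lo, hi = base * 2.0 ** -e, base * 2.0 ** e
    if state == "equivalent":
        return base, base, base
    if state == "additive-high":          # paternal is the high parent
        return lo, (lo + hi) / 2, hi
    if state == "additive-low":
        return hi, (lo + hi) / 2, lo
    if state == "ELD-M-high":
        return hi, hi, lo
    if state == "ELD-M-low":
        return lo, lo, hi
    if state == "ELD-P-high":
        return lo, hi, hi
    if state == "ELD-P-low":
        return hi, lo, lo
    if state == "transgressive-up-M":
        return hi, hi * 2.0 ** e, lo
    if state == "transgressive-up-P":
        return lo, hi * 2.0 ** e, hi
    if state == "transgressive-down-M":
        return hi, lo * 2.0 ** -e, lo
    if state == "transgressive-down-P":
        return lo, lo * 2.0 ** -e, hi
    raise ConfigError(f"unknown planted state {state!r}")


def simulate_counts(cfg: SimConfig, feature_states: dict[str, str],
                    feature_patterns: dict[str, int] | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[CountTable, SimTruth]:
    """NB count table with planted inheritance states and, optionally,
    presence patterns (variety means zeroed outside the pattern subset).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 6)
    feature_patterns = feature_patterns or {}
    n_rep = cfg.n_replicates
    samples = [f"{v}{r + 1}" for v in ("M", "H", "P") for r in range(n_rep)]
    variety_of = (["maternal"] * n_rep + ["hybrid"] * n_rep
                  + ["paternal"] * n_rep)
    size_factors = np.exp(rng.uniform(np.log(0.7), np.log(1.4),
                                      size=len(samples)))
    pattern_subsets = {1: {"maternal"}, 2: {"hybrid"}, 3: {"paternal"},
                       4: {"maternal", "paternal"}, 5: {"hybrid", "paternal"},
                       6: {"maternal", "hybrid"},
                       7: {"maternal", "hybrid", "paternal"}}
    rows = []
    truth = SimTruth()
    for fid, state in feature_states.items():
        base = float(rng.lognormal(np.log(cfg.base_mean), 0.4))
        m, h, p = _state_means(state, base, cfg.effect_log2fc)
        means = {"maternal": m, "hybrid": h, "paternal": p}
        if fid in feature_patterns:
            keep = pattern_subsets[feature_patterns[fid]]
            means = {v: (x if v in keep else 0.0) for v, x in means.items()}
            truth.pattern_truth[fid] = feature_patterns[fid]
        mu = np.array([means[v] for v in variety_of]) * size_factors
        counts = _nb_draw(rng, mu, cfg.nb_dispersion)
        rows.append(counts)
        truth.inheritance_truth[fid] = state
    counts_df = pd.DataFrame(np.vstack(rows) if rows else np.zeros((0, len(samples))),
                             index=list(feature_states), columns=samples,
                             dtype=int)
    design = pd.DataFrame({
        "variety": variety_of,
        "replicate": [r + 1 for _ in ("M", "H", "P") for r in range(n_rep)],
    }, index=pd.Index(samples, name="sample_id"))
    return CountTable(counts_df, design), truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    out = np.zeros_like(mu, dtype=int)
    pos = mu > 0
    if dispersion < 1e-12:
        out[pos] = rng.poisson(mu[pos])
    else:
        n = 1.0 / dispersion
        p = n / (n + mu[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def bsj_benchmark_config(seed: int) -> SimConfig:
    """50 kb single-chromosome configuration for back-splice benchmarks.

    The gene geometry guarantees at least 32 junction sites (8 plus-strand
    genes with 6-9 exons, so >=4 internal exons each of >=150 nt) while the
    worst-case total gene footprint stays inside the chromosome.
    """
    return SimConfig(seed=seed, n_chrom=1, chrom_len=50_000, n_genes=8,
                     te_fraction=0.0, n_lncrna_per_class=0, n_circ=20,
                     n_mirna=0, exon_len_range=(150, 200),
                     intron_len_range=(300, 350), n_exons_range=(6, 9),
                     gene_spacing=300, plus_strand_fraction=1.0)


def simulate_inheritance_benchmark(cfg: SimConfig, n_per_state: int = 200,
                                   n_background: int | None = None,
                                   ) -> tuple[CountTable, dict[str, str]]:
    """Benchmark table: ``n_per_state`` features per plantable state plus
    a null background.

    Median-of-ratios normalization assumes a non-differential majority;
    with every feature planted DE the hybrid's size factor absorbs the
    planted composition and biases all hybrid fold changes. Real count
    data keeps most features non-DE, so the benchmark adds
    ``n_background`` null features (default: ten per planted feature)
    that take part in normalization but are excluded from the returned
    scoring truth.
    """
    if n_background is None:
        n_background = 10 * n_per_state * len(PLANTABLE_STATES)
    fs: dict[str, str] = {}
    for s in PLANTABLE_STATES:
        for i in range(n_per_state):
            fs[f"{s}_{i + 1}"] = s
    for i in range(n_background):
        fs[f"background_{i + 1}"] = "equivalent"
    table, truth = simulate_counts(cfg, fs)
    scored = {f: s for f, s in truth.inheritance_truth.items()
              if not f.startswith("background_")}
    return table, scored


def assign_states(feature_ids: list[str], rng: np.random.Generator,
                  states: tuple[str, ...] = PLANTABLE_STATES) -> dict[str, str]:
    """Round-robin state assignment over a feature list."""
    return {fid: states[i % len(states)] for i, fid in enumerate(feature_ids)}


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    cfg: SimConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    te: list[tuple[str, int, int]]
    lncrnas: list[TranscriptRecord]
    bsj_reads: dict[str, str]
    mirnas: dict[str, str]
    smallrna_reads: dict[str, str]
    transcript_seqs: dict[str, tuple[str, str]]
    counts: dict[str, CountTable]
    truth: SimTruth


def simulate_all(cfg: SimConfig) -> SimBundle:
    """Generate the complete synthetic study: genome, annotations, reads,
    planted targets and one count table per RNA class, all under one seed.
    """
    rng = np.random.default_rng(cfg.seed)
    genome, genes, te = simulate_genome(cfg, rng)
    lncrnas, lnc_truth = plant_lncrna_loci(cfg, genome, genes, rng)
    bsj_reads, circ_truth, genome = simulate_bsj_reads(cfg, genome, genes, rng)
    mirnas = simulate_mirna(cfg, rng)
    smallrna = simulate_smallrna_reads(cfg, mirnas, rng)

    tx_seqs: dict[str, tuple[str, str]] = {}
    for g in genes:
        tx = TranscriptRecord(g.gene_id, g.chrom, g.start, g.end, g.strand,
                              g.exons, "mRNA")
        tx_seqs[g.gene_id] = (tx.sequence(genome), "mRNA")
    for t in lncrnas:
        tx_seqs[t.transcript_id] = (t.sequence(genome), "lncRNA")
    for cid, info in circ_truth.items():
        if info["kind"] != "positive":
            continue
        a, d, chrom = info["acceptor"], info["donor"], info["chrom"]
        circ_seq = genome[chrom][a:d]
        # include the back-splice-crossing join so sites spanning it are visible
        join = circ_seq[-30:] + circ_seq[:30]
        tx_seqs[cid] = (circ_seq + join, "circRNA")
    tx_seqs, planted_targets, target_decoys = plant_target_sites(
        cfg, mirnas, tx_seqs, rng)

    truth = SimTruth(lncrna_class_truth=lnc_truth, circ_truth=circ_truth,
                     target_truth=planted_targets, target_decoys=target_decoys)

    counts: dict[str, CountTable] = {}
    class_features = {
        "mRNA": [g.gene_id for g in genes],
        "lncRNA": [t.transcript_id for t in lncrnas],
        "circRNA": [cid for cid, i in circ_truth.items()
                    if i["kind"] == "positive"],
        "miRNA": list(mirnas),
    }
    for rna_class, fids in class_features.items():
        states = assign_states(fids, rng)
        patterns = {fid: 1 + i % 7 for i, fid in enumerate(fids[:len(fids) // 3])}
        # features with a planted absence pattern are not scored for state
        for fid in patterns:
            states[fid] = "equivalent"
        table, t = simulate_counts(cfg, states, patterns, rng)
        counts[rna_class] = table
        for fid, st in t.inheritance_truth.items():
            if fid not in patterns:
                truth.inheritance_truth[fid] = st
        truth.pattern_truth.update(t.pattern_truth)

    # plant an ASEG table over a third of the genes, alternating bias
    for i, g in enumerate(genes[: max(len(genes) // 3, 1)]):
        truth.aseg_truth[g.gene_id] = "maternal" if i % 2 == 0 else "paternal"

    return SimBundle(cfg, genome, genes, te, lncrnas, bsj_reads, mirnas,
                     smallrna, tx_seqs, counts, truth)
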