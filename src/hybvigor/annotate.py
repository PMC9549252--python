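"""Positional classification of lncRNAs and sequence/structure annotation.

The four lncRNA positional classes are decided against the protein-coding
gene models: ``intronic`` (fully inside one intron, either strand, no exon
overlap), ``antisense`` (overlaps a gene span on the opposite strand),
``sense`` (overlaps an exon on the same strand) and ``lincRNA`` (no gene
span overlap). Overlapping cases resolve most-specific-first:
intronic > antisense > sense > lincRNA.

Coding ability is screened with a longest-ORF criterion: candidates whose
longest open reading frame (both strands, three frames, ATG..stop
inclusive) reaches 300 nt (100 codons) are treated as coding and dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .iolib import GeneModel, GenomeSequence, TranscriptRecord, revcomp

LNCRNA_CLASSES = ("lincRNA", "antisense", "sense", "intronic")
META_CATEGORIES = ("TE", "ncRNA-locus", "genic", "gene-proximal",
                   "intergenic", "no-annotation")

MIN_LNCRNA_LEN = 200
MAX_NONCODING_ORF = 300          # nt; 100 codons

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class LncRNAClass:
    transcript_id: str
    lnc_class: str                 # one of LNCRNA_CLASSES
    evidence: str                  # overlapping gene id or "none"


@dataclass
class FeatureStats:
    transcript_id: str
    length_nt: int
    longest_orf_nt: int
    n_exons: int
    n_te_contained: int


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

def _longest_orf_one_strand(seq: str) -> int:
    """Longest ATG..stop ORF (stop included) scanning three frames."""
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def find_longest_orf(seq: str) -> int:
    """Length (nt) of the longest ORF on either strand; 0 when none."""
    seq = seq.upper()
    return max(_longest_orf_one_strand(seq), _longest_orf_one_strand(revcomp(seq)))


# ---------------------------------------------------------------------------
# lncRNA candidate screening and positional classification
# ---------------------------------------------------------------------------

def screen_lncrna_candidates(transcripts: Sequence[TranscriptRecord],
                             genome: GenomeSequence,
                             min_len: int = MIN_LNCRNA_LEN,
                             max_orf: int = MAX_NONCODING_ORF,
                             min_exons: int = 1,
                             known_ids: set[str] | None = None,
                             ) -> list[TranscriptRecord]:
    """Keep unknown transcripts longer than ``min_len`` whose longest ORF
    stays below ``max_orf`` nt.

    ``min_exons`` is a configurable floor (default 1): raising it to 3
    reproduces an exons-greater-than-two screen, but single-exon lncRNA
    loci are widespread so the permissive default is kept.
    """
    known_ids = known_ids or set()
    kept = []
    for t in transcripts:
        if t.transcript_id in known_ids or t.rna_class == "mRNA":
            continue
        if t.length <= min_len:
            continue
        if max(len(t.exons), 1) < min_exons:
            continue
        if find_longest_orf(t.sequence(genome)) >= max_orf:
            continue
        kept.append(t)
    return kept


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def classify_lncrna_position(t: TranscriptRecord,
                             genes: Sequence[GeneModel]) -> LncRNAClass:
    """Classify one lncRNA transcript against the gene models.

    Precedence: intronic > antisense > sense > lincRNA. A transcript past
    a gene's chromosome is fine; coordinates beyond any annotation simply
    classify as lincRNA, but negative coordinates raise upstream.
    """
    intronic_hit = antisense_hit = sense_hit = None
    for g in genes:
        if g.chrom != t.chrom or not _overlaps(t.start, t.end, g.start, g.end):
            continue
        inside_intron = any(i_s <= t.start and t.end <= i_e for i_s, i_e in g.introns())
        exon_overlap = any(_overlaps(t.start, t.end, e_s, e_e) for e_s, e_e in g.exons)
        if inside_intron and not exon_overlap and intronic_hit is None:
            intronic_hit = g.gene_id
        elif g.strand != t.strand and antisense_hit is None:
            antisense_hit = g.gene_id
        elif g.strand == t.strand and exon_overlap and sense_hit is None:
            sense_hit = g.gene_id
        elif g.strand == t.strand and sense_hit is None:
            # same-strand span overlap without exon overlap and not inside a
            # single intron (e.g. crossing an exon boundary region): treat as
            # sense overlap of the gene body
            sense_hit = g.gene_id
    if intronic_hit:
        return LncRNAClass(t.transcript_id, "intronic", intronic_hit)
    if antisense_hit:
        return LncRNAClass(t.transcript_id, "antisense", antisense_hit)
    if sense_hit:
        return LncRNAClass(t.transcript_id, "sense", sense_hit)
    return LncRNAClass(t.transcript_id, "lincRNA", "none")


def classify_lncrna_positions(transcripts: Iterable[TranscriptRecord],
                              genes: Sequence[GeneModel]) -> pd.DataFrame:
    rows = [classify_lncrna_position(t, genes) for t in transcripts]
    return pd.DataFrame(
        [(r.transcript_id, r.lnc_class, r.evidence) for r in rows],
        columns=["transcript_id", "class", "evidence"]).set_index("transcript_id")


# ---------------------------------------------------------------------------
# TE containment, meta-features, densities
# ---------------------------------------------------------------------------

def count_te_contained(t: TranscriptRecord,
                       te_intervals: Sequence[tuple[str, int, int]]) -> int:
    """Number of TE intervals fully contained in the transcript span.

    A TE that merely overlaps the boundary counts 0.
    """
    return sum(1 for chrom, s, e in te_intervals
               if chrom == t.chrom and t.start <= s and e <= t.end)


def feature_stats(t: TranscriptRecord, genome: GenomeSequence,
                  te_intervals: Sequence[tuple[str, int, int]]) -> FeatureStats:
    return FeatureStats(
        transcript_id=t.transcript_id,
        length_nt=t.length,
        longest_orf_nt=find_longest_orf(t.sequence(genome)),
        n_exons=len(t.exons),
        n_te_contained=count_te_contained(t, te_intervals),
    )


def assign_meta_feature(chrom: str, start: int, end: int,
                        genes: Sequence[GeneModel],
                        ncrna_loci: Sequence[TranscriptRecord],
                        te_intervals: Sequence[tuple[str, int, int]],
                        annotated_chroms: set[str] | None = None,
                        proximal_bp: int = 2000) -> str:
    """Assign one locus to exactly one of the six genome meta-features.

    Priority: TE > ncRNA-locus > genic > gene-proximal (within
    ``proximal_bp`` of a gene span) > intergenic; ``no-annotation`` is
    reserved for loci on chromosomes absent from the annotation set.
    """
    if annotated_chroms is not None and chrom not in annotated_chroms:
        return "no-annotation"
    if any(c == chrom and _overlaps(start, end, s, e) for c, s, e in te_intervals):
        return "TE"
    if any(t.chrom == chrom and _overlaps(start, end, t.start, t.end)
           for t in ncrna_loci):
        return "ncRNA-locus"
    if any(g.chrom == chrom and _overlaps(start, end, g.start, g.end)
           for g in genes):
        return "genic"
    if any(g.chrom == chrom and _overlaps(start - proximal_bp, end + proximal_bp,
                                          g.start, g.end) for g in genes):
        return "gene-proximal"
    return "intergenic"


def filter_small_rna_reads(reads: dict[str, str],
                           min_len: int = 18, max_len: int = 30,
                           max_n_fraction: float = 0.10) -> dict[str, str]:
    """Small-RNA QC: keep reads of 18-30 nt with at most 10% N bases."""
    out = {}
    for rid, seq in reads.items():
        s = seq.upper()
        if not min_len <= len(s) <= max_len:
            continue
        if s.count("N") > max_n_fraction * len(s):
            continue
        out[rid] = s
    return out


def window_density(features: Iterable[tuple[str, int]],
                   chrom_lengths: dict[str, int],
                   window: int = 10_000) -> pd.DataFrame:
    """Per-window feature counts over non-overlapping tiling windows.

    ``features`` yields (chrom, start); a feature counts in the window
    containing its start, and the last partial window is kept.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts: dict[tuple[str, int], int] = {}
    for chrom, length in chrom_lengths.items():
        for w0 in range(0, length, window):
            counts[(chrom, w0)] = 0
    for chrom, start in features:
        if chrom not in chrom_lengths:
            raise ValueError(f"feature on unknown chromosome {chrom!r}")
        if not 0 <= start < chrom_lengths[chrom]:
            raise ValueError(f"feature start {start} outside {chrom}")
        counts[(chrom, (start // window) * window)] += 1
    rows = [(c, w0, min(w0 + window, chrom_lengths[c]), n)
            for (c, w0), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end", "count"])
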