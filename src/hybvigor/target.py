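"""miRNA target scoring, lncRNA cis/trans targets, circRNA host genes.

miRNA sites are scored with the plant small-RNA penalty scheme: the
miRNA and the site align antiparallel without gaps; each mismatch costs
1.0, each G:U wobble 0.5, and positions 2-13 from the miRNA 5' end are
double-weighted. Sites with penalty <= 4.0 are kept. Gapped sites are a
documented limitation.

lncRNA cis targets are genes within 100 kb of the locus; trans targets
are mRNAs sharing a long (>= 100 nt) near-perfect (>= 90% identity)
reverse-complement stretch, found by exact 20-mer seeding and ungapped
extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .iolib import GeneModel, TranscriptRecord, revcomp
from .bsj import BsjCandidate

PENALTY_CUTOFF = 4.0
CORE_START, CORE_END = 2, 13          # 1-based positions doubled in weight
CIS_WINDOW = 100_000
TRANS_MIN_MATCH = 100
TRANS_MIN_IDENTITY = 0.9
TRANS_SEED = 20


@dataclass
class TargetPair:
    regulator_id: str
    regulator_class: str               # miRNA | lncRNA
    target_id: str
    target_class: str                  # mRNA | lncRNA | circRNA
    mode: str                          # complementarity | cis | trans
    score: float                       # penalty (lower better) or distance bp
    position: int = -1                 # site start on the target, if any


# ---------------------------------------------------------------------------
# miRNA complementarity
# ---------------------------------------------------------------------------

_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}     # G:U in RNA terms


def mirna_target_score(mirna_seq: str, site_seq: str) -> float:
    """Penalty of an ungapped antiparallel miRNA:site duplex.

    ``site_seq`` is the target subsequence 5'->3'; miRNA position ``i``
    (5' end, 0-based) pairs with site position ``len-1-i``. Mismatch 1.0,
    G:U wobble 0.5, doubled at miRNA positions 2-13 (1-based).
    """
    m = mirna_seq.upper().replace("U", "T")
    s = site_seq.upper().replace("U", "T")
    if len(m) != len(s):
        raise ValueError("site length must equal miRNA length")
    penalty = 0.0
    n = len(m)
    for i in range(n):
        pair = (m[i], s[n - 1 - i])
        if pair in _PAIR:
            cost = 0.0
        elif pair in _WOBBLE:
            cost = 0.5
        else:
            cost = 1.0
        if CORE_START <= i + 1 <= CORE_END:
            cost *= 2.0
        penalty += cost
    return penalty


def scan_targets(mirna_id: str, mirna_seq: str,
                 transcripts: Mapping[str, tuple[str, str]],
                 cutoff: float = PENALTY_CUTOFF) -> list[TargetPair]:
    """Slide a miRNA-length window over each transcript and report all
    sites with penalty <= cutoff.

    ``transcripts`` maps target id -> (sequence, target_class). circRNA
    sequences should already include the back-splice-crossing join.
    """
    n = len(mirna_seq)
    out: list[TargetPair] = []
    for tid, (seq, tclass) in transcripts.items():
        seq = seq.upper().replace("U", "T")
        best: tuple[float, int] | None = None
        for i in range(len(seq) - n + 1):
            p = mirna_target_score(mirna_seq, seq[i:i + n])
            if p <= cutoff and (best is None or p < best[0]):
                best = (p, i)
        if best is not None:
            out.append(TargetPair(mirna_id, "miRNA", tid, tclass,
                                  "complementarity", best[0], best[1]))
    return out


def scan_targets_all_sites(mirna_id: str, mirna_seq: str,
                           transcripts: Mapping[str, tuple[str, str]],
                           cutoff: float = PENALTY_CUTOFF) -> list[TargetPair]:
    """Like :func:`scan_targets` but reporting every qualifying site."""
    n = len(mirna_seq)
    out: list[TargetPair] = []
    for tid, (seq, tclass) in transcripts.items():
        seq = seq.upper().replace("U", "T")
        for i in range(len(seq) - n + 1):
            p = mirna_target_score(mirna_seq, seq[i:i + n])
            if p <= cutoff:
                out.append(TargetPair(mirna_id, "miRNA", tid, tclass,
                                      "complementarity", p, i))
    return out


# ---------------------------------------------------------------------------
# lncRNA cis / trans targets
# ---------------------------------------------------------------------------

def cis_targets(lncrna: TranscriptRecord, genes: Sequence[GeneModel],
                window: int = CIS_WINDOW) -> list[TargetPair]:
    """Genes whose span overlaps [start - window, end + window), either
    strand; distance 0 when overlapping, else the gap length."""
    out = []
    for g in genes:
        if g.chrom != lncrna.chrom:
            continue
        if g.start < lncrna.end + window and lncrna.start - window < g.end:
            if g.start < lncrna.end and lncrna.start < g.end:
                dist = 0
            elif g.start >= lncrna.end:
                dist = g.start - lncrna.end
            else:
                dist = lncrna.start - g.end
            out.append(TargetPair(lncrna.transcript_id, "lncRNA", g.gene_id,
                                  "mRNA", "cis", float(dist)))
    return out


def trans_targets(lncrna_id: str, lncrna_seq: str,
                  mrna_seqs: Mapping[str, str],
                  min_match: int = TRANS_MIN_MATCH,
                  min_identity: float = TRANS_MIN_IDENTITY) -> list[TargetPair]:
    """mRNAs sharing a reverse-complement match of >= min_match nt at
    >= min_identity, found by exact 20-mer seeding and ungapped extension.
    """
    query = revcomp(lncrna_seq.upper())
    if len(query) < min_match:
        return []
    seeds: dict[str, list[int]] = {}
    for i in range(len(query) - TRANS_SEED + 1):
        seeds.setdefault(query[i:i + TRANS_SEED], []).append(i)
    out = []
    for mid, mseq in mrna_seqs.items():
        mseq = mseq.upper()
        best_len = 0
        hit_positions = set()
        for j in range(len(mseq) - TRANS_SEED + 1):
            for qi in seeds.get(mseq[j:j + TRANS_SEED], ()):
                anchor = (qi - j)
                if anchor in hit_positions:
                    continue
                hit_positions.add(anchor)
                length = _extend_match(query, mseq, qi, j, min_identity)
                best_len = max(best_len, length)
        if best_len >= min_match:
            out.append(TargetPair(lncrna_id, "lncRNA", mid, "mRNA",
                                  "trans", float(best_len)))
    return out


def _extend_match(q: str, s: str, qi: int, sj: int, min_identity: float) -> int:
    """Longest ungapped window through the seed keeping identity >= threshold.

    Greedy symmetric extension: grow the aligned window outward one base
    at a time while the running identity stays at or above the threshold.
    """
    lo_q, lo_s = qi, sj
    hi_q, hi_s = qi + TRANS_SEED, sj + TRANS_SEED
    matches = TRANS_SEED
    length = TRANS_SEED
    improved = True
    while improved:
        improved = False
        if hi_q < len(q) and hi_s < len(s):
            add = 1 if q[hi_q] == s[hi_s] else 0
            if (matches + add) / (length + 1) >= min_identity:
                matches, length = matches + add, length + 1
                hi_q, hi_s = hi_q + 1, hi_s + 1
                improved = True
        if lo_q > 0 and lo_s > 0:
            add = 1 if q[lo_q - 1] == s[lo_s - 1] else 0
            if (matches + add) / (length + 1) >= min_identity:
                matches, length = matches + add, length + 1
                lo_q, lo_s = lo_q - 1, lo_s - 1
                improved = True
    return length


# ---------------------------------------------------------------------------
# circRNA host genes
# ---------------------------------------------------------------------------

@dataclass
class HostAssignment:
    circ_id: str
    host_gene_id: str                  # or "intergenic"


def assign_host_gene(circ: BsjCandidate,
                     genes: Sequence[GeneModel]) -> HostAssignment:
    """The gene whose span contains [acceptor, donor); ties break to the
    smallest containing span; no containing gene -> "intergenic"."""
    best: GeneModel | None = None
    for g in genes:
        if (g.chrom == circ.chrom and g.start <= circ.acceptor
                and circ.donor <= g.end):
            if best is None or (g.end - g.start) < (best.end - best.start):
                best = g
    return HostAssignment(circ.circ_id,
                          best.gene_id if best is not None else "intergenic")


def target_pairs_frame(pairs: Iterable[TargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.regulator_id, p.regulator_class, p.target_id, p.target_class,
          p.mode, p.score, p.position) for p in pairs],
        columns=["regulator", "regulator_class", "target", "target_class",
                 "mode", "score", "position"])
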