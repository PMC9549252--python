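"""Back-splice junction (BSJ) detection for circRNA calling.

A read that crosses a back-splice junction cannot be placed colinearly on
the genome: its 20 bp head anchor lands downstream of its 20 bp tail
anchor. Detection aligns both anchors with a k-mer index (up to two
mismatches via pigeonhole seeding on exact one-third seeds), extends the two
anchor placements toward each other to explain the whole read, and puts
the breakpoint where the canonical splice signal (GT at the donor side,
AG at the acceptor side; CT..AC on the plus strand for minus-strand
circles) flanks the genomic gap.

Candidate junctions grouped by locus then pass a six-rule screen:

1. GT/AG splice signal on both sides of the junction.
2. A single best signal-consistent breakpoint.
3. At most two mismatches per supporting read.
4. Breakpoint ambiguity of at most 2 nt.
5. At least two supporting reads.
6. The best placement scores more than 35 points above the runner-up
   (match +1, mismatch -5 over the full read).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .iolib import ConfigError, GenomeSequence, circ_id, revcomp

ANCHOR_LEN = 20
MAX_MISMATCH = 2
MAX_LOCI = 50
MIN_SUPPORT = 2
MIN_SCORE_MARGIN = 35
MAX_BREAKPOINT_AMBIGUITY = 2
MISMATCH_PENALTY = 5


@dataclass
class AnchorHit:
    chrom: str
    pos: int                      # 0-based start of the 20-mer placement
    strand: str
    mismatches: int
    read_id: str = ""
    side: str = ""                # head | tail

    @property
    def score(self) -> int:
        return ANCHOR_LEN - MISMATCH_PENALTY * self.mismatches


@dataclass
class BsjCandidate:
    """A putative back-splice junction from one read or a read group.

    ``acceptor`` and ``donor`` are the genomic junction coordinates with
    acceptor < donor (plus-strand frame); on the minus strand the
    biological donor/acceptor roles are mirrored but the stored interval
    is identical, which keeps the ``chrom:acceptor|donor`` id joinable
    across strands.
    """

    chrom: str
    acceptor: int                 # 0-based, first base inside the circle
    donor: int                    # 0-based exclusive end of the circle
    strand: str
    splice_signal: str            # biological donor+acceptor flanks, e.g. GTAG
    mismatches: int               # of the supporting read placement
    breakpoint_ambiguity: int     # equally-best breakpoints for the read
    n_signal_breakpoints: int     # equally-best breakpoints with valid signal
    score: int                    # read placement score (match +1 / mismatch -5)
    score_margin: int             # best minus second-best placement score
    support_reads: int = 1
    read_ids: list[str] = field(default_factory=list)

    @property
    def circ_id(self) -> str:
        return circ_id(self.chrom, self.donor, self.acceptor)


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact-location lookup of genomic k-mers (plus the short exact
    seeds needed for mismatch-tolerant anchor alignment).

    The seed length is k // 3 so that an anchor placed with up to two
    substitutions always keeps at least one of its three disjoint
    one-third seeds exact (pigeonhole over three parts)."""

    def __init__(self, genome: GenomeSequence, k: int = ANCHOR_LEN) -> None:
        if k < 6:
            raise ConfigError("anchor length must be at least 6")
        if k > min(genome.chrom_lengths().values()):
            raise ConfigError("k exceeds the shortest chromosome")
        self.genome = genome
        self.k = k
        self.seed_len = k // 3
        self._full: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self._seed: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                self._full[seq[i:i + k]].append((chrom, i))
            for i in range(len(seq) - self.seed_len + 1):
                self._seed[seq[i:i + self.seed_len]].append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return list(self._full.get(kmer, ()))

    def seed_lookup(self, seed: str) -> list[tuple[str, int]]:
        return list(self._seed.get(seed, ()))


def build_index(genome: GenomeSequence, k: int = ANCHOR_LEN) -> KmerIndex:
    return KmerIndex(genome, k)


# ---------------------------------------------------------------------------
# anchor alignment
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str, cap: int = 10 ** 9) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def _forward_hits(anchor: str, index: KmerIndex,
                  max_mismatch: int) -> dict[tuple[str, int], int]:
    """Placements of ``anchor`` on the forward genome with <= max_mismatch.

    Exact hits come from the full-length index; mismatch hits are seeded
    by the three disjoint one-third seeds (pigeonhole: two substitutions
    over three parts leave at least one part exact) and verified
    full-length.
    """
    k, seed_len = index.k, index.seed_len
    hits: dict[tuple[str, int], int] = {}
    for chrom, pos in index.lookup(anchor):
        hits[(chrom, pos)] = 0
    if max_mismatch > 0:
        cand: set[tuple[str, int]] = set()
        for off in (0, seed_len, 2 * seed_len):
            for chrom, pos in index.seed_lookup(anchor[off:off + seed_len]):
                cand.add((chrom, pos - off))
        for chrom, pos in cand:
            if (chrom, pos) in hits:
                continue
            seq = index.genome[chrom]
            if pos < 0 or pos + k > len(seq):
                continue
            mm = _hamming(anchor, seq[pos:pos + k], cap=max_mismatch)
            if mm <= max_mismatch:
                hits[(chrom, pos)] = mm
    return hits


def align_anchor(anchor: str, index: KmerIndex,
                 max_mismatch: int = MAX_MISMATCH) -> list[AnchorHit]:
    """All placements of a 20 bp anchor on either strand with at most
    ``max_mismatch`` substitutions."""
    if len(anchor) != index.k:
        raise ConfigError(f"anchor must be {index.k} bp")
    out = [AnchorHit(c, p, "+", mm)
           for (c, p), mm in sorted(_forward_hits(anchor, index, max_mismatch).items())]
    out += [AnchorHit(c, p, "-", mm)
            for (c, p), mm in sorted(_forward_hits(revcomp(anchor), index,
                                                   max_mismatch).items())]
    return out


# ---------------------------------------------------------------------------
# back-splice detection
# ---------------------------------------------------------------------------

def _pair_candidates(seq: str, strand: str, index: KmerIndex,
                     max_mismatch: int) -> list[BsjCandidate]:
    """Enumerate non-colinear (tail upstream of head) placements of one
    read in the plus-strand frame and pick the best breakpoint of each."""
    genome = index.genome
    L = len(seq)
    k = index.k
    head_hits = _forward_hits(seq[:k], index, max_mismatch)
    tail_hits = _forward_hits(seq[-k:], index, max_mismatch)
    if len(head_hits) > MAX_LOCI or len(tail_hits) > MAX_LOCI:
        raise _TooManyLoci()
    out: list[BsjCandidate] = []
    for (chrom_h, h) in head_hits:
        for (chrom_t, t) in tail_hits:
            if chrom_t != chrom_h or t + k > h:
                continue                      # need reversed genomic order
            cand = _best_breakpoint(seq, genome[chrom_h], chrom_h, h, t, strand, k)
            if cand is not None:
                out.append(cand)
    return out


def _padded(g: str, start: int, end: int) -> str:
    """Genome slice padded with '?' outside the chromosome."""
    left = "?" * max(0, -start)
    right = "?" * max(0, end - len(g))
    return left + g[max(start, 0):min(end, len(g))] + right


def _best_breakpoint(seq: str, g: str, chrom: str, h: int, t: int,
                     strand: str, k: int) -> BsjCandidate | None:
    """For one (head, tail) placement pair, scan breakpoints b in
    [k, L-k]: read[:b] matches genome[h:h+b] (ending at the donor-side
    coordinate d = h+b) and read[b:] matches the segment ending at t+k
    (starting at the acceptor-side coordinate a)."""
    L = len(seq)
    tail_start = (t + k) - L        # genomic start if the whole read sat here
    # prefix mismatches of read[:i] vs genome starting at h ('?' pads never match)
    read_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pre = np.cumsum(read_arr != np.frombuffer(
        _padded(g, h, h + L).encode(), dtype=np.uint8))
    # suffix mismatches of read[i:] vs genome ending at t+k
    suf_arr = read_arr != np.frombuffer(
        _padded(g, tail_start, t + k).encode(), dtype=np.uint8)
    suf = np.concatenate([np.cumsum(suf_arr[::-1])[::-1], [0]])
    best_mm = None
    best_bs: list[int] = []
    for b in range(k, L - k + 1):
        a = tail_start + b
        if a < 2 or h + b + 2 > len(g):   # room for the splice flanks
            continue
        mm = int(pre[b - 1]) + int(suf[b])
        if best_mm is None or mm < best_mm:
            best_mm, best_bs = mm, [b]
        elif mm == best_mm:
            best_bs.append(b)
    if best_mm is None or best_mm > MAX_MISMATCH:
        return None
    want = ("GT", "AG") if strand == "+" else ("AC", "CT")
    signal_bs = []
    for b in best_bs:
        d, a = h + b, tail_start + b
        donor_flank = g[d:d + 2]
        acceptor_flank = g[a - 2:a]
        if strand == "+":
            ok = donor_flank == want[0] and acceptor_flank == want[1]
        else:
            ok = acceptor_flank == want[0] and donor_flank == want[1]
        if ok:
            signal_bs.append(b)
    b = signal_bs[0] if signal_bs else best_bs[0]
    d, a = h + b, tail_start + b
    if strand == "+":
        signal = g[d:d + 2] + g[a - 2:a]
    else:
        signal = revcomp(g[a - 2:a]) + revcomp(g[d:d + 2])
    score = L - (1 + MISMATCH_PENALTY) * best_mm
    return BsjCandidate(
        chrom=chrom, acceptor=a, donor=d, strand=strand,
        splice_signal=signal, mismatches=best_mm,
        breakpoint_ambiguity=len(best_bs),
        n_signal_breakpoints=len(signal_bs),
        score=score, score_margin=score)


class _TooManyLoci(Exception):
    pass


def detect_backsplice(read_id: str, read: str, index: KmerIndex,
                      max_mismatch: int = MAX_MISMATCH) -> BsjCandidate | None:
    """Best back-splice candidate explaining one read, or None.

    Both read orientations are tried (the reverse complement yields
    minus-strand candidates). The returned candidate records the
    breakpoint ambiguity and the score margin over the second-best
    placement across all candidate loci; reads whose anchors hit more
    than 50 loci are discarded.
    """
    read = read.upper()
    if len(read) < 2 * index.k:
        return None
    try:
        cands = (_pair_candidates(read, "+", index, max_mismatch)
                 + _pair_candidates(revcomp(read), "-", index, max_mismatch))
    except _TooManyLoci:
        return None
    if not cands:
        return None
    cands.sort(key=lambda c: (-c.score, c.chrom, c.acceptor, c.donor, c.strand))
    best = cands[0]
    margin = best.score - cands[1].score if len(cands) > 1 else best.score
    best.score_margin = margin
    best.read_ids = [read_id]
    return best


# ---------------------------------------------------------------------------
# grouping and the six-rule screen
# ---------------------------------------------------------------------------

def group_candidates(per_read: list[BsjCandidate]) -> list[BsjCandidate]:
    """Merge per-read candidates by (chrom, acceptor, donor, strand)."""
    groups: dict[tuple, BsjCandidate] = {}
    for c in per_read:
        key = (c.chrom, c.acceptor, c.donor, c.strand)
        if key not in groups:
            groups[key] = BsjCandidate(
                chrom=c.chrom, acceptor=c.acceptor, donor=c.donor,
                strand=c.strand, splice_signal=c.splice_signal,
                mismatches=c.mismatches,
                breakpoint_ambiguity=c.breakpoint_ambiguity,
                n_signal_breakpoints=c.n_signal_breakpoints,
                score=c.score, score_margin=c.score_margin,
                support_reads=0, read_ids=[])
        grp = groups[key]
        grp.support_reads += 1
        grp.read_ids.extend(c.read_ids)
        grp.mismatches = max(grp.mismatches, c.mismatches)
        grp.breakpoint_ambiguity = max(grp.breakpoint_ambiguity,
                                       c.breakpoint_ambiguity)
        grp.n_signal_breakpoints = max(grp.n_signal_breakpoints,
                                       c.n_signal_breakpoints)
        grp.score = max(grp.score, c.score)
        grp.score_margin = min(grp.score_margin, c.score_margin)
    return sorted(groups.values(),
                  key=lambda c: (c.chrom, c.acceptor, c.donor, c.strand))


def screen_rules(c: BsjCandidate) -> dict[str, bool]:
    """Evaluate the six screening rules on a grouped candidate."""
    return {
        "rule1_gt_ag": c.splice_signal == "GTAG",
        "rule2_specific_breakpoint": c.n_signal_breakpoints == 1,
        "rule3_max2_mismatches": c.mismatches <= MAX_MISMATCH,
        "rule4_breakpoint_le2nt": c.breakpoint_ambiguity <= MAX_BREAKPOINT_AMBIGUITY,
        "rule5_min2_reads": c.support_reads >= MIN_SUPPORT,
        "rule6_score_margin": c.score_margin > MIN_SCORE_MARGIN,
    }


def screen_candidates(grouped: list[BsjCandidate]) -> list[BsjCandidate]:
    """Keep candidates satisfying all six rules."""
    return [c for c in grouped if all(screen_rules(c).values())]


def detect_from_reads(reads: dict[str, str], index: KmerIndex,
                      ) -> tuple[list[BsjCandidate], list[BsjCandidate]]:
    """Run detection + grouping + screening over a read set.

    Returns (all grouped candidates, screened candidates).
    """
    per_read = []
    for rid, seq in reads.items():
        cand = detect_backsplice(rid, seq, index)
        if cand is not None:
            per_read.append(cand)
    grouped = group_candidates(per_read)
    return grouped, screen_candidates(grouped)


def quantify_junction(screened: list[BsjCandidate],
                      total_mapped_reads: int) -> dict[str, float]:
    """SRPBM per screened junction (delegates to express.srpbm)."""
    from .express import srpbm
    return {c.circ_id: float(srpbm(c.support_reads, total_mapped_reads))
            for c in screened}
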