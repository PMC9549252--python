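import numpy as np
import pytest

from hybvigor.bsj import BsjCandidate
from hybvigor.iolib import GeneModel, TranscriptRecord, revcomp
from hybvigor.target import (PENALTY_CUTOFF, assign_host_gene, cis_targets,
                             mirna_target_score, scan_targets,
                             scan_targets_all_sites, target_pairs_frame,
                             trans_targets)

MIRNA = "TGACAGAAGAGAGTGAGCACA"          # 21 nt


def _perfect_site(mirna=MIRNA):
    return revcomp(mirna)


# ---------------------------------------------------------------------------
# penalty oracles
# ---------------------------------------------------------------------------

def test_score_perfect_site_is_zero():
    assert mirna_target_score(MIRNA, _perfect_site()) == 0.0


def test_score_mismatch_position_weighting():
    # miRNA position i (0-based) pairs with site position n-1-i
    n = len(MIRNA)
    site = list(_perfect_site())
    # mismatch opposite miRNA position 5 (1-based, inside the 2-13 core): 2.0
    site[n - 5] = {"A": "C", "C": "A", "G": "A", "T": "G"}[site[n - 5]]
    assert mirna_target_score(MIRNA, "".join(site)) == 2.0
    # mismatch opposite miRNA position 1 (outside the core): 1.0
    site = list(_perfect_site())
    site[n - 1] = {"A": "C", "C": "A", "G": "A", "T": "G"}[site[n - 1]]
    assert mirna_target_score(MIRNA, "".join(site)) == 1.0


def test_score_gu_wobble():
    mirna = "G" + MIRNA[1:]
    site = list(_perfect_site(mirna))
    n = len(mirna)
    site[n - 1] = "T"                    # G:U at miRNA position 1 -> 0.5
    assert mirna_target_score(mirna, "".join(site)) == 0.5
    mirna3 = MIRNA[:2] + "G" + MIRNA[3:]
    site = list(_perfect_site(mirna3))
    site[n - 3] = "T"                    # G:U at position 3 (core) -> 1.0
    assert mirna_target_score(mirna3, "".join(site)) == 1.0


def test_score_accepts_rna_alphabet():
    assert mirna_target_score(MIRNA.replace("T", "U"),
                              _perfect_site().replace("T", "U")) == 0.0


def test_score_length_mismatch_raises():
    with pytest.raises(ValueError):
        mirna_target_score(MIRNA, "ACGT")


# ---------------------------------------------------------------------------
# target scanning
# ---------------------------------------------------------------------------

def _random_seq(n, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


def test_scan_targets_finds_planted_site():
    bg = _random_seq(300, 1)
    seq = bg[:100] + _perfect_site() + bg[100:]
    hits = scan_targets("mir1", MIRNA, {"t1": (seq, "mRNA")})
    assert len(hits) == 1
    assert hits[0].position == 100
    assert hits[0].score == 0.0
    assert hits[0].target_class == "mRNA"


def test_scan_targets_cutoff_is_inclusive():
    site = list(_perfect_site())
    n = len(MIRNA)
    # two core mismatches = 4.0, exactly at the cutoff -> kept
    for pos in (5, 8):
        site[n - pos] = {"A": "C", "C": "A", "G": "A", "T": "G"}[site[n - pos]]
    hits = scan_targets("mir1", MIRNA, {"t": ("".join(site), "lncRNA")},
                        cutoff=PENALTY_CUTOFF)
    assert len(hits) == 1 and hits[0].score == 4.0
    # one more core mismatch pushes past the cutoff
    site[n - 11] = {"A": "C", "C": "A", "G": "A", "T": "G"}[site[n - 11]]
    assert scan_targets("mir1", MIRNA, {"t": ("".join(site), "lncRNA")}) == []


def test_scan_targets_all_sites_reports_every_hit():
    seq = _perfect_site() + "CCCCC" + _perfect_site()
    hits = scan_targets_all_sites("mir1", MIRNA, {"t": (seq, "circRNA")})
    assert [h.position for h in hits] == [0, len(MIRNA) + 5]


# ---------------------------------------------------------------------------
# lncRNA cis / trans targets
# ---------------------------------------------------------------------------

def test_cis_targets_window_boundary():
    lnc = TranscriptRecord("l1", "chr1", 200_000, 201_000, "+",
                           [(200_000, 201_000)], "lncRNA")
    near = GeneModel("near", "chr1", 250_000, 251_000, "+", [(250_000, 251_000)])
    edge = GeneModel("edge", "chr1", 301_000, 302_000, "+", [(301_000, 302_000)])
    overlapping = GeneModel("ovl", "chr1", 200_500, 200_600, "+",
                            [(200_500, 200_600)])
    other = GeneModel("oc", "chr2", 200_000, 201_000, "+", [(200_000, 201_000)])
    out = {p.target_id: p.score for p in
           cis_targets(lnc, [near, edge, overlapping, other])}
    assert set(out) == {"near", "ovl"}
    assert out["near"] == 49_000.0
    assert out["ovl"] == 0.0


def test_trans_targets_planted_complement():
    lnc = _random_seq(400, 3)
    mrna = _random_seq(500, 4)
    insert = revcomp(lnc[100:220])       # 120 nt perfect complement
    mrna = mrna[:200] + insert + mrna[200:]
    hits = trans_targets("l1", lnc, {"m1": mrna, "m2": _random_seq(500, 5)})
    assert [h.target_id for h in hits] == ["m1"]
    assert hits[0].score >= 120


def test_trans_targets_short_match_rejected():
    lnc = _random_seq(400, 6)
    mrna = _random_seq(300, 7) + revcomp(lnc[100:150])   # only 50 nt
    assert trans_targets("l1", lnc, {"m1": mrna}) == []


# ---------------------------------------------------------------------------
# circRNA host genes
# ---------------------------------------------------------------------------

def _circ(a, d):
    return BsjCandidate(chrom="chr1", acceptor=a, donor=d, strand="+",
                        splice_signal="GTAG", mismatches=0,
                        breakpoint_ambiguity=1, n_signal_breakpoints=1,
                        score=150, score_margin=150)


def test_assign_host_gene_smallest_containing():
    big = GeneModel("big", "chr1", 0, 10_000, "+", [(0, 10_000)])
    small = GeneModel("small", "chr1", 400, 2_000, "+", [(400, 2_000)])
    assert assign_host_gene(_circ(500, 1_500), [big, small]).host_gene_id == "small"
    assert assign_host_gene(_circ(500, 1_500), [big]).host_gene_id == "big"
    assert assign_host_gene(_circ(20_000, 21_000), [big, small]).host_gene_id \
        == "intergenic"


def test_target_pairs_frame_columns():
    hits = scan_targets("mir1", MIRNA, {"t1": (_perfect_site(), "mRNA")})
    df = target_pairs_frame(hits)
    assert list(df.columns) == ["regulator", "regulator_class", "target",
                                "target_class", "mode", "score", "position"]
    assert df.loc[0, "regulator"] == "mir1"
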