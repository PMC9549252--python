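import numpy as np
import pytest

from hybvigor import bsj
from hybvigor.bsj import (KmerIndex, align_anchor, build_index,
                          detect_backsplice, detect_from_reads,
                          group_candidates, quantify_junction, screen_rules)
from hybvigor.iolib import ConfigError, GenomeSequence, revcomp

READ_LEN = 150
A, D = 300, 800          # acceptor / donor of the planted plus-strand circle


def _make_genome(seed=101):
    rng = np.random.default_rng(seed)
    g = list("".join(rng.choice(list("ACGT"), size=2000)))
    # canonical splice flanks: AG before the acceptor, GT after the donor
    g[A - 2:A] = "AG"
    g[D:D + 2] = "GT"
    # breakpoint uniqueness: g[a] != g[d] and g[a-1] != g[d-1]
    g[A] = "C"            # g[D] is "G"
    g[D - 1] = "A"        # g[A-1] is "G"
    return GenomeSequence({"chr1": "".join(g)})


def _junction_read(genome, l1=70):
    g = genome["chr1"]
    return g[D - l1:D] + g[A:A + READ_LEN - l1]


@pytest.fixture(scope="module")
def genome():
    return _make_genome()


@pytest.fixture(scope="module")
def index(genome):
    return build_index(genome)


# ---------------------------------------------------------------------------
# anchor alignment
# ---------------------------------------------------------------------------

def test_align_anchor_exact(genome, index):
    anchor = genome["chr1"][500:520]
    hits = align_anchor(anchor, index)
    assert any(h.pos == 500 and h.strand == "+" and h.mismatches == 0
               for h in hits)


def test_align_anchor_one_mismatch(genome, index):
    anchor = list(genome["chr1"][500:520])
    anchor[7] = {"A": "C", "C": "A", "G": "T", "T": "G"}[anchor[7]]
    hits = align_anchor("".join(anchor), index)
    assert any(h.pos == 500 and h.mismatches == 1 for h in hits)


def test_align_anchor_three_mismatches_rejected(genome, index):
    anchor = list(genome["chr1"][500:520])
    for i in (3, 9, 15):
        anchor[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[anchor[i]]
    assert align_anchor("".join(anchor), index) == []


def test_align_anchor_minus_strand(genome, index):
    hits = align_anchor(revcomp(genome["chr1"][500:520]), index)
    assert any(h.pos == 500 and h.strand == "-" and h.mismatches == 0
               for h in hits)


def test_align_anchor_wrong_length(index):
    with pytest.raises(ConfigError):
        align_anchor("ACGT", index)


# ---------------------------------------------------------------------------
# back-splice detection
# ---------------------------------------------------------------------------

def test_detect_plus_strand_junction(genome, index):
    c = detect_backsplice("r1", _junction_read(genome), index)
    assert c is not None
    assert (c.chrom, c.acceptor, c.donor, c.strand) == ("chr1", A, D, "+")
    assert c.splice_signal == "GTAG"
    assert c.mismatches == 0
    assert c.breakpoint_ambiguity == 1


def test_detect_minus_strand_junction():
    # CT..AC on the plus strand = a minus-strand GT/AG circle
    rng = np.random.default_rng(202)
    g = list("".join(rng.choice(list("ACGT"), size=2000)))
    g[A - 2:A] = "AC"
    g[D:D + 2] = "CT"
    g[A] = "G"
    g[D - 1] = "T"
    genome = GenomeSequence({"chr1": "".join(g)})
    read = revcomp(_junction_read(genome, l1=60))
    c = detect_backsplice("r1", read, build_index(genome))
    assert c is not None
    assert (c.acceptor, c.donor, c.strand) == (A, D, "-")
    assert c.splice_signal == "GTAG"


def test_detect_breakpoint_independent_of_split(genome, index):
    for l1 in (30, 75, 120):
        c = detect_backsplice("r", _junction_read(genome, l1), index)
        assert (c.acceptor, c.donor) == (A, D)


def test_detect_tolerates_two_mismatches(genome, index):
    read = list(_junction_read(genome))
    for i in (40, 110):
        read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
    c = detect_backsplice("r", "".join(read), index)
    assert c is not None and c.mismatches == 2


def test_detect_rejects_three_mismatches(genome, index):
    read = list(_junction_read(genome))
    for i in (25, 75, 125):
        read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
    assert detect_backsplice("r", "".join(read), index) is None


def test_detect_ignores_colinear_read(genome, index):
    assert detect_backsplice("r", genome["chr1"][400:550], index) is None


def test_detect_ignores_short_read(index):
    assert detect_backsplice("r", "ACGT" * 9, index) is None


# ---------------------------------------------------------------------------
# grouping, screening, quantification
# ---------------------------------------------------------------------------

def test_group_and_screen_pass(genome, index):
    reads = {f"r{i}": _junction_read(genome, l1) for i, l1 in
             enumerate((40, 70, 100))}
    grouped, screened = detect_from_reads(reads, index)
    assert len(grouped) == 1
    assert grouped[0].support_reads == 3
    assert all(screen_rules(grouped[0]).values())
    assert len(screened) == 1
    assert screened[0].circ_id == f"chr1:{A}|{D}"


def test_single_read_fails_rule5(genome, index):
    grouped, screened = detect_from_reads({"r": _junction_read(genome)}, index)
    assert len(grouped) == 1
    rules = screen_rules(grouped[0])
    assert not rules["rule5_min2_reads"]
    assert screened == []


def test_quantify_junction_srpbm(genome, index):
    reads = {f"r{i}": _junction_read(genome, l1) for i, l1 in
             enumerate((40, 70))}
    _, screened = detect_from_reads(reads, index)
    out = quantify_junction(screened, 1_000_000)
    assert out[f"chr1:{A}|{D}"] == pytest.approx(2 / 1e6 * 1e9)


# ---------------------------------------------------------------------------
# generator-built benchmark: every decoy family fails its rule
# ---------------------------------------------------------------------------

def test_benchmark_decoys_rejected(bsj_sim):
    genome, _genes, reads, truth = bsj_sim
    index = build_index(genome)
    grouped, screened = detect_from_reads(reads, index)
    true_ids = {cid for cid, rec in truth.items() if rec["kind"] == "positive"}
    assert {c.circ_id for c in screened} == true_ids
    by_id = {c.circ_id: c for c in grouped}
    for cid, rec in truth.items():
        if rec["kind"] == "positive":
            continue
        cand = by_id.get(cid)
        if cand is None:
            continue             # decoy never produced a candidate: rejected
        assert not all(screen_rules(cand).values())
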