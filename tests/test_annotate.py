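import pytest

from hybvigor import annotate
from hybvigor.annotate import (assign_meta_feature, classify_lncrna_position,
                               count_te_contained, filter_small_rna_reads,
                               find_longest_orf, screen_lncrna_candidates,
                               window_density)
from hybvigor.iolib import GeneModel, GenomeSequence, TranscriptRecord, revcomp


# ---------------------------------------------------------------------------
# ORF finder oracles
# ---------------------------------------------------------------------------

def test_orf_simple():
    assert find_longest_orf("ATGAAATAA") == 9


def test_orf_reverse_strand():
    assert find_longest_orf(revcomp("ATGAAATAA")) == 9


def test_orf_requires_stop():
    assert find_longest_orf("ATGAAAAAA") == 0


def test_orf_none():
    assert find_longest_orf("CCCCCCCCCCCC") == 0


def test_orf_out_of_frame_start_ignored():
    # ATG only in frame 2 of the embedded context
    assert find_longest_orf("CCATGAAATAGCC") == 9


def test_orf_picks_longest_of_multiple():
    seq = "ATGTAA" + "CCC" + "ATG" + "AAA" * 10 + "TGA"
    assert find_longest_orf(seq) == 3 + 30 + 3


# ---------------------------------------------------------------------------
# Positional classification
# ---------------------------------------------------------------------------

GENE = GeneModel("g1", "chr1", 0, 1000, "+", [(0, 200), (800, 1000)])


def _tx(start, end, strand, tid="t"):
    return TranscriptRecord(tid, "chr1", start, end, strand,
                            [(start, end)], "lncRNA")


def test_class_intronic_either_strand():
    assert classify_lncrna_position(_tx(300, 500, "+"), [GENE]).lnc_class == "intronic"
    assert classify_lncrna_position(_tx(300, 500, "-"), [GENE]).lnc_class == "intronic"


def test_class_antisense():
    out = classify_lncrna_position(_tx(100, 300, "-"), [GENE])
    assert out.lnc_class == "antisense"
    assert out.evidence == "g1"


def test_class_sense():
    assert classify_lncrna_position(_tx(100, 300, "+"), [GENE]).lnc_class == "sense"


def test_class_lincrna():
    out = classify_lncrna_position(_tx(2000, 2300, "+"), [GENE])
    assert out.lnc_class == "lincRNA"
    assert out.evidence == "none"


def test_class_other_chrom_is_lincrna():
    t = TranscriptRecord("t", "chr2", 100, 300, "+", [(100, 300)], "lncRNA")
    assert classify_lncrna_position(t, [GENE]).lnc_class == "lincRNA"


# ---------------------------------------------------------------------------
# Candidate screening
# ---------------------------------------------------------------------------

def test_screen_lncrna_candidates_filters():
    genome = GenomeSequence({"chr1": "C" * 250 + "ATG" + "AAA" * 120 + "TAA"
                             + "C" * 1000})
    short = TranscriptRecord("short", "chr1", 0, 150, "+", [(0, 150)], "lncRNA")
    coding = TranscriptRecord("coding", "chr1", 250, 617, "+", [(250, 617)],
                              "lncRNA")
    mrna = TranscriptRecord("m", "chr1", 700, 1000, "+", [(700, 1000)], "mRNA")
    known = TranscriptRecord("k", "chr1", 700, 1000, "+", [(700, 1000)], "lncRNA")
    good = TranscriptRecord("good", "chr1", 900, 1200, "+", [(900, 1200)],
                            "lncRNA")
    kept = screen_lncrna_candidates([short, coding, mrna, known, good], genome,
                                    known_ids={"k"})
    assert [t.transcript_id for t in kept] == ["good"]


# ---------------------------------------------------------------------------
# TE containment and meta-features
# ---------------------------------------------------------------------------

def test_count_te_contained():
    t = _tx(100, 500, "+")
    tes = [("chr1", 150, 250),   # contained
           ("chr1", 50, 150),    # boundary overlap only
           ("chr1", 600, 700),   # outside
           ("chr2", 150, 250)]   # other chromosome
    assert count_te_contained(t, tes) == 1


def test_meta_feature_priority():
    genes = [GENE]
    nc = [_tx(100, 300, "-", "nc1")]
    tes = [("chr1", 150, 250)]
    assert assign_meta_feature("chr1", 160, 240, genes, nc, tes) == "TE"
    assert assign_meta_feature("chr1", 260, 290, genes, nc, tes) == "ncRNA-locus"
    assert assign_meta_feature("chr1", 400, 600, genes, [], []) == "genic"
    assert assign_meta_feature("chr1", 1500, 1600, genes, [], []) == "gene-proximal"
    assert assign_meta_feature("chr1", 50_000, 50_100, genes, [], []) == "intergenic"
    assert assign_meta_feature("chrUn", 10, 20, genes, [], [],
                               annotated_chroms={"chr1"}) == "no-annotation"


# ---------------------------------------------------------------------------
# Small-RNA QC and windows
# ---------------------------------------------------------------------------

def test_filter_small_rna_reads():
    reads = {"ok": "A" * 21,
             "too_short": "A" * 16,
             "too_long": "A" * 34,
             "n_rich": "A" * 17 + "NNN"}
    kept = filter_small_rna_reads(reads)
    assert set(kept) == {"ok"}


def test_filter_small_rna_allows_one_n_in_20():
    kept = filter_small_rna_reads({"edge": "A" * 19 + "N"})
    assert set(kept) == {"edge"}


def test_window_density_oracle():
    out = window_density([("chr1", 0), ("chr1", 9_999), ("chr1", 10_000)],
                         {"chr1": 25_000}, window=10_000)
    assert out["count"].tolist() == [2, 1, 0]
    assert out["window_end"].tolist() == [10_000, 20_000, 25_000]


def test_window_density_rejects_out_of_range():
    with pytest.raises(ValueError):
        window_density([("chr1", 30_000)], {"chr1": 25_000})
    with pytest.raises(ValueError):
        window_density([("chr2", 0)], {"chr1": 25_000})
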