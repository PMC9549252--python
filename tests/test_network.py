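import numpy as np
import pandas as pd
import pytest

from hybvigor.network import (CeRNATriad, aseg_join, build_cerna_triads,
                              build_de_sets, circ_host_correlation,
                              correlation_modules, de_set_summary,
                              overrepresentation_test, regulator_target_network,
                              triad_components, triads_frame)
from hybvigor.target import HostAssignment, TargetPair


def _de_frame(sig_ids, all_ids):
    return pd.DataFrame({"significant": [i in sig_ids for i in all_ids]},
                        index=pd.Index(all_ids, name="feature_id"))


@pytest.fixture()
def de_sets():
    mrna = ["g1", "g2", "g3"]
    mirna = ["mir1", "mir2"]
    lnc = ["l1", "l2"]
    return build_de_sets({
        "mRNA": {"HM": _de_frame({"g1"}, mrna), "HP": _de_frame({"g2"}, mrna),
                 "MP": _de_frame({"g3"}, mrna)},
        "miRNA": {"HM": _de_frame({"mir1"}, mirna),
                  "HP": _de_frame(set(), mirna)},
        "lncRNA": {"HM": _de_frame({"l1"}, lnc), "HP": _de_frame({"l1"}, lnc)},
    })


def test_build_de_sets_union_and_pp(de_sets):
    assert de_sets.de_hp["mRNA"] == {"g1", "g2"}
    assert de_sets.de_pp["mRNA"] == {"g3"}
    assert de_sets.de_hp["miRNA"] == {"mir1"}
    assert de_sets.de_pp["miRNA"] == set()


def test_de_set_summary(de_sets):
    row = de_set_summary(de_sets).set_index("rna_class").loc["mRNA"]
    assert (row.n_HM, row.n_HP, row.n_HM_and_HP, row.n_DE_HP, row.n_DE_PP) \
        == (1, 1, 0, 2, 1)


def _pair(reg, rclass, tgt, tclass, mode="complementarity", score=0.0):
    return TargetPair(reg, rclass, tgt, tclass, mode, score)


def test_regulator_target_network_requires_both_de(de_sets):
    pairs = [_pair("mir1", "miRNA", "g1", "mRNA"),
             _pair("mir1", "miRNA", "g3", "mRNA"),     # g3 not DE_HP
             _pair("mir2", "miRNA", "g1", "mRNA")]     # mir2 not DE_HP
    edges = regulator_target_network(de_sets, pairs)
    assert len(edges) == 1
    assert edges.loc[0, "regulator"] == "mir1" and edges.loc[0, "target"] == "g1"


def test_cerna_triads_match_triple_loop(de_sets):
    pairs = [_pair("mir1", "miRNA", "g1", "mRNA", score=1.0),
             _pair("mir1", "miRNA", "g2", "mRNA", score=2.0),
             _pair("mir1", "miRNA", "l1", "lncRNA", score=0.5),
             _pair("mir1", "miRNA", "l2", "lncRNA"),   # l2 not DE_HP
             _pair("mir2", "miRNA", "g1", "mRNA"),     # mir2 not DE_HP
             _pair("l1", "lncRNA", "g1", "mRNA", mode="trans")]
    triads = build_cerna_triads(de_sets, pairs)
    got = {(t.cerna_id, t.mirna_id, t.mrna_id) for t in triads}
    assert got == {("l1", "mir1", "g1"), ("l1", "mir1", "g2")}
    comps = triad_components(triads)
    assert comps == [{"mir1", "l1", "g1", "g2"}]
    frame = triads_frame(triads)
    assert set(frame["mrna"]) == {"g1", "g2"}


def test_aseg_join():
    pairs = [_pair("mir1", "miRNA", "g1", "mRNA"),
             _pair("l1", "lncRNA", "g2", "mRNA", mode="cis"),
             _pair("l1", "lncRNA", "g9", "mRNA", mode="trans")]
    hosts = [HostAssignment("chr1:5|50", "g1"), HostAssignment("chr1:7|70", "gX")]
    out = aseg_join({"g1": "maternal", "g2": "paternal"}, pairs, hosts)
    assert len(out) == 3
    assert set(zip(out["bias"], out["mode"])) == \
        {("maternal", "miRNA"), ("paternal", "cis"), ("maternal", "circ-host")}


def test_correlation_modules_planted_blocks():
    rng = np.random.default_rng(9)
    base_a = np.array([1, 5, 2, 8, 3, 9], dtype=float)
    base_b = base_a[::-1].copy()
    genes = {}
    for i in range(6):
        genes[f"a{i}"] = base_a + rng.normal(0, 0.05, 6)
    for i in range(6):
        genes[f"b{i}"] = base_b + rng.normal(0, 0.05, 6)
    cols = [f"s{j}" for j in range(6)]
    deg = pd.DataFrame(genes, index=cols).T
    nc = pd.DataFrame({"nc_pos": base_a, "nc_neg": base_b,
                       "nc_flat": np.zeros(6)}, index=cols).T
    assign, profiles, calls = correlation_modules(nc, deg, k_modules=2)
    mods_a = set(assign[[f"a{i}" for i in range(6)]])
    mods_b = set(assign[[f"b{i}" for i in range(6)]])
    assert len(mods_a) == 1 and len(mods_b) == 1 and mods_a != mods_b
    mod_a = mods_a.pop()
    by = calls.set_index(["ncrna", "module"])
    assert by.loc[("nc_pos", mod_a), "call"] == "positive"
    assert by.loc[("nc_neg", mod_a), "call"] == "negative"
    assert "nc_flat" not in set(calls["ncrna"])   # zero variance: no r


def test_correlation_modules_needs_shared_samples():
    deg = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("wxyz"))
    nc = pd.DataFrame(np.eye(2), index=["n1", "n2"], columns=["w", "q"])
    with pytest.raises(ValueError):
        correlation_modules(nc, deg)


def test_circ_host_correlation_perfect_tracking():
    cols = ["maternal", "hybrid", "paternal"]
    circ = pd.DataFrame({"maternal": [1.0, 3.0], "hybrid": [2.0, 2.0],
                         "paternal": [4.0, 1.0]},
                        index=["c1", "c2"])[cols]
    hosts = pd.DataFrame({"maternal": [10.0, 30.0], "hybrid": [20.0, 20.0],
                          "paternal": [40.0, 10.0]},
                         index=["h1", "h2"])[cols]
    per, pooled = circ_host_correlation(circ, hosts, {"c1": "h1", "c2": "h2",
                                                      "c3": "missing"})
    assert per.set_index("circ_id").loc["c1", "r"] == pytest.approx(1.0)
    assert per.set_index("circ_id").loc["c2", "r"] == pytest.approx(1.0)
    assert pooled == pytest.approx(1.0)


def test_overrepresentation_hand_value():
    # universe 10, term 4, selected 5, hits 4:
    # P(X >= 4) = C(4,4) C(6,1) / C(10,5) = 6/252
    universe = {f"f{i}" for i in range(10)}
    term = {"f0", "f1", "f2", "f3"}
    selected = {"f0", "f1", "f2", "f3", "f9"}
    out = overrepresentation_test(selected, universe, {"t": term})
    assert out.loc[0, "p_value"] == pytest.approx(6 / 252)
    assert out.loc[0, "n_hits"] == 4
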