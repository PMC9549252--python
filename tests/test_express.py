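import numpy as np
import pandas as pd
import pytest

from hybvigor import express
from hybvigor.express import (INHERITANCE_STATES, classify_inheritance_one,
                              classify_presence, fpkm, inheritance_analysis,
                              midparent_value, mpv_test, nb_wald_test,
                              size_factors_median_ratio, srpbm)
from hybvigor.iolib import ConfigError, CountTable


def _table(counts_by_variety, n_rep=3, rng=None):
    """Build a full 3x3 CountTable from per-variety per-feature means."""
    rng = rng or np.random.default_rng(0)
    cols, data, design_rows = [], {}, []
    for v, short in (("maternal", "M"), ("hybrid", "H"), ("paternal", "P")):
        for r in range(1, n_rep + 1):
            name = f"{short}{r}"
            cols.append(name)
            design_rows.append((name, v, r))
            data[name] = rng.poisson(np.asarray(counts_by_variety[v], dtype=float))
    counts = pd.DataFrame(data, index=[f"f{i}" for i in
                                       range(len(counts_by_variety["maternal"]))])
    design = pd.DataFrame(
        [(v, r) for _, v, r in design_rows], columns=["variety", "replicate"],
        index=pd.Index(cols, name="sample_id"))
    return CountTable(counts, design)


# ---------------------------------------------------------------------------
# Normalization oracles
# ---------------------------------------------------------------------------

def test_size_factors_median_ratio_oracle():
    counts = pd.DataFrame({"A": [2, 2], "B": [8, 8]}, index=["f1", "f2"])
    design = pd.DataFrame({"variety": ["maternal", "paternal"],
                           "replicate": [1, 1]},
                          index=pd.Index(["A", "B"], name="sample_id"))
    sf = size_factors_median_ratio(CountTable(counts, design))
    assert sf["A"] == pytest.approx(0.5)
    assert sf["B"] == pytest.approx(2.0)


def test_srpbm_oracle():
    assert srpbm(5, 5e7) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        srpbm(5, 0)


def test_fpkm_oracle():
    counts = pd.DataFrame({"s1": [10]}, index=["t1"])
    out = fpkm(counts, pd.Series({"t1": 2000}), pd.Series({"s1": 1e6}))
    assert out.values.loc["t1", "s1"] == pytest.approx(5.0)
    assert out.unit == "FPKM"


def test_fpkm_rejects_missing_length():
    counts = pd.DataFrame({"s1": [10]}, index=["t1"])
    with pytest.raises(ValueError):
        fpkm(counts, pd.Series({"other": 2000}), pd.Series({"s1": 1e6}))


def test_midparent_value_is_arithmetic_mean():
    means = pd.DataFrame({"maternal": [10.0], "hybrid": [99.0],
                          "paternal": [30.0]}, index=["f"])
    assert midparent_value(means, "f") == pytest.approx(20.0)
    assert midparent_value(means.loc["f"]) == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# Presence patterns
# ---------------------------------------------------------------------------

def test_classify_presence_patterns():
    t = _table({"maternal": [50, 50, 0], "hybrid": [0, 50, 0],
                "paternal": [0, 50, 0]}, rng=np.random.default_rng(1))
    design = t.design
    values = t.counts.astype(float)
    out = classify_presence(values, design)
    assert out.loc["f0", "pattern"] == 1          # maternal only
    assert out.loc["f1", "pattern"] == 7          # all three
    assert out.loc["f2", "pattern"] == "none"


def test_classify_presence_needs_full_design():
    t = _table({"maternal": [5], "hybrid": [5], "paternal": [5]})
    with pytest.raises(ConfigError):
        classify_presence(t.counts.astype(float).iloc[:, :6], t.design)


# ---------------------------------------------------------------------------
# Wald test behaviour
# ---------------------------------------------------------------------------

def test_wald_antisymmetry():
    t = _table({"maternal": [100, 400, 30], "hybrid": [100, 400, 30],
                "paternal": [500, 100, 30]}, rng=np.random.default_rng(7))
    ab = nb_wald_test(t, "maternal", "paternal")
    ba = nb_wald_test(t, "paternal", "maternal")
    assert np.allclose(ab.log2fc.to_numpy(), -ba.log2fc.to_numpy())
    assert np.allclose(ab.p_value.to_numpy(), ba.p_value.to_numpy())


def test_wald_detects_planted_fold_change():
    # a null majority keeps median-of-ratios normalization anchored; the
    # last three features carry a planted 8-fold paternal increase
    t = _table({"maternal": [300] * 10 + [100] * 3,
                "hybrid": [300] * 10 + [100] * 3,
                "paternal": [300] * 10 + [800] * 3},
               rng=np.random.default_rng(11))
    out = nb_wald_test(t, "maternal", "paternal")
    planted = out.iloc[10:]
    assert planted.significant.all()
    assert (planted.log2fc > 1).all()
    assert not out.iloc[:10].significant.any()


def test_wald_rejects_single_replicate():
    t = _table({"maternal": [5], "hybrid": [5], "paternal": [5]})
    dropped = CountTable(t.counts.drop(columns=["P2", "P3"]),
                         t.design.drop(index=["P2", "P3"]))
    with pytest.raises(ConfigError):
        nb_wald_test(dropped, "maternal", "paternal")


def test_mpv_test_hybrid_at_midparent_is_additive():
    t = _table({"maternal": [100] * 4, "hybrid": [250] * 4,
                "paternal": [400] * 4}, rng=np.random.default_rng(5))
    out = mpv_test(t)
    assert not out.nonadditive.any()
    assert np.abs(out.log2_mpv_f1).max() < 1.0


# ---------------------------------------------------------------------------
# 12-state classifier unit cases
# ---------------------------------------------------------------------------

SIG, NS = 1e-6, 0.9


def test_classifier_equivalent():
    assert classify_inheritance_one(0.1, NS, 0.1, NS, 0.0, NS, NS, False) \
        == "equivalent"


def test_classifier_transgressive():
    assert classify_inheritance_one(2.0, SIG, 2.0, SIG, 1.5, SIG, SIG, True) \
        == "transgressive-up-P"
    assert classify_inheritance_one(-2.0, SIG, -2.0, SIG, -1.5, SIG, SIG, True) \
        == "transgressive-down-M"


def test_classifier_eld():
    # parents differ (M high); hybrid indistinguishable from maternal
    assert classify_inheritance_one(-2.0, SIG, 0.0, NS, 2.0, SIG, SIG, True) \
        == "ELD-M-high"
    # parents differ (M high); hybrid indistinguishable from paternal
    assert classify_inheritance_one(-2.0, SIG, -2.0, SIG, 0.0, NS, SIG, True) \
        == "ELD-P-low"
    # parents differ (P high); hybrid at the paternal level
    assert classify_inheritance_one(2.0, SIG, 2.0, SIG, 0.0, NS, SIG, True) \
        == "ELD-P-high"


def test_classifier_additive_and_ambiguous():
    # hybrid closest to the mid-parent value and not non-additive
    assert classify_inheritance_one(2.0, SIG, 1.0, 0.01, -1.0, 0.01, NS, False) \
        == "additive-high"
    assert classify_inheritance_one(-2.0, SIG, -1.0, 0.01, 1.0, 0.01, NS, False) \
        == "additive-low"
    # nearest the MPV by standard-error distance yet still non-additive
    assert classify_inheritance_one(2.0, SIG, 1.0, 1e-9, -1.0, 1e-9, 0.01, True) \
        == "ambiguous"


def test_classifier_outputs_are_valid_states():
    rng = np.random.default_rng(2)
    for _ in range(200):
        lfc = rng.normal(0, 2, 3)
        p = rng.uniform(0, 1, 4)
        state = classify_inheritance_one(lfc[0], p[0], lfc[1], p[1],
                                         lfc[2], p[2], p[3], bool(p[3] < 0.05))
        assert state in INHERITANCE_STATES


def test_inheritance_analysis_recovers_planted_states():
    # ten null features anchor normalization and the dispersion trend
    t = _table({"maternal": [300] * 10 + [100, 100, 600],
                "hybrid": [300] * 10 + [100, 350, 600],
                "paternal": [300] * 10 + [600, 600, 600]},
               rng=np.random.default_rng(13))
    inh = inheritance_analysis(t)["inheritance"]
    assert inh.loc["f10", "state"] == "ELD-M-low"
    assert inh.loc["f11", "state"] == "additive-high"
    assert inh.loc["f12", "state"] == "equivalent"
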