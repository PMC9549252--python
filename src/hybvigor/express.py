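"""Normalization, presence patterns, differential expression, and
mid-parent-value inheritance classification.

The trio design is maternal / hybrid / paternal with three biological
replicates each. Differential expression uses a self-contained
negative-binomial (NB) Wald test: median-of-ratios size factors, a
method-of-moments per-feature dispersion shrunk 50/50 toward a fitted
``a0 + a1/mu`` mean-dispersion trend, and a normal-reference Wald p-value
on the log2 fold change (0.5 pseudo-count on normalized group means).

A feature is called differential between two varieties when
``|log2FC| > 1`` and ``p < 0.05`` (raw p; an optional Benjamini-Hochberg
flag exists but is off by default). Non-additivity is called when
``|log2(MPV / F1)| > 1`` and the MPV Wald p < 0.05, where MPV is the
arithmetic mean of the two parental means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iolib import ConfigError, CountTable, VARIETIES

logger = logging.getLogger(__name__)

LOG2FC_THRESHOLD = 1.0
P_THRESHOLD = 0.05
PSEUDOCOUNT = 0.5
MIN_DISPERSION = 1e-8

#: Canonical order of the twelve expression-inheritance states.
INHERITANCE_STATES = (
    "additive-high", "additive-low",
    "ELD-M-high", "ELD-M-low",
    "ELD-P-high", "ELD-P-low",
    "transgressive-up-M", "transgressive-up-P",
    "transgressive-down-M", "transgressive-down-P",
    "equivalent", "ambiguous",
)

_LN2 = np.log(2.0)


@dataclass
class NormalizedTable:
    """Normalized expression values (features x samples)."""

    values: pd.DataFrame
    unit: str                      # FPKM | SRPBM | RPM | norm-counts
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite normalized values")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class DECall:
    feature_id: str
    group_a: str
    group_b: str
    log2fc: float                  # b over a
    p_value: float
    significant: bool              # |log2fc| > 1 and p < 0.05


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def size_factors_median_ratio(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over all-positive features of
    count / geometric-mean-across-samples. When no feature is positive in
    every sample, falls back to per-million scaling (factors proportional
    to column sums, geometric-mean 1) with a warning.
    """
    counts = table.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.sum() == 0:
        logger.warning("no all-positive feature; falling back to per-million scaling")
        libs = counts.sum(axis=0)
        if (libs <= 0).any():
            raise ConfigError("sample with zero total counts")
        factors = libs / np.exp(np.mean(np.log(libs)))
    else:
        sub = counts[positive]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return pd.Series(factors, index=table.sample_ids, name="size_factor")


def normalized_counts(table: CountTable,
                      size_factors: pd.Series | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = size_factors_median_ratio(table)
    return table.counts / size_factors


def fpkm(counts: pd.DataFrame, lengths_bp: pd.Series,
         library_sizes: pd.Series) -> NormalizedTable:
    """Fragments per kilobase per million mapped fragments.

    ``value = count / (length / 1e3) / (library / 1e6)``.
    """
    lengths = lengths_bp.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive for all samples")
    vals = counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)
    return NormalizedTable(vals, "FPKM")


def srpbm(junction_reads: pd.DataFrame | pd.Series | float,
          mapped_reads: pd.Series | float):
    """Spliced reads per billion mapped reads: ``reads / mapped * 1e9``."""
    if np.ndim(mapped_reads) == 0:
        if mapped_reads <= 0:
            raise ValueError("mapped_reads must be positive")
        out = junction_reads / mapped_reads * 1e9
    else:
        mapped = pd.Series(mapped_reads)
        if (mapped <= 0).any():
            raise ValueError("mapped_reads must be positive")
        if isinstance(junction_reads, pd.DataFrame):
            out = junction_reads.div(mapped, axis=1) * 1e9
        else:
            out = junction_reads / mapped * 1e9
    if isinstance(out, (pd.DataFrame,)):
        return NormalizedTable(out, "SRPBM")
    return out


# ---------------------------------------------------------------------------
# Presence / absence patterns
# ---------------------------------------------------------------------------

#: Map from the expressed-variety subset to the pattern number.
PATTERN_OF_SUBSET = {
    frozenset({"maternal"}): 1,
    frozenset({"hybrid"}): 2,
    frozenset({"paternal"}): 3,
    frozenset({"maternal", "paternal"}): 4,
    frozenset({"hybrid", "paternal"}): 5,
    frozenset({"maternal", "hybrid"}): 6,
    frozenset({"maternal", "hybrid", "paternal"}): 7,
}


def classify_presence(norm: NormalizedTable | pd.DataFrame, design: pd.DataFrame,
                      min_expressed_replicates: int = 2,
                      min_value: float = 0.0) -> pd.DataFrame:
    """Assign each feature a presence pattern 1..7 (or ``none``).

    A feature counts as expressed in a variety when at least
    ``min_expressed_replicates`` of its replicates exceed ``min_value``.
    The seven non-empty subsets of {maternal, hybrid, paternal} map to
    patterns 1-7; features expressed nowhere get pattern ``none``.
    """
    values = norm.values if isinstance(norm, NormalizedTable) else norm
    per = design.loc[list(values.columns), "variety"].value_counts()
    if any(per.get(v, 0) != 3 for v in VARIETIES):
        raise ConfigError("presence classification needs the full 3x3 design")
    expressed = {}
    for v in VARIETIES:
        cols = [s for s in values.columns if design.loc[s, "variety"] == v]
        expressed[v] = (values[cols] > min_value).sum(axis=1) >= min_expressed_replicates
    rows = []
    for fid in values.index:
        subset = frozenset(v for v in VARIETIES if expressed[v][fid])
        pattern = PATTERN_OF_SUBSET.get(subset, "none") if subset else "none"
        rows.append((fid, pattern, ",".join(sorted(subset))))
    return pd.DataFrame(rows, columns=["feature_id", "pattern", "expressed_in"]
                        ).set_index("feature_id")


# ---------------------------------------------------------------------------
# NB dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(table: CountTable,
                         size_factors: pd.Series | None = None) -> pd.Series:
    """Per-feature NB dispersion, method-of-moments shrunk toward a trend.

    For each feature the within-variety excess variance gives a moment
    estimate ``alpha = (var - mean) / mean^2`` (pooled over varieties); a
    mean-dispersion trend ``a0 + a1/mu`` is fit across features and the
    final dispersion is the 50/50 average of the moment estimate and the
    trend value, floored at 1e-8.
    """
    if size_factors is None:
        size_factors = size_factors_median_ratio(table)
    q = normalized_counts(table, size_factors)
    mom = np.zeros(len(q))
    weights = np.zeros(len(q))
    grand = np.zeros(len(q))
    n_groups = 0
    for v in VARIETIES:
        cols = table.samples_of(v)
        if len(cols) < 2:
            continue
        sub = q[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        df = len(cols) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (var - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        mom += df * a
        weights += df
        grand += m
        n_groups += 1
    if n_groups == 0:
        raise ConfigError("dispersion estimation needs >=2 replicates per group")
    mom = np.where(weights > 0, mom / np.maximum(weights, 1), 0.0)
    mu = grand / n_groups
    trend = _fit_dispersion_trend(mu, mom)
    alpha = 0.5 * np.maximum(mom, MIN_DISPERSION) + 0.5 * trend
    alpha = np.maximum(alpha, MIN_DISPERSION)
    return pd.Series(alpha, index=table.feature_ids, name="dispersion")


def _fit_dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Least-squares fit of ``alpha = a0 + a1/mu`` on informative features."""
    ok = (mu > 0) & (alpha_mom > 0) & np.isfinite(alpha_mom)
    fallback = float(np.median(alpha_mom[ok])) if ok.sum() else 0.1
    if ok.sum() < 10:
        return np.full_like(mu, max(fallback, MIN_DISPERSION))
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(x, alpha_mom[ok], rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    if a0 == 0.0 and a1 == 0.0:
        return np.full_like(mu, max(fallback, MIN_DISPERSION))
    with np.errstate(divide="ignore"):
        tr = a0 + a1 / np.maximum(mu, 1e-12)
    return np.maximum(tr, MIN_DISPERSION)


# ---------------------------------------------------------------------------
# Wald machinery
# ---------------------------------------------------------------------------

def _group_stats(q: pd.DataFrame, cols: list[str], size_factors: pd.Series,
                 alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group mean of normalized counts and model-based variance of that mean.

    Var(K_j / s_j) = mu / s_j + alpha * mu^2 under NB(mu * s_j, alpha).
    """
    sub = q[cols].to_numpy(dtype=float)
    mu = sub.mean(axis=1)
    inv_s = np.array([1.0 / size_factors[c] for c in cols])
    n = len(cols)
    var_mean = (np.outer(mu, inv_s).sum(axis=1) + n * alpha * mu ** 2) / n ** 2
    return mu, var_mean


def _wald(mu_a, var_a, mu_b, var_b):
    """Two-sided normal-reference Wald test on log2(mu_b / mu_a)."""
    a = mu_a + PSEUDOCOUNT
    b = mu_b + PSEUDOCOUNT
    lfc = np.log2(b / a)
    se = np.sqrt(var_a / (a * _LN2) ** 2 + var_b / (b * _LN2) ** 2)
    both_zero = (mu_a == 0) & (mu_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.inf * np.sign(lfc))
        z = np.where(lfc == 0, 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    lfc = np.where(both_zero, 0.0, lfc)
    p = np.where(both_zero, 1.0, np.clip(p, 0.0, 1.0))
    return lfc, p


def nb_wald_test(table: CountTable, variety_a: str, variety_b: str,
                 size_factors: pd.Series | None = None,
                 dispersions: pd.Series | None = None,
                 bh_adjust: bool = False) -> pd.DataFrame:
    """NB Wald differential-expression test of ``variety_b`` over ``variety_a``.

    Returns a frame indexed by feature with columns ``log2fc`` (b over a),
    ``p_value``, ``significant`` (|log2fc| > 1 and p < 0.05) and
    ``dir_significant`` (p < 0.05 regardless of fold change).
    """
    for v in (variety_a, variety_b):
        if len(table.samples_of(v)) < 2:
            raise ConfigError(f"need >=2 replicates in group {v!r}")
    if size_factors is None:
        size_factors = size_factors_median_ratio(table)
    if dispersions is None:
        dispersions = estimate_dispersions(table, size_factors)
    alpha = dispersions.reindex(table.feature_ids).to_numpy(dtype=float)
    q = normalized_counts(table, size_factors)
    mu_a, var_a = _group_stats(q, table.samples_of(variety_a), size_factors, alpha)
    mu_b, var_b = _group_stats(q, table.samples_of(variety_b), size_factors, alpha)
    lfc, p = _wald(mu_a, var_a, mu_b, var_b)
    if bh_adjust:
        p = _bh_adjust(p)
    out = pd.DataFrame({
        "group_a": variety_a,
        "group_b": variety_b,
        "log2fc": lfc,
        "p_value": p,
        "significant": (np.abs(lfc) > LOG2FC_THRESHOLD) & (p < P_THRESHOLD),
        "dir_significant": p < P_THRESHOLD,
    }, index=pd.Index(table.feature_ids, name="feature_id"))
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def de_call(table: CountTable, feature_id: str, variety_a: str,
            variety_b: str, **kwargs) -> DECall:
    """Single-feature convenience wrapper around :func:`nb_wald_test`."""
    row = nb_wald_test(table, variety_a, variety_b, **kwargs).loc[feature_id]
    return DECall(feature_id, variety_a, variety_b,
                  float(row.log2fc), float(row.p_value), bool(row.significant))


# ---------------------------------------------------------------------------
# Mid-parent value and non-additivity
# ---------------------------------------------------------------------------

def midparent_value(norm_means: pd.DataFrame | pd.Series,
                    feature: str | None = None):
    """Arithmetic mid-parent value from per-variety normalized means.

    Accepts a frame with ``maternal`` and ``paternal`` columns (per-feature
    MPV) or a two-entry series for a single feature.
    """
    if isinstance(norm_means, pd.Series):
        return 0.5 * (norm_means["maternal"] + norm_means["paternal"])
    mpv = 0.5 * (norm_means["maternal"] + norm_means["paternal"])
    return mpv if feature is None else float(mpv[feature])


def variety_means(table: CountTable,
                  size_factors: pd.Series | None = None) -> pd.DataFrame:
    q = normalized_counts(table, size_factors)
    return pd.DataFrame({v: q[table.samples_of(v)].mean(axis=1) for v in VARIETIES})


def mpv_test(table: CountTable,
             size_factors: pd.Series | None = None,
             dispersions: pd.Series | None = None) -> pd.DataFrame:
    """Wald test of the hybrid against the mid-parent value.

    The reference group pools the six parental replicates with each
    parent's normalized counts rescaled to the MPV mean, so the reference
    carries within-parent noise but not the parental gap. The returned
    ``log2_mpv_f1`` is log2(MPV / F1): positive when the hybrid sits below
    the mid-parent value. ``nonadditive`` applies the
    |log2(MPV/F1)| > 1 and p < 0.05 rule.
    """
    if not table.is_full_design():
        raise ConfigError("MPV test needs the full 3x3 design")
    if size_factors is None:
        size_factors = size_factors_median_ratio(table)
    if dispersions is None:
        dispersions = estimate_dispersions(table, size_factors)
    alpha = dispersions.reindex(table.feature_ids).to_numpy(dtype=float)
    q = normalized_counts(table, size_factors)
    cols_m = table.samples_of("maternal")
    cols_p = table.samples_of("paternal")
    cols_h = table.samples_of("hybrid")
    mean_m = q[cols_m].mean(axis=1).to_numpy()
    mean_p = q[cols_p].mean(axis=1).to_numpy()
    mpv = 0.5 * (mean_m + mean_p)

    mu_h, var_h = _group_stats(q, cols_h, size_factors, alpha)
    # model-based variance of the pooled (rescaled) parental mean at mu = MPV
    inv_s = np.array([1.0 / size_factors[c] for c in cols_m + cols_p])
    n_ref = len(inv_s)
    var_ref = (np.outer(mpv, inv_s).sum(axis=1) + n_ref * alpha * mpv ** 2) / n_ref ** 2

    lfc, p = _wald(mu_h, var_h, mpv, var_ref)   # b over a = MPV over F1
    out = pd.DataFrame({
        "mpv": mpv,
        "log2_mpv_f1": lfc,
        "p_value": p,
        "nonadditive": (np.abs(lfc) > LOG2FC_THRESHOLD) & (p < P_THRESHOLD),
    }, index=pd.Index(table.feature_ids, name="feature_id"))
    return out


# ---------------------------------------------------------------------------
# 12-state inheritance classification
# ---------------------------------------------------------------------------

def classify_inheritance_one(lfc_mp: float, p_mp: float,
                             lfc_hm: float, p_hm: float,
                             lfc_hp: float, p_hp: float,
                             p_mpv: float, nonadditive: bool) -> str:
    """Map one feature's test outcomes to one of the twelve states.

    Inputs are the Wald results of (paternal over maternal), (hybrid over
    maternal) and (hybrid over paternal), the MPV-vs-F1 test p-value and
    the MPV non-additivity flag.

    Decision order: ``equivalent`` when no pairwise comparison passes the
    full DE rule (|log2FC| > 1 and p < 0.05); ``transgressive`` when the
    hybrid is full-DE beyond both parents in the same direction; when the
    parents are full-DE different, the hybrid is assigned to the nearest
    reference — the maternal level (ELD-M), the mid-parent value
    (additive) or the paternal level (ELD-P) — where distance is the Wald
    |z| of the corresponding test, i.e. how many standard errors the
    hybrid sits from each reference. A nearest-reference rule is used
    rather than a significance test on the hybrid-vs-parent legs because
    an intermediate hybrid is always within 2-fold of the high parent
    under an arithmetic MPV, so a test-based additive row has no power at
    the fold-change threshold; measuring distance in standard errors
    weights each reference by its precision (the MPV pools six parental
    replicates). A feature nearest the MPV that still fails the
    non-additivity rule is reported ``ambiguous``. High/low suffixes
    encode which parent is higher (-high: the hybrid shares or tracks the
    higher expression level).
    """
    def fullsig(lfc, p):
        return abs(lfc) > LOG2FC_THRESHOLD and p < P_THRESHOLD

    if not (fullsig(lfc_mp, p_mp) or fullsig(lfc_hm, p_hm) or fullsig(lfc_hp, p_hp)):
        return "equivalent"
    parent_high = "P" if lfc_mp > 0 else "M"
    if fullsig(lfc_hm, p_hm) and fullsig(lfc_hp, p_hp):
        if lfc_hm > 0 and lfc_hp > 0:
            return f"transgressive-up-{parent_high}"
        if lfc_hm < 0 and lfc_hp < 0:
            return f"transgressive-down-{parent_high}"
    if fullsig(lfc_mp, p_mp):
        # Wald |z| recovered from the two-sided p-value; a larger p means
        # the hybrid is fewer standard errors from that reference
        distances = tuple(float(stats.norm.isf(min(max(p, 0.0), 1.0) / 2))
                          for p in (p_hm, p_mpv, p_hp))
        nearest = min(range(3), key=lambda i: distances[i])
        if nearest == 0:       # hybrid at the maternal level
            return "ELD-M-high" if parent_high == "M" else "ELD-M-low"
        if nearest == 2:       # hybrid at the paternal level
            return "ELD-P-high" if parent_high == "P" else "ELD-P-low"
        if nonadditive:        # at MPV by distance yet significantly off it
            return "ambiguous"
        return "additive-high" if parent_high == "P" else "additive-low"
    return "ambiguous"


def classify_inheritance(de_mp: pd.DataFrame, de_hm: pd.DataFrame,
                         de_hp: pd.DataFrame, mpv: pd.DataFrame) -> pd.DataFrame:
    """Per-feature 12-state inheritance calls from the three pairwise DE
    frames (maternal->paternal, maternal->hybrid, paternal->hybrid) and the
    MPV test frame. Returns a frame with ``state``, ``mpv``,
    ``log2_mpv_f1``, ``mpv_p`` and ``nonadditive``.
    """
    idx = de_mp.index
    if not (idx.equals(de_hm.index) and idx.equals(de_hp.index)
            and idx.equals(mpv.index)):
        raise ConfigError("inheritance classification needs aligned feature indexes")
    states = [
        classify_inheritance_one(
            de_mp.log2fc.iloc[i], de_mp.p_value.iloc[i],
            de_hm.log2fc.iloc[i], de_hm.p_value.iloc[i],
            de_hp.log2fc.iloc[i], de_hp.p_value.iloc[i],
            float(mpv.p_value.iloc[i]), bool(mpv.nonadditive.iloc[i]))
        for i in range(len(idx))
    ]
    return pd.DataFrame({
        "state": states,
        "mpv": mpv["mpv"],
        "log2_mpv_f1": mpv["log2_mpv_f1"],
        "mpv_p": mpv["p_value"],
        "nonadditive": mpv["nonadditive"],
    }, index=idx)


def inheritance_analysis(table: CountTable, bh_adjust: bool = False) -> dict:
    """Run the full inheritance workflow on one count table.

    Returns a dict with the three pairwise DE frames (keys ``MP``, ``HM``,
    ``HP``), the ``mpv`` frame and the combined ``inheritance`` frame.
    """
    sf = size_factors_median_ratio(table)
    disp = estimate_dispersions(table, sf)
    de_mp = nb_wald_test(table, "maternal", "paternal", sf, disp, bh_adjust)
    de_hm = nb_wald_test(table, "maternal", "hybrid", sf, disp, bh_adjust)
    de_hp = nb_wald_test(table, "paternal", "hybrid", sf, disp, bh_adjust)
    mpv = mpv_test(table, sf, disp)
    inh = classify_inheritance(de_mp, de_hm, de_hp, mpv)
    return {"size_factors": sf, "dispersions": disp, "MP": de_mp,
            "HM": de_hm, "HP": de_hp, "mpv": mpv, "inheritance": inh}
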