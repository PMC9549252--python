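"""Heterosis-related regulatory network assembly.

Builds the differential-expression sets (hybrid-vs-parent DE_HP and
parent-vs-parent DE_PP), filters regulator-target edges to DE features,
assembles ceRNA triads (miRNA targeting both a DE ncRNA sponge and a DE
mRNA), joins allele-specific-expression genes (ASEGs) onto the edge
lists, clusters DE genes into co-expression modules as a correlation
target for non-additive ncRNAs (+-0.8 rule), and correlates circRNA
abundance with host-gene expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .target import HostAssignment, TargetPair

R_THRESHOLD = 0.8
MIN_MODULE_R = 0.3


@dataclass
class DESets:
    """Per-RNA-class DE feature sets."""

    de_hp: dict[str, set[str]] = field(default_factory=dict)
    de_pp: dict[str, set[str]] = field(default_factory=dict)
    pair_sets: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def in_de_hp(self, rna_class: str, feature: str) -> bool:
        return feature in self.de_hp.get(rna_class, set())


@dataclass
class CeRNATriad:
    cerna_id: str
    cerna_class: str                   # lncRNA | circRNA
    mirna_id: str
    mrna_id: str
    cerna_score: float
    mrna_score: float


# ---------------------------------------------------------------------------
# DE sets
# ---------------------------------------------------------------------------

def build_de_sets(decalls: Mapping[str, Mapping[str, pd.DataFrame]]) -> DESets:
    """Assemble DE_HP / DE_PP sets per RNA class.

    ``decalls[rna_class]`` maps pair keys ``MP`` (maternal vs paternal),
    ``HM`` (hybrid vs maternal) and ``HP`` (hybrid vs paternal) to DE
    frames with a boolean ``significant`` column. DE_HP is the union of
    HM- and HP-significant features; DE_PP is the MP-significant set.
    """
    out = DESets()
    for rna_class, pairs in decalls.items():
        sig = {key: set(df.index[df["significant"]]) for key, df in pairs.items()}
        out.pair_sets[rna_class] = sig
        out.de_hp[rna_class] = sig.get("HM", set()) | sig.get("HP", set())
        out.de_pp[rna_class] = sig.get("MP", set())
    return out


def de_set_summary(de_sets: DESets) -> pd.DataFrame:
    rows = []
    for rna_class in de_sets.de_hp:
        sig = de_sets.pair_sets[rna_class]
        rows.append((rna_class,
                     len(sig.get("HM", set())), len(sig.get("HP", set())),
                     len(sig.get("HM", set()) & sig.get("HP", set())),
                     len(de_sets.de_hp[rna_class]), len(de_sets.de_pp[rna_class])))
    return pd.DataFrame(rows, columns=["rna_class", "n_HM", "n_HP",
                                       "n_HM_and_HP", "n_DE_HP", "n_DE_PP"])


# ---------------------------------------------------------------------------
# DE-constrained edges and ceRNA triads
# ---------------------------------------------------------------------------

def regulator_target_network(de_sets: DESets, pairs: Sequence[TargetPair],
                             modes: set[str] | None = None,
                             inheritance: pd.DataFrame | None = None,
                             ) -> pd.DataFrame:
    """Regulator-target edges with both endpoints hybrid-vs-parent DE.

    Optionally annotates each endpoint with its inheritance state so
    same-direction and opposite-direction sub-networks are queryable.
    """
    rows = []
    for p in pairs:
        if modes is not None and p.mode not in modes:
            continue
        if not de_sets.in_de_hp(p.regulator_class, p.regulator_id):
            continue
        if not de_sets.in_de_hp(p.target_class, p.target_id):
            continue
        rows.append((p.regulator_id, p.regulator_class, p.target_id,
                     p.target_class, p.mode, p.score))
    edges = pd.DataFrame(rows, columns=["regulator", "regulator_class",
                                        "target", "target_class", "mode", "score"])
    if inheritance is not None and len(edges):
        state = inheritance["state"]
        edges["regulator_state"] = edges["regulator"].map(state).fillna("NA")
        edges["target_state"] = edges["target"].map(state).fillna("NA")
    return edges


def build_cerna_triads(de_sets: DESets,
                       pairs: Sequence[TargetPair]) -> list[CeRNATriad]:
    """(ceRNA, miRNA, mRNA) triples where the miRNA targets both partners
    and all three members are in their DE_HP sets."""
    mrna_edges: dict[str, list[tuple[str, float]]] = {}
    cerna_edges: dict[str, list[tuple[str, str, float]]] = {}
    for p in pairs:
        if p.regulator_class != "miRNA" or p.mode != "complementarity":
            continue
        if not de_sets.in_de_hp("miRNA", p.regulator_id):
            continue
        if p.target_class == "mRNA" and de_sets.in_de_hp("mRNA", p.target_id):
            mrna_edges.setdefault(p.regulator_id, []).append((p.target_id, p.score))
        elif p.target_class in ("lncRNA", "circRNA") and \
                de_sets.in_de_hp(p.target_class, p.target_id):
            cerna_edges.setdefault(p.regulator_id, []).append(
                (p.target_id, p.target_class, p.score))
    triads = []
    for mirna, sponges in cerna_edges.items():
        for cid, cclass, cscore in sponges:
            for gid, gscore in mrna_edges.get(mirna, ()):
                triads.append(CeRNATriad(cid, cclass, mirna, gid, cscore, gscore))
    triads.sort(key=lambda t: (t.mirna_id, t.cerna_id, t.mrna_id))
    return triads


def triad_components(triads: Sequence[CeRNATriad]) -> list[set[str]]:
    """Connected network groups over the union of triad edges."""
    g = nx.Graph()
    for t in triads:
        g.add_edge(t.mirna_id, t.cerna_id)
        g.add_edge(t.mirna_id, t.mrna_id)
    return [set(c) for c in nx.connected_components(g)]


def triads_frame(triads: Sequence[CeRNATriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.cerna_id, t.cerna_class, t.mirna_id, t.mrna_id,
          t.cerna_score, t.mrna_score) for t in triads],
        columns=["cerna", "cerna_class", "mirna", "mrna",
                 "cerna_score", "mrna_score"])


# ---------------------------------------------------------------------------
# ASEG joins
# ---------------------------------------------------------------------------

def aseg_join(aseg_table: Mapping[str, str],
              pairs: Sequence[TargetPair] = (),
              hosts: Sequence[HostAssignment] = ()) -> pd.DataFrame:
    """Edges whose gene endpoint is an allele-specific expression gene.

    ``aseg_table`` maps gene id -> parental bias ("maternal"/"paternal").
    Returns one row per (bias, mode) edge, including circRNA-host edges.
    """
    rows = []
    for p in pairs:
        bias = aseg_table.get(p.target_id)
        if bias is None:
            continue
        mode = "miRNA" if p.regulator_class == "miRNA" else p.mode
        rows.append((bias, mode, p.regulator_id, p.regulator_class, p.target_id))
    for h in hosts:
        bias = aseg_table.get(h.host_gene_id)
        if bias is not None:
            rows.append((bias, "circ-host", h.circ_id, "circRNA", h.host_gene_id))
    return pd.DataFrame(rows, columns=["bias", "mode", "regulator",
                                       "regulator_class", "aseg"])


# ---------------------------------------------------------------------------
# Correlation modules (co-expression stand-in for WGCNA's role)
# ---------------------------------------------------------------------------

def correlation_modules(ncrna_expr: pd.DataFrame, deg_expr: pd.DataFrame,
                        r_threshold: float = R_THRESHOLD,
                        k_modules: int = 4,
                        min_module_r: float = MIN_MODULE_R,
                        ) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Cluster DE genes into co-expression modules and correlate
    non-additive ncRNAs against the module mean profiles.

    Expression frames are features x samples on a log2(x+1)-like scale
    with matching sample columns. Genes are clustered by average linkage
    on (1 - Pearson) distance into ``k_modules``; a gene whose correlation
    to its own module profile falls below ``min_module_r`` in absolute
    value moves to the "unassigned" bucket. Each ncRNA is called
    positively (r > threshold) or negatively (r < -threshold) associated
    per module.

    Returns (module assignment per gene, module mean profiles,
    ncRNA x module association frame with columns module/r/call).
    """
    common = [s for s in deg_expr.columns if s in set(ncrna_expr.columns)]
    if len(common) < 3:
        raise ValueError("need >=3 shared samples")
    deg = deg_expr[common]
    nc = ncrna_expr[common]
    var = deg.std(axis=1, ddof=0)
    usable = deg.loc[var > 0]
    dropped = deg.index.difference(usable.index)
    if len(usable) < k_modules:
        raise ValueError("fewer variable genes than requested modules")
    corr = np.corrcoef(usable.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=k_modules, criterion="maxclust")
    assign = pd.Series([f"module{l}" for l in labels], index=usable.index)

    profiles = pd.DataFrame({m: usable.loc[assign.index[assign == m]].mean(axis=0)
                             for m in sorted(assign.unique())}).T
    # move weakly-attached genes to the unassigned bucket
    for gid in list(assign.index):
        r = _pearson(usable.loc[gid].to_numpy(),
                     profiles.loc[assign[gid]].to_numpy())
        if r is None or abs(r) < min_module_r:
            assign[gid] = "unassigned"
    for gid in dropped:
        assign[gid] = "unassigned"
    assign = assign.reindex(deg.index, fill_value="unassigned")

    rows = []
    for nid in nc.index:
        x = nc.loc[nid].to_numpy()
        for m in profiles.index:
            r = _pearson(x, profiles.loc[m].to_numpy())
            if r is None:
                continue
            call = ("positive" if r > r_threshold
                    else "negative" if r < -r_threshold else "none")
            rows.append((nid, m, r, call))
    calls = pd.DataFrame(rows, columns=["ncrna", "module", "r", "call"])
    return assign, profiles, calls


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# circRNA-host correlation
# ---------------------------------------------------------------------------

def circ_host_correlation(circ_srpbm: pd.DataFrame, host_fpkm: pd.DataFrame,
                          circ_to_host: Mapping[str, str],
                          ) -> tuple[pd.DataFrame, float | None]:
    """Pearson correlation between circRNA abundance and host expression
    over matched columns (variety-level means).

    Returns (per-circRNA frame with r, pooled r over all paired points).
    Pairs with a zero-variance vector are excluded.
    """
    rows = []
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    for cid, hid in circ_to_host.items():
        if cid not in circ_srpbm.index or hid not in host_fpkm.index:
            continue
        x = circ_srpbm.loc[cid].to_numpy(dtype=float)
        y = host_fpkm.loc[hid, circ_srpbm.columns].to_numpy(dtype=float)
        pooled_x.extend(x)
        pooled_y.extend(y)
        r = _pearson(x, y)
        if r is not None:
            rows.append((cid, hid, r))
    per = pd.DataFrame(rows, columns=["circ_id", "host_gene", "r"])
    pooled = _pearson(np.asarray(pooled_x), np.asarray(pooled_y)) \
        if len(pooled_x) >= 3 else None
    return per, pooled


# ---------------------------------------------------------------------------
# Over-representation test and export
# ---------------------------------------------------------------------------

def overrepresentation_test(selected: set[str], universe: set[str],
                            term_map: Mapping[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of user-supplied terms.

    ``term_map`` maps term -> feature set. One-sided p per term.
    """
    n_universe = len(universe)
    n_selected = len(selected & universe)
    rows = []
    for term, members in term_map.items():
        members = members & universe
        k = len(members & selected)
        p = stats.hypergeom.sf(k - 1, n_universe, len(members), n_selected)
        rows.append((term, k, len(members), float(p)))
    return pd.DataFrame(rows, columns=["term", "n_hits", "n_term", "p_value"]
                        ).sort_values("p_value").reset_index(drop=True)


def export_graphml(edges: pd.DataFrame, path: str,
                   source_col: str = "regulator", target_col: str = "target") -> None:
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row[source_col], row[target_col],
                   **{c: row[c] for c in edges.columns
                      if c not in (source_col, target_col)
                      and not isinstance(row[c], (list, dict, set))})
    nx.write_graphml(g, path)
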