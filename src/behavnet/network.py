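"""Directed behavioral influence networks and centrality comparison.

Nodes are variables; a directed edge input -> target is kept when the
median influence is positive (optionally above a magnitude threshold and/or
gated on sign stability) and weighted by its magnitude.  Five centrality
metrics characterize each node's systemic role — normalized in-/out-degree,
eigenvector centrality (prestige convention: a node is central when
influential nodes point at it), betweenness on strongest-influence shortest
paths (distance = 1 / weight), and PageRank — and healthy -> disease-state
deltas plus hazard-ratio direction feed a three-way role classification:

* dual-priority target: significant risk factor (HR > 1) that also gains
  eigenvector or betweenness centrality in the disease state;
* structural stabilizer: significant protective factor (HR < 1) that loses
  eigenvector centrality;
* emergent driver: risk-direction variable whose outgoing reach or bridging
  grows while its eigenvector centrality does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .influence import InfluenceMatrix, TIERS

__all__ = [
    "EdgeRule",
    "RoleRules",
    "build_network",
    "centrality_profile",
    "centrality_deltas",
    "vector_shift",
    "classify_roles",
]

METRICS = ("in_degree", "out_degree", "eigenvector", "betweenness", "pagerank")

_TIER_ORDER = {t: i for i, t in enumerate(TIERS)}  # lower index = more stable


@dataclass
class EdgeRule:
    """Edge inclusion policy: positive medians above a threshold, optionally
    gated on sign-stability tier (``'moderately_stable'`` keeps highly and
    moderately stable edges)."""

    threshold: float = 0.0
    min_tier: str | None = None


def build_network(matrix: InfluenceMatrix,
                  edge_rule: EdgeRule | None = None) -> nx.DiGraph:
    """Directed weighted graph from an influence matrix.

    Keeps edges whose median influence exceeds ``edge_rule.threshold``
    (strictly positive by default); edge weight is the median magnitude.
    An empty graph after thresholding is returned with a warning.
    """
    rule = edge_rule or EdgeRule()
    g = nx.DiGraph()
    g.add_nodes_from(matrix.variables)
    for (src, dst), est in matrix.estimates.items():
        if est.median_weight <= rule.threshold:
            continue
        if rule.min_tier is not None and (
                _TIER_ORDER[est.tier] > _TIER_ORDER[rule.min_tier]):
            continue
        g.add_edge(src, dst, weight=float(est.median_weight),
                   distance=1.0 / float(est.median_weight), tier=est.tier)
    if g.number_of_edges() == 0:
        warnings.warn("no edges survive the edge rule; graph is empty")
    return g


def centrality_profile(graph: nx.DiGraph, cohort_label: str = "",
                       weighted_paths: bool = True) -> pd.DataFrame:
    """Five centrality metrics per node.

    Degrees are edge counts normalized by (n - 1); eigenvector centrality is
    computed on in-edges and scaled to max 1; betweenness uses reciprocal
    weights as distances (so stronger influence = shorter path) unless
    ``weighted_paths=False``; PageRank uses damping 0.85 and sums to 1.
    Eigenvector non-convergence falls back to the undirected variant with a
    warning.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    denom = n - 1
    in_deg = {v: d / denom for v, d in graph.in_degree()}
    out_deg = {v: d / denom for v, d in graph.out_degree()}
    try:
        eig = nx.eigenvector_centrality(graph, max_iter=2000, weight="weight")
    except (nx.PowerIterationFailedConvergence, nx.NetworkXException):
        warnings.warn("eigenvector centrality did not converge on the "
                      "directed graph; falling back to undirected")
        und = graph.to_undirected()
        try:
            eig = nx.eigenvector_centrality(und, max_iter=2000, weight="weight")
        except nx.NetworkXException:
            eig = {v: 0.0 for v in graph}
    mx = max(eig.values()) if eig and max(eig.values()) > 0 else 1.0
    eig = {v: x / mx for v, x in eig.items()}
    btw = nx.betweenness_centrality(
        graph, normalized=True,
        weight="distance" if weighted_paths else None)
    if graph.number_of_edges() > 0:
        pr = nx.pagerank(graph, alpha=0.85, weight="weight")
    else:
        pr = {v: 1.0 / n for v in graph}
    rows = [{"node": v, "in_degree": in_deg[v], "out_degree": out_deg[v],
             "eigenvector": eig[v], "betweenness": btw[v], "pagerank": pr[v],
             "cohort": cohort_label} for v in graph.nodes]
    return pd.DataFrame(rows).set_index("node")


def centrality_deltas(healthy: pd.DataFrame, t2dm: pd.DataFrame,
                      ndigits: int = 2) -> pd.DataFrame:
    """Per-node, per-metric disease-state minus healthy shifts (2 dp)."""
    if set(healthy.index) != set(t2dm.index):
        raise ValueError("profiles cover different node sets")
    t2dm = t2dm.loc[healthy.index]
    out = {}
    for m in METRICS:
        out[f"{m}_healthy"] = healthy[m]
        out[f"{m}_t2dm"] = t2dm[m]
        out[f"delta_{m}"] = (t2dm[m] - healthy[m]).round(ndigits)
    return pd.DataFrame(out)


def vector_shift(healthy: pd.DataFrame, t2dm: pd.DataFrame,
                 axes: tuple = ("eigenvector", "betweenness"),
                 theme_map: dict | None = None) -> pd.DataFrame:
    """Per-node arrows from healthy to disease-state positions in metric space.

    ``axes`` names two centrality metrics; the arrow runs from the healthy
    (x, y) to the disease-state (x, y), with Euclidean magnitude and an
    optional behavioral-domain theme per node (dietary / psychological /
    lifestyle / sleep) for plotting.
    """
    for a in axes:
        if a not in METRICS:
            raise ValueError(f"unknown metric {a!r}")
    if set(healthy.index) != set(t2dm.index):
        raise ValueError("profiles cover different node sets")
    theme_map = theme_map or {}
    x, y = axes
    rows = []
    for v in healthy.index:
        bx, by = float(healthy.loc[v, x]), float(healthy.loc[v, y])
        tx, ty = float(t2dm.loc[v, x]), float(t2dm.loc[v, y])
        rows.append({
            "node": v, "base_x": bx, "base_y": by, "tip_x": tx, "tip_y": ty,
            "magnitude": float(np.hypot(tx - bx, ty - by)),
            "theme": theme_map.get(v, "other"),
        })
    return pd.DataFrame(rows).set_index("node")


# ----------------------------------------------------------------------
@dataclass
class RoleRules:
    """Thresholds for combining hazard ratios with centrality shifts."""

    hr_alpha: float = 0.05
    eig_gain: float = 0.0
    eig_loss: float = 0.0
    out_gain: float = 0.0
    btw_gain: float = 0.0


def classify_roles(delta_table: pd.DataFrame, hazard_table: pd.DataFrame,
                   node_map: dict | None = None,
                   rules: RoleRules | None = None) -> pd.DataFrame:
    """Assign each network node an intervention-relevance category.

    ``hazard_table`` is the printed-style table (term, hr, p); ``node_map``
    maps hazard terms to network nodes (categorical terms to their parent
    node).  Classification is a pure function of the inputs:

    * ``dual_priority``: HR > 1, p < alpha, and eigenvector or betweenness
      centrality rises in the disease state;
    * ``structural_stabilizer``: HR < 1, p < alpha, eigenvector falls;
    * ``emergent_driver``: HR > 1 and out-degree or betweenness rises while
      eigenvector does not;
    * otherwise ``other``.  Unmapped nodes classify as ``other`` with a
      warning.
    """
    rules = rules or RoleRules()
    node_map = node_map or {t: t for t in hazard_table["term"]}
    hr_by_node = {}
    for _, row in hazard_table.iterrows():
        node = node_map.get(row["term"])
        if node is None:
            continue
        # for multi-term variables keep the most significant term
        if node not in hr_by_node or row["p"] < hr_by_node[node]["p"]:
            hr_by_node[node] = {"hr": float(row["hr"]), "p": float(row["p"])}
    rows = []
    for node in delta_table.index:
        d_eig = float(delta_table.loc[node, "delta_eigenvector"])
        d_in = float(delta_table.loc[node, "delta_in_degree"])
        d_out = float(delta_table.loc[node, "delta_out_degree"])
        d_btw = float(delta_table.loc[node, "delta_betweenness"])
        ev = hr_by_node.get(node)
        if ev is None:
            warnings.warn(f"node {node} has no mapped hazard term; "
                          "classified as other")
            cat, hr, p = "other", np.nan, np.nan
        else:
            hr, p = ev["hr"], ev["p"]
            sig = p < rules.hr_alpha
            if (hr > 1.0 and sig
                    and (d_eig > rules.eig_gain or d_btw > rules.btw_gain)):
                cat = "dual_priority"
            elif hr < 1.0 and sig and d_eig < rules.eig_loss:
                cat = "structural_stabilizer"
            elif (hr > 1.0 and d_eig <= rules.eig_gain
                    and (d_out > rules.out_gain or d_btw > rules.btw_gain)):
                cat = "emergent_driver"
            else:
                cat = "other"
        rows.append({"node": node, "category": cat, "hr": hr, "hr_p": p,
                     "delta_eigenvector": d_eig, "delta_in_degree": d_in,
                     "delta_out_degree": d_out, "delta_betweenness": d_btw})
    return pd.DataFrame(rows).set_index("node")
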