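"""Correlation networks: filtering, communities, and strength categories.

Detected pairwise correlations form a weighted undirected graph — nucleotides
are nodes, edges carry the correlation magnitude |phi| (the sign is kept as an
attribute; modularity on negative weights is ill-defined).  The published
filtering recipe is applied before community detection: drop edges at or below
a weight floor (0.015), then take the k-core (k = 3).  Communities come from
Louvain modularity maximization at resolution 1.0, seeded for reproducibility.

Node strength (weighted degree) is banded strong / medium / weak at fixed
cutoffs; edge strength is banded at the 50th and 75th weight percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .pairwise_correlation import RingSet

__all__ = [
    "RingNetwork",
    "CommunityPartition",
    "EdgeDelta",
    "build_graph",
    "filter_graph",
    "detect_communities",
    "node_strengths",
    "edge_categories",
    "cross_community_edges",
    "differential_edges",
    "write_graphml",
    "write_community_tsv",
    "write_edge_delta_tsv",
]

NODE_STRONG = 0.25   # weighted degree strictly above -> strong
NODE_WEAK = 0.1      # weighted degree strictly below -> weak; [0.1, 0.25] medium


@dataclass
class RingNetwork:
    """Weighted undirected nucleotide graph with its filter parameters.

    Wraps a :class:`networkx.Graph` whose nodes are 1-based positions and whose
    edges carry ``weight`` (= |phi|) and ``sign`` (+1/-1) attributes.
    """

    graph: nx.Graph
    weight_min: float | None = None
    kcore_k: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CommunityPartition:
    """Node -> community assignment with the modularity achieved.

    Community ids are consecutive integers from 0, ordered by decreasing
    community size (ties broken by smallest member position).
    """

    assignment: dict[int, int]
    modularity: float
    resolution: float
    seed: int | None = None

    def communities(self) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities()]


@dataclass(frozen=True)
class EdgeDelta:
    """Weight change of one edge between two conditions (0 when absent)."""

    i: int
    j: int
    weight_a: float
    weight_b: float
    delta: float
    classification: str  # strengthened | weakened | unchanged


def build_graph(rings: RingSet, use_magnitude: bool = True) -> RingNetwork:
    """Unfiltered network from a ring set: one node per involved position, one
    edge per ring with weight |phi| (or signed phi if ``use_magnitude=False``)
    and the phi sign as an attribute."""
    g = nx.Graph()
    for row in rings.rings.itertuples(index=False):
        phi = float(row.phi)
        w = abs(phi) if use_magnitude else phi
        g.add_edge(int(row.i), int(row.j), weight=w,
                   sign=int(np.sign(phi)) if phi != 0 else 0)
    return RingNetwork(graph=g)


def filter_graph(g: RingNetwork, weight_min: float = 0.015,
                 kcore_k: int = 3) -> RingNetwork:
    """Published network filter: drop edges with weight <= ``weight_min``
    (strictly "greater than 0.015" survives), then take the k-core — the
    maximal subgraph where every node keeps at least ``kcore_k`` edges,
    obtained by iterative peeling."""
    h = g.graph.copy()
    drop = [(u, v) for u, v, w in h.edges(data="weight") if w <= weight_min]
    h.remove_edges_from(drop)
    h.remove_nodes_from(list(nx.isolates(h)))
    h = nx.k_core(h, k=kcore_k)
    return RingNetwork(graph=h, weight_min=weight_min, kcore_k=kcore_k)


def detect_communities(g: RingNetwork, resolution: float = 1.0,
                       seed: int = 0) -> CommunityPartition:
    """Louvain modularity maximization on edge weights.

    Deterministic given ``seed``.  Community ids are relabelled by decreasing
    size (ties by smallest member) so output is stable across runs.

    Raises
    ------
    ValueError
        On an empty graph.
    """
    if g.graph.number_of_nodes() == 0:
        raise ValueError("cannot detect communities on an empty graph")
    comms = nx.community.louvain_communities(
        g.graph, weight="weight", resolution=resolution, seed=seed)
    mod = nx.community.modularity(g.graph, comms, weight="weight",
                                  resolution=resolution)
    ordered = sorted(comms, key=lambda c: (-len(c), min(c)))
    assignment = {node: cid for cid, comm in enumerate(ordered) for node in comm}
    return CommunityPartition(assignment=assignment, modularity=mod,
                              resolution=resolution, seed=seed)


def node_strengths(g: RingNetwork) -> pd.DataFrame:
    """Weighted degree (sum of incident edge weights) and strength band per node.

    Bands: strong if weighted degree > 0.25, weak if < 0.1, medium in between
    (both ends of [0.1, 0.25] inclusive).
    """
    rows = []
    for node in sorted(g.graph.nodes):
        wd = sum(d["weight"] for _, _, d in g.graph.edges(node, data=True))
        if wd > NODE_STRONG:
            cat = "strong"
        elif wd < NODE_WEAK:
            cat = "weak"
        else:
            cat = "medium"
        rows.append({"position": node, "degree": g.graph.degree(node),
                     "weighted_degree": wd, "strength_category": cat})
    return pd.DataFrame(rows, columns=["position", "degree", "weighted_degree",
                                       "strength_category"])


def _nearest_rank(sorted_weights: np.ndarray, q: float) -> float:
    """Upper nearest-rank percentile: value at 0-based index floor(q*n)."""
    n = len(sorted_weights)
    idx = min(int(np.floor(q * n)), n - 1)
    return float(sorted_weights[idx])


def edge_categories(g: RingNetwork) -> tuple[pd.DataFrame, dict]:
    """Band edges by weight percentile: strong >= p75, medium in [p50, p75),
    weak < p50 (nearest-rank convention).  With fewer than 4 edges the
    percentiles are meaningless and every edge is "unranked".

    Returns the per-edge table and the thresholds used, so every category is
    recomputable.
    """
    edges = [(u, v, d["weight"]) for u, v, d in g.graph.edges(data=True)]
    edges = [(min(u, v), max(u, v), w) for u, v, w in edges]
    edges.sort()
    if len(edges) < 4:
        df = pd.DataFrame([{"i": u, "j": v, "weight": w, "strength_category": "unranked"}
                           for u, v, w in edges],
                          columns=["i", "j", "weight", "strength_category"])
        return df, {"p50": None, "p75": None}
    weights = np.sort(np.array([w for _, _, w in edges]))
    p50 = _nearest_rank(weights, 0.50)
    p75 = _nearest_rank(weights, 0.75)
    rows = []
    for u, v, w in edges:
        if w >= p75:
            cat = "strong"
        elif w >= p50:
            cat = "medium"
        else:
            cat = "weak"
        rows.append({"i": u, "j": v, "weight": w, "strength_category": cat})
    return pd.DataFrame(rows), {"p50": p50, "p75": p75}


def cross_community_edges(g: RingNetwork, p: CommunityPartition,
                          a: int, b: int) -> list[tuple[int, int, float]]:
    """Edges with one endpoint in community ``a`` and the other in ``b``
    (symmetric in a and b).  Returns (i, j, weight) with i < j, sorted."""
    known = set(p.assignment.values())
    for cid in (a, b):
        if cid not in known:
            raise ValueError(f"unknown community id {cid}")
    out = []
    for u, v, d in g.graph.edges(data=True):
        cu, cv = p.assignment.get(u), p.assignment.get(v)
        if {cu, cv} == {a, b} and cu != cv:
            out.append((min(u, v), max(u, v), d["weight"]))
    return sorted(out)


def differential_edges(a: RingNetwork, b: RingNetwork,
                       delta_min: float = 0.01) -> list[EdgeDelta]:
    """Edge-weight changes from condition *a* to condition *b*.

    Over the union of edge sets (an absent edge has weight 0):
    ``delta = weight_b - weight_a``; strengthened if delta >= ``delta_min``,
    weakened if delta <= -``delta_min``, else unchanged.  Only strengthened and
    weakened edges are returned.
    """
    wa = {(min(u, v), max(u, v)): d["weight"] for u, v, d in a.graph.edges(data=True)}
    wb = {(min(u, v), max(u, v)): d["weight"] for u, v, d in b.graph.edges(data=True)}
    out = []
    for key in sorted(set(wa) | set(wb)):
        w0, w1 = wa.get(key, 0.0), wb.get(key, 0.0)
        delta = w1 - w0
        if delta >= delta_min:
            cls = "strengthened"
        elif delta <= -delta_min:
            cls = "weakened"
        else:
            continue
        out.append(EdgeDelta(i=key[0], j=key[1], weight_a=w0, weight_b=w1,
                             delta=delta, classification=cls))
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_graphml(path: str | Path, g: RingNetwork,
                  partition: CommunityPartition | None = None) -> None:
    """GraphML with node attributes (community, degree, weighted_degree,
    strength_category) and edge attributes (weight, sign, strength_category)."""
    h = g.graph.copy()
    strengths = node_strengths(g).set_index("position")
    for node in h.nodes:
        h.nodes[node]["degree"] = int(strengths.loc[node, "degree"])
        h.nodes[node]["weighted_degree"] = float(strengths.loc[node, "weighted_degree"])
        h.nodes[node]["strength_category"] = str(strengths.loc[node, "strength_category"])
        if partition is not None:
            h.nodes[node]["community"] = int(partition.assignment[node])
    cats, _ = edge_categories(g)
    lookup = {(r.i, r.j): r.strength_category for r in cats.itertuples(index=False)}
    for u, v in h.edges:
        h.edges[u, v]["strength_category"] = lookup[(min(u, v), max(u, v))]
    nx.write_graphml(h, str(path))


def write_community_tsv(path: str | Path, partition: CommunityPartition) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# modularity={partition.modularity:.6g} "
                 f"resolution={partition.resolution} seed={partition.seed}\n")
        fh.write("position\tcommunity\n")
        for node in sorted(partition.assignment):
            fh.write(f"{node}\t{partition.assignment[node]}\n")


def write_edge_delta_tsv(path: str | Path, deltas: Iterable[EdgeDelta]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("i\tj\tweight_a\tweight_b\tdelta\tclass\n")
        for d in deltas:
            fh.write(f"{d.i}\t{d.j}\t{d.weight_a:.6g}\t{d.weight_b:.6g}"
                     f"\t{d.delta:.6g}\t{d.classification}\n")
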