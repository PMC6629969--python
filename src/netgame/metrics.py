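"""Summary network measures and per-node structural features.

Two consumers: the comparison tables (clustering, path length, neighbours,
diameter, betweenness, homogeneity, density, plus degree / path-length /
betweenness distributions) and the game's utility function, which needs each
node's average shortest-path length S_i, PageRank P_i, closeness C_i and
betweenness Be_i.

Conventions, since the networks may be directed and need not be connected:

* clustering is always computed on the undirected projection (nodes with
  undirected degree < 2 contribute 0);
* shortest-path averages run over *ordered reachable pairs only*; the
  diameter is the largest finite distance;
* S_i, C_i, Be_i are computed on the undirected projection, P_i on the
  directed graph (damping 0.85, uniform teleport);
* homogeneity is the degree-uniformity index ⟨k⟩²/⟨k²⟩ over undirected
  degrees — 1 for regular graphs, small for heavy-tailed ones.

Quantities undefined on a given graph (e.g. path length with no reachable
pair, S_i of an isolated node) are reported as ``nan`` sentinels, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

UNDEFINED = float("nan")

#: measures shown in the comparison tables, in display order
TABLE_MEASURES = [
    "avg_clustering",
    "avg_shortest_path",
    "avg_neighbors",
    "diameter",
    "avg_betweenness",
    "homogeneity",
    "density",
]


@dataclass
class MetricsReport:
    label: str
    directed: bool
    n_nodes: int
    n_edges: int
    avg_clustering: float
    avg_shortest_path: float
    avg_neighbors: float
    diameter: float
    avg_betweenness: float
    homogeneity: float
    density: float
    in_degree_hist: dict[int, int] = field(default_factory=dict)
    out_degree_hist: dict[int, int] = field(default_factory=dict)
    degree_hist: dict[int, int] = field(default_factory=dict)
    shortest_path_hist: dict[int, int] = field(default_factory=dict)
    betweenness_values: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def scalar_row(self) -> dict:
        return {m: getattr(self, m) for m in TABLE_MEASURES}


@dataclass(frozen=True)
class NodeFeatures:
    """Structural features of one node: S_i, P_i, C_i, Be_i."""

    S: float
    P: float
    C: float
    Be: float

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.P, self.C, self.Be], dtype=float)


def _degree_hist(degrees) -> dict[int, int]:
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def _path_stats(g) -> tuple[float, float, dict[int, int]]:
    """(average shortest path, diameter, distance histogram) over ordered
    reachable pairs; (nan, nan, {}) when no pair is reachable."""
    total = 0
    count = 0
    longest = 0
    hist: dict[int, int] = {}
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d == 0:
                continue
            total += d
            count += 1
            hist[d] = hist.get(d, 0) + 1
            if d > longest:
                longest = d
    if count == 0:
        return UNDEFINED, UNDEFINED, {}
    return total / count, float(longest), dict(sorted(hist.items()))


def homogeneity_index(g: nx.Graph) -> float:
    """⟨k⟩² / ⟨k²⟩ over undirected degrees; in (0, 1], 1 iff regular."""
    und = g.to_undirected() if g.is_directed() else g
    k = np.array([d for _, d in und.degree()], dtype=float)
    if len(k) == 0 or np.all(k == 0):
        return UNDEFINED
    return float(np.mean(k) ** 2 / np.mean(k**2))


def compute_metrics(g: nx.DiGraph | nx.Graph, *, directed: bool = True,
                    label: str = "network") -> MetricsReport:
    """Compute the full comparison report for one network.

    With ``directed=False`` every measure uses the undirected projection;
    with ``directed=True`` path measures and density use the digraph while
    clustering, neighbour count and homogeneity (which the comparison tables
    define once, undirected) use the projection.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("metrics undefined for the empty graph")
    und = g.to_undirected() if g.is_directed() else g
    work = g if (directed and g.is_directed()) else und

    n = work.number_of_nodes()
    avg_sp, diam, sp_hist = _path_stats(work)
    bc = nx.betweenness_centrality(work, normalized=True)
    clustering = nx.average_clustering(und) if n > 0 else UNDEFINED
    report = MetricsReport(
        label=label,
        directed=work.is_directed(),
        n_nodes=n,
        n_edges=work.number_of_edges(),
        avg_clustering=float(clustering),
        avg_shortest_path=avg_sp,
        avg_neighbors=2.0 * und.number_of_edges() / n,
        diameter=diam,
        avg_betweenness=float(np.mean(list(bc.values()))),
        homogeneity=homogeneity_index(und),
        density=float(nx.density(work)),
        in_degree_hist=_degree_hist(
            d for _, d in (work.in_degree() if work.is_directed() else work.degree())
        ),
        out_degree_hist=_degree_hist(
            d for _, d in (work.out_degree() if work.is_directed() else work.degree())
        ),
        degree_hist=_degree_hist(d for _, d in und.degree()),
        shortest_path_hist=sp_hist,
        betweenness_values=sorted(float(v) for v in bc.values()),
    )
    return report


def avg_path_from_node(und: nx.Graph, node, *, sentinel: float = UNDEFINED) -> float:
    """S_i: mean hop distance from *node* to its reachable peers on the
    undirected projection; *sentinel* when no peer is reachable."""
    dists = nx.single_source_shortest_path_length(und, node)
    total = sum(d for d in dists.values() if d > 0)
    reachable = len(dists) - 1
    if reachable == 0:
        return sentinel
    return total / reachable


def node_features(g: nx.DiGraph | nx.Graph, node, *, pagerank_damping: float = 0.85) -> NodeFeatures:
    """Features of one node; see module docstring for conventions."""
    feats = all_node_features(g, pagerank_damping=pagerank_damping)
    return feats[node]


def all_node_features(g: nx.DiGraph | nx.Graph, *, pagerank_damping: float = 0.85,
                      ) -> dict[object, NodeFeatures]:
    """Features for every node at once (one traversal set, not n)."""
    und = g.to_undirected() if g.is_directed() else g
    pr = nx.pagerank(g, alpha=pagerank_damping) if g.number_of_edges() else {
        v: 1.0 / g.number_of_nodes() for v in g
    }
    bc = nx.betweenness_centrality(und, normalized=True)
    out = {}
    for v in g:
        s = avg_path_from_node(und, v)
        # closeness over reachable peers only (Wasserman-Faust unscaled form
        # restricted to the reachable set); isolated node -> 0
        c = 0.0 if np.isnan(s) or s == 0 else 1.0 / s
        out[v] = NodeFeatures(S=s, P=float(pr[v]), C=c, Be=float(bc[v]))
    return out


def compare_networks(reports: list[MetricsReport], labels: list[str] | None = None):
    """Tables-style comparison: per-measure values for every network and
    absolute differences versus the first (reference) report.

    Returns a DataFrame with one row per network, one column per measure,
    plus ``|Δ measure|`` columns for the non-reference rows.
    """
    import pandas as pd

    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    labels = labels or [r.label for r in reports]
    rows = []
    ref = reports[0]
    for lab, rep in zip(labels, reports):
        row = {"network": lab}
        row.update(rep.scalar_row())
        for m in TABLE_MEASURES:
            row[f"abs_diff_{m}"] = (
                0.0 if rep is ref else abs(getattr(rep, m) - getattr(ref, m))
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("network")
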