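"""Random-network generators used as candidate base networks and baselines.

Three undirected models (distance-based Watts-Strogatz, expected-degree,
power-law clustering) and three directed ones (Havel-Hakimi from an in/out
degree sequence, scale-free preferential attachment, Erdos-Renyi).  All are
seed-deterministic: the same parameters and seed give an identical edge set.

Where networkx ships the exact construction (Havel-Hakimi, G(n,p),
expected-degree, power-law clustering) we delegate to it; the distance-based
small-world variant and the directed scale-free growth with an edge-budget
stopping rule are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .netio import AttributeTable

logger = logging.getLogger("netgame")

GENERATOR_KINDS = (
    "watts_strogatz_distance",
    "expected_degree",
    "powerlaw_cluster",
    "havel_hakimi_directed",
    "scale_free_directed",
    "erdos_renyi_directed",
)


class GraphicalityError(ValueError):
    """The in/out degree sequences admit no simple digraph."""


@dataclass
class GeneratorSpec:
    """Declarative description of one generator run (for configs/CLI)."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in GENERATOR_KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; "
                             f"choose from {GENERATOR_KINDS}")


def _relabel_sorted(g: nx.Graph, ids=None) -> nx.Graph:
    if ids is None:
        return g
    mapping = dict(zip(sorted(g.nodes), ids))
    return nx.relabel_nodes(g, mapping)


def havel_hakimi_directed(in_seq, out_seq, seed: int | None = None,
                          ids=None) -> nx.DiGraph:
    """Realize an in/out degree sequence exactly as a simple digraph.

    Node ``i`` of the output has in-degree ``in_seq[i]`` and out-degree
    ``out_seq[i]`` exactly.  The constructive algorithm itself is
    deterministic; *seed* randomizes which node receives which degree pair by
    shuffling the sequence jointly before construction, so repeated draws
    explore different realizations while every node still carries one of the
    prescribed degree pairs.  Raises :class:`GraphicalityError` when the
    sequences are not di-graphical.
    """
    in_seq = [int(d) for d in in_seq]
    out_seq = [int(d) for d in out_seq]
    if len(in_seq) != len(out_seq):
        raise GraphicalityError("in/out sequences differ in length")
    if any(d < 0 for d in in_seq + out_seq):
        raise GraphicalityError("degrees must be non-negative")
    if sum(in_seq) != sum(out_seq):
        raise GraphicalityError("in/out degree sums differ")
    n = len(in_seq)
    order = list(range(n))
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(order)
    try:
        g = nx.directed_havel_hakimi_graph(
            [in_seq[i] for i in order], [out_seq[i] for i in order]
        )
    except nx.NetworkXError as exc:
        raise GraphicalityError(str(exc)) from exc
    # undo the shuffle so degrees line up with the input indices
    g = nx.relabel_nodes(g, {pos: orig for pos, orig in enumerate(order)})
    g = nx.DiGraph(g)
    if ids is not None:
        g = nx.relabel_nodes(g, dict(enumerate(ids)))
    return g


def erdos_renyi_directed(n: int, p: float, seed: int | None = None) -> nx.DiGraph:
    """G(n, p) digraph: each ordered pair an edge independently with prob p."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return nx.gnp_random_graph(n, p, seed=seed, directed=True)


def watts_strogatz_distance(attrs: AttributeTable, k: int, rewire_p: float,
                            seed: int | None = None) -> nx.Graph:
    """Small-world graph wired by physical proximity instead of a ring.

    Stage 1 links every neuron to its *k* nearest neighbours by Euclidean
    soma distance (undirected union of the k-NN relation, so degrees are
    >= k up to n-1).  Stage 2 visits each edge once and, with probability
    *rewire_p*, moves its far endpoint to a uniformly chosen partner that
    does not duplicate an existing edge; edge count is preserved.  Distance
    ties break lexicographically by id.
    """
    ids = sorted(attrs.ids)
    n = len(ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of nodes")
    rng = np.random.default_rng(seed)
    pos = np.array([attrs.position(i) for i in ids])
    g = nx.Graph()
    g.add_nodes_from(ids)
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    for a in range(n):
        order = sorted(range(n), key=lambda b: (d2[a, b], ids[b]))
        neigh = [b for b in order if b != a][:k]
        for b in neigh:
            g.add_edge(ids[a], ids[b])
    for u, v in list(g.edges):
        if rng.random() < rewire_p:
            candidates = [w for w in ids if w != u and not g.has_edge(u, w)]
            if not candidates:
                continue
            w = candidates[rng.integers(len(candidates))]
            g.remove_edge(u, v)
            g.add_edge(u, w)
    return g


def expected_degree_graph(degree_seq, seed: int | None = None, ids=None) -> nx.Graph:
    """Chung-Lu graph: edge (u,v) present with probability w_u w_v / Σw.

    Self-pairs are excluded (simple graph); probabilities above 1 are
    clipped to 1 with a warning.
    """
    w = [float(d) for d in degree_seq]
    if any(x < 0 for x in w):
        raise ValueError("expected degrees must be non-negative")
    total = sum(w)
    if total > 0 and max(w) ** 2 > total:
        logger.warning(
            "expected_degree_graph: max degree^2 exceeds the degree sum; "
            "edge probabilities clipped to 1"
        )
    g = nx.expected_degree_graph(w, seed=seed, selfloops=False)
    return _relabel_sorted(g, ids)


def powerlaw_cluster_graph(n: int, m: int, triangle_p: float,
                           seed: int | None = None) -> nx.Graph:
    """Preferential-attachment growth with probabilistic triangle closure."""
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    return nx.powerlaw_cluster_graph(n, m, triangle_p, seed=seed)


def scale_free_directed(n_target: int, alpha: float = 0.15, beta: float = 0.8,
                        gamma: float = 0.05, delta_in: float = 0.2,
                        delta_out: float = 0.0, seed: int | None = None,
                        edge_budget: int | None = None,
                        max_events: int | None = None) -> nx.DiGraph:
    """Directed scale-free growth (Bollobas et al. alpha/beta/gamma process).

    Each event, with probability *alpha* a new node is added with an edge to
    an existing node chosen by in-degree (+ *delta_in*); with probability
    *beta* an edge is added between existing nodes, source by out-degree
    (+ *delta_out*), target by in-degree; with probability *gamma* a new node
    is added receiving an edge from an existing node chosen by out-degree.
    Growth stops when the node count reaches *n_target* or, if given, the
    simple-graph edge count reaches *edge_budget*.  The returned digraph is
    simple (the process's duplicate draws are dropped), so the final node
    count is not guaranteed to equal *n_target* when an edge budget binds.
    """
    probs = np.array([alpha, beta, gamma], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("alpha, beta, gamma must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_edge(0, 1)
    g.add_edge(1, 2)

    def pick_by_in(exclude=None):
        nodes = list(g.nodes)
        wts = np.array([g.in_degree(v) + delta_in for v in nodes], dtype=float)
        if exclude is not None:
            wts[nodes.index(exclude)] = 0.0
        if wts.sum() <= 0:
            wts[:] = 1.0
            if exclude is not None:
                wts[nodes.index(exclude)] = 0.0
        return nodes[rng.choice(len(nodes), p=wts / wts.sum())]

    def pick_by_out(exclude=None):
        nodes = list(g.nodes)
        wts = np.array([g.out_degree(v) + delta_out for v in nodes], dtype=float)
        if exclude is not None:
            wts[nodes.index(exclude)] = 0.0
        if wts.sum() <= 0:
            wts[:] = 1.0
            if exclude is not None:
                wts[nodes.index(exclude)] = 0.0
        return nodes[rng.choice(len(nodes), p=wts / wts.sum())]

    events = 0
    limit = max_events if max_events is not None else 50 * (
        edge_budget if edge_budget is not None else max(n_target, 3)
    )
    while events < limit:
        if g.number_of_nodes() >= n_target and (
            edge_budget is None or g.number_of_edges() >= edge_budget
        ):
            break
        if edge_budget is not None and g.number_of_edges() >= edge_budget:
            break
        r = rng.random()
        if r < alpha and g.number_of_nodes() < n_target:
            new = max(g.nodes) + 1
            tgt = pick_by_in()
            g.add_edge(new, tgt)
        elif r < alpha + beta:
            src = pick_by_out()
            tgt = pick_by_in(exclude=src)
            g.add_edge(src, tgt)  # duplicate draws are no-ops: simple graph
        elif g.number_of_nodes() < n_target:
            new = max(g.nodes) + 1
            src = pick_by_out()
            g.add_edge(src, new)
        events += 1
    return g


def from_spec(spec: GeneratorSpec, attrs: AttributeTable | None = None):
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    p = dict(spec.params)
    kind = spec.kind
    if kind == "watts_strogatz_distance":
        if attrs is None:
            raise ValueError("watts_strogatz_distance needs an attribute table")
        return watts_strogatz_distance(attrs, p["k"], p["rewire_p"], seed=spec.seed)
    if kind == "expected_degree":
        return expected_degree_graph(p["degree_seq"], seed=spec.seed, ids=p.get("ids"))
    if kind == "powerlaw_cluster":
        return powerlaw_cluster_graph(p["n"], p["m"], p["triangle_p"], seed=spec.seed)
    if kind == "havel_hakimi_directed":
        return havel_hakimi_directed(p["in_seq"], p["out_seq"], seed=spec.seed,
                                     ids=p.get("ids"))
    if kind == "scale_free_directed":
        return scale_free_directed(
            p.get("n_target", 131), p.get("alpha", 0.15), p.get("beta", 0.8),
            p.get("gamma", 0.05), p.get("delta_in", 0.2), p.get("delta_out", 0.0),
            seed=spec.seed, edge_budget=p.get("edge_budget"),
        )
    if kind == "erdos_renyi_directed":
        return erdos_renyi_directed(p["n"], p["p"], seed=spec.seed)
    raise ValueError(kind)
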