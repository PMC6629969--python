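"""The strategic network-formation game.

Neurons are agents whose strategy toward every other neuron is to hold a
link (L) or not (D).  Each neuron i scores a state of the network, relative
to an opponent j, with the linear utility

    u_i = 1[linked] * (alpha * D_ij + beta * B_ij)
          + lam * S_i + rho * P_i + theta * C_i + omega * Be_i

where D_ij is the Euclidean soma distance (µm), B_ij the absolute birth-time
difference (min), S_i the node's average shortest-path length, P_i its
PageRank, C_i its closeness and Be_i its betweenness centrality.  The link
cost terms D and B apply only while the link exists; the structural terms
are evaluated on whichever network state is being scored.

A network is *pairwise stable* when no agent gains by deleting one of its
links and no pair of agents can both gain by adding the missing link between
them.  :func:`is_pairwise_stable` checks that condition exhaustively;
:func:`evolve` iterates add/delete moves over a base network until it holds.

Conventions (all held in :class:`GameConfig` so that checking and evolving
agree): the game acts on unordered pairs — a pair counts as linked when any
directed edge exists between the two nodes, deletion removes every such
edge, and addition inserts one directed edge whose direction is a
deterministic per-pair coin (or a fixed rule, configurable).  S, C, Be are
computed on the undirected projection, P on the digraph.  A node isolated
by a move takes the penalty sentinel S_i = n so the dynamics stay defined.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .netio import AttributeTable

FEATURE_NAMES = ("D", "B", "S", "P", "C", "Be")


@dataclass(frozen=True)
class UtilityCoefficients:
    """Weights (alpha, beta, lam, rho, theta, omega) on (D, B, S, P, C, Be)."""

    alpha: float
    beta: float
    lam: float
    rho: float
    theta: float
    omega: float
    normalized_features: bool = False  # scaling metadata, not used in the math

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.beta, self.lam, self.rho, self.theta, self.omega]
        )

    @classmethod
    def from_array(cls, arr, **kw) -> "UtilityCoefficients":
        a = [float(x) for x in arr]
        if len(a) != 6:
            raise ValueError("expected 6 coefficients")
        return cls(*a, **kw)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "beta": self.beta, "lam": self.lam,
            "rho": self.rho, "theta": self.theta, "omega": self.omega,
        }

    @classmethod
    def from_dict(cls, d) -> "UtilityCoefficients":
        return cls(**{k: float(d[k]) for k in ("alpha", "beta", "lam", "rho", "theta", "omega")})


@dataclass(frozen=True)
class GameConfig:
    """Shared conventions of the stability check and the dynamics.

    tol: absolute tolerance for "strictly increases".
    deletion_rule: 'either' — a link falls when one endpoint gains by cutting
        it (deletion is unilateral); 'both' — only when both gain.
    addition_rule: 'both_strict' — a link forms only when both endpoints
        strictly gain; 'standard' additionally counts an addition where one
        endpoint strictly gains and the other is indifferent as a stability
        violation (the textbook pairwise-stability condition).
    edge_direction: direction given to a newly formed link —
        'coin' (deterministic per-pair fair coin keyed by direction_seed),
        'low_to_high' (lexicographic), or 'both' (two directed edges).
    isolated_path_sentinel: S_i for a node with no reachable peer; 'n' means
        the node count (a penalty that makes isolation costly when lam < 0).
    """

    tol: float = 1e-12
    deletion_rule: str = "either"
    addition_rule: str = "standard"
    edge_direction: str = "coin"
    direction_seed: int = 0
    pagerank_damping: float = 0.85
    isolated_path_sentinel: float | str = "n"
    max_sweeps: int = 60

    def __post_init__(self):
        if self.deletion_rule not in ("either", "both"):
            raise ValueError("deletion_rule must be 'either' or 'both'")
        if self.addition_rule not in ("standard", "both_strict"):
            raise ValueError("addition_rule must be 'standard' or 'both_strict'")
        if self.edge_direction not in ("coin", "low_to_high", "both"):
            raise ValueError("edge_direction must be coin, low_to_high or both")


@dataclass(frozen=True)
class PairFeatures:
    """The 6 utility inputs for one endpoint of one pair in one state."""

    D: float
    B: float
    S: float
    P: float
    C: float
    Be: float

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.B, self.S, self.P, self.C, self.Be])


@dataclass
class MoveRecord:
    pair: tuple
    action: str  # 'L' (link added) or 'D' (link deleted)
    sweep: int
    gain_i: float
    gain_j: float


@dataclass
class StabilityReport:
    stable: bool
    violations: list = field(default_factory=list)  # (pair, kind, gain_i, gain_j)
    n_pairs_checked: int = 0


@dataclass
class EvolutionResult:
    graph: nx.DiGraph
    moves: list[MoveRecord]
    converged: bool
    sweeps: int
    config: GameConfig


def utility(features: PairFeatures, linked: bool, coeffs: UtilityCoefficients) -> float:
    """Evaluate the linear utility; D and B terms vanish when not linked."""
    vec = features.as_array()
    if not linked:
        vec = vec.copy()
        vec[0] = 0.0
        vec[1] = 0.0
    return float(coeffs.as_array() @ vec)


def _pair_direction(i, j, cfg: GameConfig) -> list[tuple]:
    """Directed edge(s) a new link between i and j would materialize as."""
    a, b = sorted((i, j))
    if cfg.edge_direction == "both":
        return [(a, b), (b, a)]
    if cfg.edge_direction == "low_to_high":
        return [(a, b)]
    # deterministic fair coin, stable across processes and sweeps
    h = zlib.crc32(f"{cfg.direction_seed}:{a}:{b}".encode())
    return [(a, b)] if h % 2 == 0 else [(b, a)]


class _Evaluator:
    """Incremental utility evaluation on a mutable working graph.

    Maintains the digraph and its undirected projection together and
    evaluates both states (pair linked / pair unlinked) of any pair by
    toggling the pair in place.  PageRank and betweenness are only
    recomputed when their coefficients are non-zero (`need` mask), which is
    the dominant cost in the dynamics.
    """

    def __init__(self, g: nx.DiGraph, attrs: AttributeTable, cfg: GameConfig,
                 need_pagerank: bool, need_betweenness: bool):
        self.g = g
        self.und = nx.Graph()
        self.und.add_nodes_from(g.nodes)
        self.und.add_edges_from(g.edges)
        self.attrs = attrs
        self.cfg = cfg
        self.need_pr = need_pagerank
        self.need_bc = need_betweenness
        self.n = g.number_of_nodes()
        self.sentinel = (
            float(self.n) if cfg.isolated_path_sentinel == "n"
            else float(cfg.isolated_path_sentinel)
        )

    # --- state toggling -------------------------------------------------
    def linked(self, i, j) -> bool:
        return self.und.has_edge(i, j)

    def remove_pair(self, i, j) -> list[tuple]:
        removed = [e for e in ((i, j), (j, i)) if self.g.has_edge(*e)]
        self.g.remove_edges_from(removed)
        if self.und.has_edge(i, j):
            self.und.remove_edge(i, j)
        return removed

    def restore_pair(self, edges) -> None:
        self.g.add_edges_from(edges)
        for u, v in edges:
            self.und.add_edge(u, v)

    def add_pair(self, i, j) -> list[tuple]:
        edges = [e for e in _pair_direction(i, j, self.cfg) if not self.g.has_edge(*e)]
        self.g.add_edges_from(edges)
        self.und.add_edge(i, j)
        return edges

    def unadd_pair(self, edges, i, j) -> None:
        self.g.remove_edges_from(edges)
        if self.und.has_edge(i, j):
            self.und.remove_edge(i, j)

    # --- features -------------------------------------------------------
    def _avg_path(self, v) -> float:
        dists = nx.single_source_shortest_path_length(self.und, v)
        reachable = len(dists) - 1
        if reachable == 0:
            return self.sentinel
        return sum(dists.values()) / reachable

    def endpoint_features(self, i, j, linked: bool) -> PairFeatures:
        s = self._avg_path(i)
        c = 0.0 if s == self.sentinel and self.und.degree(i) == 0 else (
            0.0 if s == 0 else 1.0 / s
        )
        p = 0.0
        if self.need_pr:
            p = float(nx.pagerank(self.g, alpha=self.cfg.pagerank_damping)[i]) \
                if self.g.number_of_edges() else 1.0 / self.n
        be = 0.0
        if self.need_bc:
            be = float(nx.betweenness_centrality(self.und, normalized=True)[i])
        if linked:
            d = self.attrs.distance(i, j)
            b = self.attrs.birth_diff(i, j)
        else:
            d = b = 0.0
        return PairFeatures(D=d, B=b, S=s, P=p, C=c, Be=be)

    def pair_state_features(self, i, j):
        """Features of both endpoints in the linked and unlinked states.

        Returns ((fi_linked, fj_linked), (fi_unlinked, fj_unlinked)); the
        working graph is left exactly as found.
        """
        currently = self.linked(i, j)
        if currently:
            fi_l = self.endpoint_features(i, j, True)
            fj_l = self.endpoint_features(j, i, True)
            removed = self.remove_pair(i, j)
            fi_u = self.endpoint_features(i, j, False)
            fj_u = self.endpoint_features(j, i, False)
            self.restore_pair(removed)
        else:
            fi_u = self.endpoint_features(i, j, False)
            fj_u = self.endpoint_features(j, i, False)
            added = self.add_pair(i, j)
            fi_l = self.endpoint_features(i, j, True)
            fj_l = self.endpoint_features(j, i, True)
            self.unadd_pair(added, i, j)
        return (fi_l, fj_l), (fi_u, fj_u)

    def pair_utilities(self, i, j, coeffs: UtilityCoefficients):
        """((u_i, u_j) linked state, (u_i, u_j) unlinked state)."""
        (fi_l, fj_l), (fi_u, fj_u) = self.pair_state_features(i, j)
        return (
            (utility(fi_l, True, coeffs), utility(fj_l, True, coeffs)),
            (utility(fi_u, False, coeffs), utility(fj_u, False, coeffs)),
        )


def _make_evaluator(g, attrs, coeffs, cfg) -> _Evaluator:
    missing = set(g.nodes) - set(attrs.ids)
    if missing:
        raise KeyError(f"attributes missing for nodes: {sorted(missing)[:5]}")
    return _Evaluator(
        g, attrs, cfg,
        need_pagerank=coeffs.rho != 0.0,
        need_betweenness=coeffs.omega != 0.0,
    )


def all_pairs(nodes) -> list[tuple]:
    ids = sorted(nodes)
    return [(ids[a], ids[b]) for a in range(len(ids)) for b in range(a + 1, len(ids))]


def is_pairwise_stable(g: nx.DiGraph, attrs: AttributeTable,
                       coeffs: UtilityCoefficients,
                       config: GameConfig | None = None) -> StabilityReport:
    """Exhaustively check pairwise stability of *g* under *coeffs*.

    For every linked pair the check asks whether deletion profits an
    endpoint (per ``deletion_rule``); for every unlinked pair whether
    addition profits both (per ``addition_rule``).  Every violating pair is
    reported with both endpoints' utility gains from the deviation.
    """
    cfg = config or GameConfig()
    ev = _make_evaluator(g.copy(), attrs, coeffs, cfg)
    violations = []
    pairs = all_pairs(g.nodes)
    for i, j in pairs:
        (ul_i, ul_j), (uu_i, uu_j) = ev.pair_utilities(i, j, coeffs)
        if ev.linked(i, j):
            gain_i, gain_j = uu_i - ul_i, uu_j - ul_j  # gains from deleting
            bad = (
                max(gain_i, gain_j) > cfg.tol
                if cfg.deletion_rule == "either"
                else min(gain_i, gain_j) > cfg.tol
            )
            if bad:
                violations.append(((i, j), "delete", gain_i, gain_j))
        else:
            gain_i, gain_j = ul_i - uu_i, ul_j - uu_j  # gains from adding
            if cfg.addition_rule == "standard":
                bad = (gain_i > cfg.tol and gain_j >= -cfg.tol) or (
                    gain_j > cfg.tol and gain_i >= -cfg.tol
                )
            else:
                bad = gain_i > cfg.tol and gain_j > cfg.tol
            if bad:
                violations.append(((i, j), "add", gain_i, gain_j))
    return StabilityReport(stable=not violations, violations=violations,
                           n_pairs_checked=len(pairs))


def map_nodes_by_degree(base: nx.DiGraph, reference: nx.DiGraph) -> dict:
    """Degree-rank bijection base node -> reference node.

    Both node sets are sorted by total (in+out) degree ascending, ties by
    id, and paired rank-for-rank; used to pull soma positions and birth
    times from the reference neurons onto the nodes of a random base
    network.
    """
    if base.number_of_nodes() != reference.number_of_nodes():
        raise ValueError(
            f"node counts differ: base {base.number_of_nodes()} vs "
            f"reference {reference.number_of_nodes()}"
        )

    def ranked(g):
        und_total = {v: g.in_degree(v) + g.out_degree(v) for v in g} if g.is_directed() \
            else {v: 2 * g.degree(v) for v in g}
        return sorted(g.nodes, key=lambda v: (und_total[v], str(v)))

    return dict(zip(ranked(base), ranked(reference)))


def transfer_attributes(mapping: dict, attrs: AttributeTable) -> AttributeTable:
    """Attribute table re-indexed onto base-network node ids via *mapping*."""
    frame = attrs.frame.loc[[mapping[b] for b in mapping]].copy()
    frame.index = list(mapping.keys())
    frame.index.name = attrs.frame.index.name or "neuron_id"
    return AttributeTable(frame)


def evolve(base: nx.DiGraph, attrs: AttributeTable, coeffs: UtilityCoefficients,
           config: GameConfig | None = None, seed: int = 0) -> EvolutionResult:
    """Run the add/delete dynamics on *base* until pairwise stable.

    Each sweep visits every unordered pair once, in a seeded random order.
    A linked pair is cut when deletion profits an endpoint (per
    ``deletion_rule``); an unlinked pair is joined when both endpoints
    strictly profit.  The dynamics stop at the first sweep that makes no
    move (converged) or at ``max_sweeps`` (converged=False — reported, not
    raised).  Deterministic given (base, attrs, coeffs, config, seed).
    """
    cfg = config or GameConfig()
    if cfg.edge_direction == "coin" and cfg.direction_seed == 0:
        cfg = replace(cfg, direction_seed=seed)
    g = base.copy()
    ev = _make_evaluator(g, attrs, coeffs, cfg)
    rng = np.random.default_rng(seed)
    pairs = all_pairs(g.nodes)
    moves: list[MoveRecord] = []
    converged = False
    sweep = 0
    for sweep in range(1, cfg.max_sweeps + 1):
        order = rng.permutation(len(pairs))
        made = 0
        for idx in order:
            i, j = pairs[idx]
            (ul_i, ul_j), (uu_i, uu_j) = ev.pair_utilities(i, j, coeffs)
            if ev.linked(i, j):
                gain_i, gain_j = uu_i - ul_i, uu_j - ul_j
                cut = (
                    max(gain_i, gain_j) > cfg.tol
                    if cfg.deletion_rule == "either"
                    else min(gain_i, gain_j) > cfg.tol
                )
                if cut:
                    ev.remove_pair(i, j)
                    moves.append(MoveRecord((i, j), "D", sweep, gain_i, gain_j))
                    made += 1
            else:
                gain_i, gain_j = ul_i - uu_i, ul_j - uu_j
                if gain_i > cfg.tol and gain_j > cfg.tol:
                    ev.add_pair(i, j)
                    moves.append(MoveRecord((i, j), "L", sweep, gain_i, gain_j))
                    made += 1
        if made == 0:
            converged = True
            break
    return EvolutionResult(graph=g, moves=moves, converged=converged,
                           sweeps=sweep, config=cfg)
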