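"""Utility evaluation, pairwise-stability checking and the evolution dynamics.

The stability oracle used here enumerates single-link deviations directly
with networkx calls, independent of the package's incremental evaluator.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netgame import (
    AttributeTable,
    GameConfig,
    PairFeatures,
    UtilityCoefficients,
    evolve,
    is_pairwise_stable,
    map_nodes_by_degree,
    transfer_attributes,
    utility,
)
from netgame.game import _pair_direction

ZERO = UtilityCoefficients(0, 0, 0, 0, 0, 0)
TABLE_LIKE = UtilityCoefficients(-1.0, -1.0, -0.02344, 0.0, -1.0, 0.0)


def make_attrs(ids, pos, bt):
    frame = pd.DataFrame(
        {
            "x_um": [p[0] for p in pos],
            "y_um": [p[1] for p in pos],
            "z_um": [p[2] for p in pos],
            "birth_time_min": bt,
        },
        index=pd.Index(ids, name="neuron_id"),
    )
    return AttributeTable(frame)


class TestUtility:
    def test_zero_coefficients_zero_utility(self):
        f = PairFeatures(D=3.0, B=2.0, S=1.5, P=0.2, C=0.6, Be=0.1)
        assert utility(f, True, ZERO) == 0.0
        assert utility(f, False, ZERO) == 0.0

    def test_linear_form_linked(self):
        f = PairFeatures(D=10.0, B=5.0, S=2.0, P=0.1, C=0.4, Be=0.05)
        assert utility(f, True, TABLE_LIKE) == pytest.approx(-15.44688)

    def test_link_costs_vanish_when_unlinked(self):
        f = PairFeatures(D=10.0, B=5.0, S=2.0, P=0.1, C=0.4, Be=0.05)
        assert utility(f, False, TABLE_LIKE) == pytest.approx(-0.44688)


# ---------------------------------------------------------------------------
# brute-force oracle: features via direct networkx calls on each deviation
# ---------------------------------------------------------------------------

def oracle_node_utility(g, attrs, coeffs, i, j, cfg):
    und = g.to_undirected()
    n = g.number_of_nodes()
    dists = nx.single_source_shortest_path_length(und, i)
    if len(dists) <= 1:
        s, c = float(n), 0.0
    else:
        s = sum(dists.values()) / (len(dists) - 1)
        c = 1.0 / s
    p = nx.pagerank(g, alpha=cfg.pagerank_damping)[i] if g.number_of_edges() else 1 / n
    be = nx.betweenness_centrality(und, normalized=True)[i]
    linked = und.has_edge(i, j)
    base = coeffs.lam * s + coeffs.rho * p + coeffs.theta * c + coeffs.omega * be
    if linked:
        base += coeffs.alpha * attrs.distance(i, j) + coeffs.beta * attrs.birth_diff(i, j)
    return base


def oracle_is_stable(g, attrs, coeffs, cfg):
    for i, j in itertools.combinations(sorted(g.nodes), 2):
        linked = g.has_edge(i, j) or g.has_edge(j, i)
        if linked:
            h = g.copy()
            h.remove_edges_from([(i, j), (j, i)])
            di = oracle_node_utility(h, attrs, coeffs, i, j, cfg) - \
                oracle_node_utility(g, attrs, coeffs, i, j, cfg)
            dj = oracle_node_utility(h, attrs, coeffs, j, i, cfg) - \
                oracle_node_utility(g, attrs, coeffs, j, i, cfg)
            if max(di, dj) > cfg.tol:
                return False
        else:
            h = g.copy()
            h.add_edges_from(_pair_direction(i, j, cfg))
            gi = oracle_node_utility(h, attrs, coeffs, i, j, cfg) - \
                oracle_node_utility(g, attrs, coeffs, i, j, cfg)
            gj = oracle_node_utility(h, attrs, coeffs, j, i, cfg) - \
                oracle_node_utility(g, attrs, coeffs, j, i, cfg)
            if (gi > cfg.tol and gj >= -cfg.tol) or (gj > cfg.tol and gi >= -cfg.tol):
                return False
    return True


class TestIsPairwiseStable:
    def test_zero_coefficients_always_stable(self):
        g = nx.gnp_random_graph(8, 0.3, seed=1, directed=True)
        attrs = make_attrs(list(g.nodes), [(i, 0, 0) for i in g.nodes],
                           [0.0] * 8)
        assert is_pairwise_stable(g, attrs, ZERO).stable

    def test_two_nodes_distance_only(self, two_node_attrs):
        coeffs = UtilityCoefficients(-1, 0, 0, 0, 0, 0)
        unlinked = nx.DiGraph()
        unlinked.add_nodes_from(["a", "b"])
        assert is_pairwise_stable(unlinked, two_node_attrs, coeffs).stable
        linked = nx.DiGraph([("a", "b")])
        rep = is_pairwise_stable(linked, two_node_attrs, coeffs)
        assert not rep.stable
        (pair, kind, gi, gj), = rep.violations
        assert kind == "delete" and gi == pytest.approx(1.0)

    def test_agrees_with_bruteforce_oracle_on_random_instances(self):
        """200 seeded random attributed digraphs (n<=6), random coefficients:
        verdict must match exhaustive single-deviation enumeration."""
        cfg = GameConfig()
        rng = np.random.default_rng(20240917)
        agree = 0
        for trial in range(200):
            n = int(rng.integers(2, 7))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.9)),
                                    seed=int(rng.integers(2**31)), directed=True)
            g = nx.relabel_nodes(g, {k: f"v{k}" for k in range(n)})
            attrs = make_attrs(
                sorted(g.nodes),
                rng.uniform(0, 2, size=(n, 3)).tolist(),
                rng.uniform(0, 2, size=n).tolist(),
            )
            coeffs = UtilityCoefficients(*rng.uniform(-1, 1, size=6))
            verdict = is_pairwise_stable(g, attrs, coeffs, cfg).stable
            agree += verdict == oracle_is_stable(g, attrs, coeffs, cfg)
        assert agree == 200


class TestMapNodesByDegree:
    def test_identity_on_same_graph(self):
        g = nx.gnp_random_graph(10, 0.3, seed=2, directed=True)
        mapping = map_nodes_by_degree(g, g)
        totals = {v: g.in_degree(v) + g.out_degree(v) for v in g}
        assert all(totals[a] == totals[b] for a, b in mapping.items())

    def test_rank_pairing_example(self):
        base = nx.DiGraph()
        base.add_nodes_from("abc")
        base.add_edges_from([("a", "b"), ("b", "c"), ("c", "b")])
        # totals: a1 b3 c2
        ref = nx.DiGraph()
        ref.add_nodes_from("xyz")
        ref.add_edges_from(
            [("x", "y"), ("x", "z"), ("y", "x"), ("z", "x"), ("z", "y"),
             ("y", "z"), ("x", "y")]
        )
        totals_ref = {v: ref.in_degree(v) + ref.out_degree(v) for v in ref}
        mapping = map_nodes_by_degree(base, ref)
        ranked_ref = sorted(ref.nodes, key=lambda v: (totals_ref[v], v))
        assert [mapping[v] for v in ("a", "c", "b")] == ranked_ref

    def test_all_equal_degrees_pair_lexicographically(self):
        base = nx.DiGraph()
        base.add_nodes_from(["b2", "b1", "b3"])
        ref = nx.DiGraph()
        ref.add_nodes_from(["r3", "r1", "r2"])
        mapping = map_nodes_by_degree(base, ref)
        assert mapping == {"b1": "r1", "b2": "r2", "b3": "r3"}

    def test_unequal_sizes_raise(self):
        g1 = nx.DiGraph()
        g1.add_nodes_from("ab")
        g2 = nx.DiGraph()
        g2.add_nodes_from("abc")
        with pytest.raises(ValueError):
            map_nodes_by_degree(g1, g2)

    def test_transfer_reindexes_attributes(self, square_attrs):
        base = nx.DiGraph()
        base.add_nodes_from(["w", "x", "y", "z"])
        ref = nx.DiGraph()
        ref.add_nodes_from(square_attrs.ids)
        mapping = map_nodes_by_degree(base, ref)
        moved = transfer_attributes(mapping, square_attrs)
        assert set(moved.ids) == {"w", "x", "y", "z"}
        for b, r in mapping.items():
            assert moved.birth_time(b) == square_attrs.birth_time(r)


class TestEvolve:
    def test_stable_input_is_fixed_point(self, two_node_attrs):
        coeffs = UtilityCoefficients(-1, 0, 0, 0, 0, 0)
        g = nx.DiGraph()
        g.add_nodes_from(["a", "b"])
        res = evolve(g, two_node_attrs, coeffs, seed=1)
        assert res.converged and not res.moves
        assert set(res.graph.edges) == set()

    def test_distant_triangle_empties(self):
        attrs = make_attrs(["a", "b", "c"],
                           [(0, 0, 0), (100, 0, 0), (0, 100, 0)],
                           [0, 0, 0])
        g = nx.DiGraph(itertools.permutations("abc", 2))
        res = evolve(g, attrs, UtilityCoefficients(-1, 0, 0, 0, 0, 0), seed=2)
        assert res.converged and res.graph.number_of_edges() == 0
        assert all(m.action == "D" for m in res.moves)

    def test_zero_coefficients_leave_graph_unchanged(self):
        g = nx.gnp_random_graph(9, 0.3, seed=5, directed=True)
        attrs = make_attrs(list(g.nodes), [(i, i, 0) for i in g.nodes],
                           list(range(9)))
        res = evolve(g, attrs, ZERO, seed=3)
        assert res.converged and set(res.graph.edges) == set(g.edges)

    def test_seed_determinism(self, small_synth):
        coeffs = UtilityCoefficients(-1, -0.5, -0.1, 0, -0.25, 0)
        g = nx.gnp_random_graph(12, 0.2, seed=9, directed=True)
        g = nx.relabel_nodes(g, dict(enumerate(sorted(small_synth.ids))))
        r1 = evolve(g, small_synth, coeffs, seed=17)
        r2 = evolve(g, small_synth, coeffs, seed=17)
        assert set(r1.graph.edges) == set(r2.graph.edges)
        assert [m.pair for m in r1.moves] == [m.pair for m in r2.moves]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_converged_runs_are_pairwise_stable(self, seed, small_synth):
        """Fixed-point property on small synthetic instances."""
        coeffs = UtilityCoefficients(-1, -0.5, -0.1, 0, -0.25, 0)
        g = nx.gnp_random_graph(12, 0.25, seed=seed, directed=True)
        g = nx.relabel_nodes(g, dict(enumerate(sorted(small_synth.ids))))
        res = evolve(g, small_synth, coeffs, seed=seed)
        assert res.converged
        assert is_pairwise_stable(res.graph, small_synth, coeffs,
                                  config=res.config).stable


class TestPairDirection:
    def test_coin_is_deterministic_and_covers_both_directions(self):
        cfg = GameConfig(edge_direction="coin", direction_seed=11)
        seen = set()
        for k in range(20):
            (e,) = _pair_direction(f"a{k}", f"b{k}", cfg)
            assert _pair_direction(f"a{k}", f"b{k}", cfg) == [e]
            seen.add(e[0].startswith("a"))
        assert seen == {True, False}

    def test_both_returns_two_arcs(self):
        cfg = GameConfig(edge_direction="both")
        assert len(_pair_direction("a", "b", cfg)) == 2
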