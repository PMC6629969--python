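"""Fully synthetic attributed networks for testing and benchmarking.

Emulates the shape of a small connectome without any download: a
heavy-tailed di-graphical in/out degree sequence (lognormal draws, repaired
to equal sums), soma positions uniform in a bounded box, birth times uniform
or bimodal (a crude stand-in for two neurogenesis waves — a convenience, not
a biological claim), and ground-truth *pairwise-stable* networks obtained by
running the game dynamics to convergence under known coefficients.
Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import game
from .generators import erdos_renyi_directed, havel_hakimi_directed
from .netio import AttributeTable


@dataclass
class SynthConfig:
    """Study conditions for one synthetic connectome.

    Defaults are sized for a small worm-like network: 30 neurons in a
    (50 µm)^3 box with birth times across 800 min of development and a
    lognormal total-degree scale giving mean total degree ~5-6; n=131 with
    lognormal(mu=1.6, sigma=0.6) emulates the frontal-network scale.
    """

    n: int = 30
    volume_um: float = 50.0
    birth_time_range_min: float = 800.0
    birth_time_mode: str = "uniform"  # 'uniform' | 'bimodal'
    degree_mu: float = 1.0
    degree_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.birth_time_mode not in ("uniform", "bimodal"):
            raise ValueError("birth_time_mode must be 'uniform' or 'bimodal'")


def _node_ids(n: int) -> list[str]:
    width = len(str(max(n - 1, 0)))
    return [f"n{str(k).zfill(width)}" for k in range(n)]


def synth_attributes(config: SynthConfig) -> AttributeTable:
    """Positions uniform in the box; birth times uniform or a 2-component
    mixture (early wave in the first 25% of the range, late wave in the
    last 35%, 60/40 split)."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    ids = _node_ids(n)
    pos = rng.uniform(0.0, config.volume_um, size=(n, 3))
    span = config.birth_time_range_min
    if config.birth_time_mode == "uniform":
        bt = rng.uniform(0.0, span, size=n)
    else:
        early = rng.random(n) < 0.6
        bt = np.where(
            early,
            rng.uniform(0.0, 0.25 * span, size=n),
            rng.uniform(0.65 * span, span, size=n),
        )
    frame = pd.DataFrame(
        {
            "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
            "birth_time_min": bt,
        },
        index=pd.Index(ids, name="neuron_id"),
    )
    return AttributeTable(frame)


def synth_degree_sequences(config: SynthConfig) -> tuple[list[int], list[int]]:
    """Draw a heavy-tailed di-graphical (in, out) degree pair per node.

    Lognormal draws are clipped to [0, n-1]; the two sums are then equalized
    by seeded unit increments/decrements so the pair is realizable.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n
    cap = max(n - 1, 0)

    def draw():
        d = rng.lognormal(config.degree_mu, config.degree_sigma, size=n)
        return np.clip(np.rint(d).astype(int), 0, cap)

    din, dout = draw(), draw()
    # repair: move the larger sum down / smaller sum up one unit at a time
    guard = 0
    while din.sum() != dout.sum():
        if din.sum() > dout.sum():
            k = rng.integers(n)
            if dout[k] < cap:
                dout[k] += 1
            else:
                j = rng.integers(n)
                if din[j] > 0:
                    din[j] -= 1
        else:
            k = rng.integers(n)
            if din[k] < cap:
                din[k] += 1
            else:
                j = rng.integers(n)
                if dout[j] > 0:
                    dout[j] -= 1
        guard += 1
        if guard > 100 * n + 100:
            raise RuntimeError("degree-sequence repair did not terminate")
    return din.tolist(), dout.tolist()


def synth_reference_network(config: SynthConfig) -> tuple[nx.DiGraph, AttributeTable]:
    """Heavy-tailed reference digraph (via directed Havel-Hakimi) plus its
    attribute table, on shared node ids."""
    attrs = synth_attributes(config)
    din, dout = synth_degree_sequences(config)
    g = havel_hakimi_directed(din, dout, seed=config.seed + 2, ids=_node_ids(config.n))
    return g, attrs


@dataclass
class InitSpec:
    """Starting graph for the stable-network construction."""

    kind: str = "sparse_random"  # 'sparse_random' | 'empty' | 'reference'
    edge_p: float = 0.12
    graph: nx.DiGraph | None = field(default=None, repr=False)


def synth_stable_network(attrs: AttributeTable, true_coeffs: game.UtilityCoefficients,
                         init_spec: InitSpec | None = None, seed: int = 0,
                         config: game.GameConfig | None = None) -> nx.DiGraph:
    """A network pairwise stable under *true_coeffs*, for recovery tests.

    Starts from the init graph (default: sparse Erdos-Renyi digraph on the
    attribute table's nodes) and runs the game dynamics to convergence.
    Non-convergence raises — fixtures must be bona fide equilibria; callers
    retry with another seed.
    """
    spec = init_spec or InitSpec()
    ids = attrs.ids
    if spec.kind == "sparse_random":
        base = erdos_renyi_directed(len(ids), spec.edge_p, seed=seed)
        base = nx.relabel_nodes(base, dict(enumerate(sorted(ids))))
    elif spec.kind == "empty":
        base = nx.DiGraph()
        base.add_nodes_from(ids)
    elif spec.kind == "reference":
        if spec.graph is None:
            raise ValueError("init_spec.kind='reference' needs init_spec.graph")
        base = spec.graph.copy()
    else:
        raise ValueError(f"unknown init kind {spec.kind!r}")
    result = game.evolve(base, attrs, true_coeffs, config=config, seed=seed)
    if not result.converged:
        raise RuntimeError(
            f"dynamics did not converge within {result.config.max_sweeps} sweeps; "
            "retry with another seed"
        )
    return result.graph
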