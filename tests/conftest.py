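import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netgame import AttributeTable, SynthConfig, synth_attributes


@pytest.fixture
def square_attrs():
    """Four neurons on the corners of a unit square (z=0), staggered births."""
    frame = pd.DataFrame(
        {
            "x_um": [0.0, 1.0, 1.0, 0.0],
            "y_um": [0.0, 0.0, 1.0, 1.0],
            "z_um": [0.0, 0.0, 0.0, 0.0],
            "birth_time_min": [0.0, 10.0, 20.0, 30.0],
        },
        index=pd.Index(["a", "b", "c", "d"], name="neuron_id"),
    )
    return AttributeTable(frame)


@pytest.fixture
def two_node_attrs():
    frame = pd.DataFrame(
        {
            "x_um": [0.0, 1.0],
            "y_um": [0.0, 0.0],
            "z_um": [0.0, 0.0],
            "birth_time_min": [5.0, 5.0],
        },
        index=pd.Index(["a", "b"], name="neuron_id"),
    )
    return AttributeTable(frame)


@pytest.fixture
def small_synth():
    """12-neuron synthetic attributed network, unit-scaled features."""
    cfg = SynthConfig(n=12, seed=42)
    return synth_attributes(cfg).unit_scaled()


def random_attrs(n, seed):
    cfg = SynthConfig(n=n, seed=seed)
    return synth_attributes(cfg).unit_scaled()


def random_digraph(n, p, seed, ids):
    g = nx.gnp_random_graph(n, p, seed=seed, directed=True)
    return nx.relabel_nodes(g, dict(enumerate(ids)))
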