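import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import diffembed as de

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


def weighted_graph_from_edges(edges):
    """Small WeightedPPINetwork from (u, v, weight) triples."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w), raw_weight=float(w))
    return de.WeightedPPINetwork(graph=g, condition_label="toy")


@pytest.fixture
def two_node_network():
    return weighted_graph_from_edges([("a", "b", 0.7)])


@pytest.fixture
def small_scenario():
    return de.SyntheticScenario(
        n_genes=60, graph_model="scale_free", attachment_or_density=2, seed=11
    )


@pytest.fixture
def small_count_matrix(small_scenario):
    graph, _, _ = de.generate_graph(small_scenario)
    control, disease = de.generate_counts(small_scenario, graph)
    counts = pd.concat([control, disease], axis=1)
    groups = pd.Series(
        {**{s: "control" for s in control.columns},
         **{s: "disease" for s in disease.columns}}
    )
    return de.CountMatrix(counts=counts, group_of=groups), graph


def random_weighted_graph(n, rng, p=0.3):
    """Random connected-ish weighted graph for numerical oracle checks."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    net = nx.Graph()
    net.add_nodes_from(f"n{i}" for i in range(n))
    for u, v in g.edges:
        net.add_edge(f"n{u}", f"n{v}", weight=float(rng.uniform(0.05, 2.0)))
    return de.WeightedPPINetwork(graph=net, condition_label="rand")
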