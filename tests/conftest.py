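import numpy as np
import pytest

from carecov.synthetic.city import CitySpec, gen_providers, gen_road_network
from carecov.accessibility import build_travel_time_graph


@pytest.fixture(scope="session")
def small_city():
    """10x10 single-class grid city with a handful of providers."""
    spec = CitySpec(
        grid_rows=10, grid_cols=10, cell_length=100.0,
        road_class_mix={"residential": 1.0}, speed_table={"residential": 30.0},
        n_bpjs_providers=6, n_nonbpjs_providers=5, n_households=500, seed=11,
    )
    roads = gen_road_network(spec)
    providers = gen_providers(roads, spec)
    graph = build_travel_time_graph(roads, spec.speed_table)
    return spec, roads, providers, graph


@pytest.fixture(scope="session")
def survey_2000():
    """2000 respondents from the default DGPs (shared; treat as read-only)."""
    from carecov.synthetic.survey import gen_respondents

    return gen_respondents(2000, seed=101)


def random_travel_graph(rng: np.random.Generator, n_nodes: int):
    """Small random connected travel graph for shortest-path oracles."""
    import networkx as nx

    from carecov.accessibility import TravelGraph, edge_minutes

    pts = rng.uniform(0, 1000, size=(n_nodes, 2))
    g = nx.Graph()
    nodes = [tuple(np.round(p, 1)) for p in pts]
    for nd in nodes:
        g.add_node(nd, xy=nd)
    # random spanning tree plus extra edges
    order = rng.permutation(n_nodes)
    for i in range(1, n_nodes):
        a, b = nodes[order[i - 1]], nodes[order[i]]
        _add_edge(g, a, b, rng)
    for _ in range(n_nodes):
        i, j = rng.integers(0, n_nodes, 2)
        if i != j and not g.has_edge(nodes[i], nodes[j]):
            _add_edge(g, nodes[i], nodes[j], rng)
    return TravelGraph(graph=g, n_components=1)


def _add_edge(g, a, b, rng):
    from carecov.accessibility import edge_minutes

    length = float(np.hypot(a[0] - b[0], a[1] - b[1])) + 1.0
    speed = float(rng.uniform(10, 50))
    g.add_edge(a, b, length=length, road_class="x", speed=speed,
               time=edge_minutes(length, speed), geometry=None)
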