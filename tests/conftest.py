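import pytest

import bionet as bn


@pytest.fixture()
def simple_registries():
    nt = bn.NodeTypeRegistry.of("Gene", "Protein", "Phenotype")
    et = bn.EdgeTypeRegistry.of(
        ("codes_for", "coded_by"), "interacts_with", ("affects", "affected_by")
    )
    return nt, et


@pytest.fixture()
def plain_graph_factory():
    """Untyped-feeling single-type graphs for proximity tests."""
    nt = bn.NodeTypeRegistry.of("N")
    et = bn.EdgeTypeRegistry.of("link")

    def build(edges, weights=None, cap=True):
        g = bn.HeteroGraph(nt, et)
        for u, v, *rest in edges:
            if u not in g:
                g.add_node(u, "N")
            if v not in g:
                g.add_node(v, "N")
            g.add_edge(u, v, "link", rest[0] if rest else 1.0)
        if weights is None:
            w = {e: e.reliability for e in g.edges()}
        else:
            w = {e: weights[frozenset((e.source, e.target))] for e in g.edges()}
        return bn.WeightedGraph(g, w, cap=cap)

    return build


@pytest.fixture()
def three_edge_graph(plain_graph_factory):
    """Direct s-t edge of prob 0.5 plus an independent s-a-t path of 0.5/0.5.

    Exact reliability 1 - 0.5*(1 - 0.25) = 0.625; exact ERD
    (0.5*1 + 0.125*2)/0.625 = 1.2.
    """
    return plain_graph_factory([("s", "t", 0.5), ("s", "a", 0.5), ("a", "t", 0.5)])


def random_weighted_graph(rng, n_nodes, n_edges, cap=True, wmin=0.05, wmax=0.95):
    """Random connected-ish weighted graph for oracle comparisons."""
    nt = bn.NodeTypeRegistry.of("N")
    et = bn.EdgeTypeRegistry.of("link")
    g = bn.HeteroGraph(nt, et)
    names = [f"n{i:02d}" for i in range(n_nodes)]
    for n in names:
        g.add_node(n, "N")
    n_edges = min(n_edges, n_nodes * (n_nodes - 1) // 2)
    placed = set()
    while len(placed) < n_edges:
        i, j = rng.choice(n_nodes, size=2, replace=False)
        key = frozenset((names[i], names[j]))
        if key in placed:
            continue
        placed.add(key)
        g.add_edge(names[i], names[j], "link")
    w = {e: float(rng.uniform(wmin, wmax)) for e in g.edges()}
    return bn.WeightedGraph(g, w, cap=cap)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic graph + truth, shared across the session."""
    graph, truth = bn.generate_graph(bn.default_config(seed=0))
    return graph, truth


@pytest.fixture(scope="session")
def default_sim_rw(default_sim):
    graph, truth = default_sim
    wg = bn.apply_weights(graph, bn.WeightingConfig(cap=False))
    return wg, truth
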