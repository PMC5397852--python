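import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from lncprop import (
    CNCNetwork,
    PropagationResult,
    SyntheticSpec,
    generate_cnc,
    restrict_to_components,
)


@pytest.fixture
def toy_ranked():
    """Five-gene ranked list with propagation scores (0.5 ... 0.1)."""
    genes = ["g1", "g2", "g3", "g4", "g5"]
    scores = dict(zip(genes, [0.5, 0.4, 0.3, 0.2, 0.1]))
    return PropagationResult(
        steady_state={g: s**2 for g, s in scores.items()},
        seed_ids=("L1",),
        propagation_scores=scores,
        ranked_list=genes,
    )


@pytest.fixture
def two_node_net():
    return CNCNetwork.from_edges(
        [("A", "B", "coexpression", 1)], {"A": "lncRNA", "B": "coding"}
    )


def coding_chain(n, with_lnc_seed=True):
    """Path network: optional lncRNA seed L followed by coding genes C1..Cn."""
    ids = [f"C{i:04d}" for i in range(1, n + 1)]
    nodes = {g: "coding" for g in ids}
    edges = [(ids[i], ids[i + 1], "ppi", None) for i in range(n - 1)]
    if with_lnc_seed:
        nodes["L"] = "lncRNA"
        edges.insert(0, ("L", ids[0], "coexpression", 1))
    return CNCNetwork.from_edges(edges, nodes)


@pytest.fixture(scope="session")
def synthetic_bundle():
    return generate_cnc(SyntheticSpec(rng_seed=42))


@pytest.fixture(scope="session")
def synthetic_net(synthetic_bundle):
    net, _ = restrict_to_components(synthetic_bundle.network)
    return net


def random_connected_network(rng, max_nodes=50):
    """Random connected mixed-biotype network (spanning tree + extra edges)."""
    import networkx as nx

    n = int(rng.integers(3, max_nodes + 1))
    g = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = rng.integers(0, n, size=2)
        if u != v:
            g.add_edge(int(u), int(v))
    biotypes = {}
    edges = []
    lnc = {0} | {int(x) for x in rng.integers(0, n, size=max(1, n // 5))}
    for node in g.nodes:
        biotypes[f"N{node:03d}"] = "lncRNA" if node in lnc else "coding"
    for u, v in g.edges:
        edges.append((f"N{u:03d}", f"N{v:03d}", "coexpression", 1))
    return CNCNetwork.from_edges(edges, biotypes)


def seed_vector_and_matrix(net, seeds):
    from lncprop.propagation import column_normalize

    M, nodes = column_normalize(net)
    p0 = np.zeros(len(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    for s in seeds:
        p0[idx[s]] = 1.0 / len(seeds)
    return M, nodes, p0
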