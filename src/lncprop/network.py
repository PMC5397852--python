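"""The coding--non-coding (CNC) network: assembly and structural QC.

The CNC network is an undirected graph whose nodes are lncRNAs and
protein-coding genes and whose edges come from consensus co-expression
calls, protein--protein interactions (PPIs), or both.  Edge signs from
co-expression are retained as metadata only: propagation runs on the
unweighted adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .coexpr import BIOTYPES, ConsensusEdge

logger = logging.getLogger(__name__)

__all__ = [
    "CNCNetwork",
    "PowerLawFit",
    "build_network",
    "restrict_to_components",
    "degree_powerlaw_fit",
]

PROVENANCES = ("coexpression", "ppi", "both")


class CNCNetwork:
    """Undirected mixed-biotype graph with per-edge provenance.

    Thin wrapper over a :class:`networkx.Graph` whose nodes carry a
    ``biotype`` attribute (``"lncRNA"`` or ``"coding"``) and whose edges
    carry ``provenance`` (``"coexpression"``, ``"ppi"`` or ``"both"``) and
    an optional co-expression ``sign``.
    """

    def __init__(self, graph: nx.Graph):
        for node, data in graph.nodes(data=True):
            if data.get("biotype") not in BIOTYPES:
                raise ValueError(f"node {node!r} has no valid biotype")
        for u, v, data in graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if data.get("provenance") not in PROVENANCES:
                raise ValueError(f"edge {u!r}-{v!r} has no valid provenance")
        self.graph = graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str, int | None]],
        biotypes: Mapping[str, str],
    ) -> "CNCNetwork":
        """Build from ``(gene_a, gene_b, provenance, sign)`` tuples."""
        g = nx.Graph()
        for a, b, prov, sign in edges:
            for node in (a, b):
                if node not in biotypes:
                    raise ValueError(f"edge endpoint {node!r} has no declared biotype")
                g.add_node(node, biotype=biotypes[node])
            g.add_edge(a, b, provenance=prov, sign=sign)
        return cls(g)

    # -- basic views -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def biotype(self, node: str) -> str:
        return self.graph.nodes[node]["biotype"]

    @property
    def coding_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["biotype"] == "coding"
        )

    @property
    def lncrna_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["biotype"] == "lncRNA"
        )

    def summary_counts(self) -> dict[str, int]:
        """Node counts by biotype and edge counts by provenance."""
        counts = {
            "nodes": self.n_nodes,
            "lncRNA": len(self.lncrna_nodes),
            "coding": len(self.coding_nodes),
            "edges": self.n_edges,
        }
        for prov in PROVENANCES:
            counts[prov] = sum(
                1 for _, _, d in self.graph.edges(data=True)
                if d["provenance"] == prov
            )
        return counts

    def edge_records(self) -> list[tuple[str, str, str, int | None]]:
        """Edges as sorted ``(gene_a, gene_b, provenance, sign)`` tuples."""
        recs = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            recs.append((a, b, d["provenance"], d.get("sign")))
        recs.sort(key=lambda r: (r[0], r[1]))
        return recs


@dataclass(frozen=True)
class PowerLawFit:
    """Log--log least-squares fit of the degree distribution P(k) ~ k^-gamma."""

    gamma: float
    r_squared: float
    degree_histogram: dict[int, int]


def build_network(
    coexpr: Iterable[ConsensusEdge],
    ppi: Iterable[tuple[str, str]],
    node_biotypes: Mapping[str, str],
) -> CNCNetwork:
    """Merge consensus co-expression edges with PPI pairs into a CNC network.

    Every co-expression endpoint must have a declared biotype; PPI nodes
    missing from ``node_biotypes`` default to ``"coding"``.  A declared
    lncRNA appearing in a PPI edge is an error (PPIs connect proteins).
    Pairs present in both sources are tagged ``"both"``; isolated declared
    nodes are not materialised (only edge endpoints enter the graph).
    """
    coexpr_pairs: dict[tuple[str, str], int] = {}
    for e in coexpr:
        coexpr_pairs[e.pair] = e.sign
    ppi_pairs: set[tuple[str, str]] = set()
    for a, b in ppi:
        if a == b:
            raise ValueError(f"self-loop in PPI input on node {a!r}")
        ppi_pairs.add((a, b) if a < b else (b, a))

    biotypes = dict(node_biotypes)
    for a, b in ppi_pairs:
        for node in (a, b):
            bt = biotypes.setdefault(node, "coding")
            if bt == "lncRNA":
                raise ValueError(
                    f"lncRNA node {node!r} appears in a PPI edge; "
                    "PPIs connect proteins"
                )

    edges = []
    for pair, sign in coexpr_pairs.items():
        prov = "both" if pair in ppi_pairs else "coexpression"
        edges.append((pair[0], pair[1], prov, sign))
    for pair in ppi_pairs - set(coexpr_pairs):
        edges.append((pair[0], pair[1], "ppi", None))

    net = CNCNetwork.from_edges(edges, biotypes)
    logger.info("built CNC network: %s", net.summary_counts())
    return net


def restrict_to_components(
    net: CNCNetwork,
) -> tuple[CNCNetwork, dict[str, int]]:
    """Drop zero-degree nodes and label connected components.

    Returns the restricted network and a node -> component-label map;
    components are numbered by decreasing size (0 = largest), ties broken
    by smallest member id.  Raises on an empty network.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    g = net.graph.copy()
    g.remove_nodes_from([n for n, d in g.degree() if d == 0])
    if g.number_of_nodes() == 0:
        raise ValueError("network has no edges")
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    labels = {node: i for i, comp in enumerate(comps) for node in comp}
    logger.info(
        "%d connected component(s); largest has %d nodes",
        len(comps), len(comps[0]),
    )
    return CNCNetwork(g), labels


def degree_powerlaw_fit(net: CNCNetwork) -> PowerLawFit:
    """Least-squares power-law fit of the empirical degree distribution.

    Fits a line to (log k, log P(k)) over degrees with nonzero empirical
    frequency; ``gamma`` is the negative slope and ``r_squared`` the
    coefficient of determination of the same regression.  Scale-free
    networks give a good linear fit; the CNC construction is expected to
    produce one.
    """
    degrees = [d for _, d in net.graph.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    support = sorted(k for k in hist if k > 0)
    if len(support) < 2:
        raise ValueError(
            "degree distribution has fewer than 2 distinct degrees; "
            "power-law fit is undefined"
        )
    total = sum(hist[k] for k in support)
    x = np.log(np.array(support, dtype=float))
    y = np.log(np.array([hist[k] / total for k in support]))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(gamma=float(-slope), r_squared=r2, degree_histogram=hist)
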