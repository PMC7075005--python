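"""One-mode projection of the target-pathway map into the TPT network.

Two targets are joined by an edge iff they share at least one pathway; the
edge carries the exact set of shared pathways as its ``pathways`` attribute.
Edges are unweighted (length 1) at baseline — all reweighting happens in the
knockout-perturbation engine.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, FrozenSet, Set, Tuple

import networkx as nx

from .data_model import BipartiteMap


def project(bmap: BipartiteMap) -> nx.Graph:
    """Build the targets-pathways-targets graph from the bipartite map.

    The node set is every target belonging to at least one pathway (targets
    without pathway annotation drop out of the network). Equivalent to the
    union over pathways of the clique on the pathway's members, each edge
    annotated with the set of pathways whose cliques cover it.
    """
    shared: Dict[Tuple[str, str], Set[str]] = {}
    graph = nx.Graph()
    graph.add_nodes_from(bmap.targets)
    for pathway in bmap.pathways:
        for u, v in combinations(sorted(bmap.members(pathway)), 2):
            shared.setdefault((u, v), set()).add(pathway)
    for (u, v), pathways in shared.items():
        graph.add_edge(u, v, pathways=frozenset(pathways))
    return graph


def edge_pathways(graph: nx.Graph, u: str, v: str) -> FrozenSet[str]:
    """The set of pathways shared by the two endpoints of an edge."""
    return graph.edges[u, v]["pathways"]


def graph_stats(graph: nx.Graph) -> Tuple[int, int, int]:
    """(node count, edge count, connected-component count)."""
    return (
        graph.number_of_nodes(),
        graph.number_of_edges(),
        nx.number_connected_components(graph),
    )
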