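"""Knockout-perturbation engine: the network-efficiency-decrease (NED) score.

The model: a target T_i is assumed undruggable ("set off"). Every pathway j
containing it, with N_j member targets, loses one member's worth of efficacy
and drops to PE = (N_j - 1) / N_j; unaffected pathways keep efficacy 1.
A TPT edge carrying t affected pathways has edge efficacy EE equal to the
product of their PEs, and its length grows from 1 to 1/EE. Network
efficiency NE is the sum over unordered node pairs of the reciprocal
shortest-path length, and NED_i = NE_0 - NE_i measures the influence of the
knocked-out target on global network integrity. Efficacies are kept as exact
fractions internally; percentages shown to users round to the nearest
integer (2/3 -> 67%).
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .data_model import BipartiteMap, EdgeState, PerturbationResult

Edge = Tuple[str, str]

ONE = Fraction(1)


def pathway_efficacy(pathway_size: int, is_member: bool) -> Fraction:
    """PE = (N_j - 1)/N_j if the knocked target is a member, else 1."""
    if pathway_size < 1:
        raise ValueError(f"pathway size must be >= 1, got {pathway_size}")
    if not is_member:
        return ONE
    return Fraction(pathway_size - 1, pathway_size)


def edge_efficacy(
    edge_pathway_sizes: Sequence[int], knocked_member_flags: Sequence[bool]
) -> Tuple[Fraction, Fraction]:
    """(EE, L) for one edge: EE = product of affected-pathway PEs, L = 1/EE.

    An edge none of whose pathways contain the knocked target keeps
    EE = 1, L = 1. Pathway sizes on an edge are >= 2 by construction, so
    EE > 0; a zero efficacy is guarded by returning infinite length.
    """
    if len(edge_pathway_sizes) != len(knocked_member_flags):
        raise ValueError("size and membership lists must be aligned")
    ee = ONE
    for n, member in zip(edge_pathway_sizes, knocked_member_flags):
        ee *= pathway_efficacy(n, member)
    if ee == 0:
        return ee, Fraction(0)  # caller treats the edge as absent
    return ee, 1 / ee


def _length_matrix(
    graph: nx.Graph,
    nodes: Sequence[str],
    lengths: Optional[Mapping[Edge, Fraction]] = None,
) -> csr_array:
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v in graph.edges():
        w = 1.0
        if lengths is not None:
            w = lengths.get((u, v), lengths.get((v, u), 1))
            if w == 0:
                continue  # zero-efficacy guard: edge treated as absent
            w = float(w)
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    n = len(nodes)
    return csr_array((vals, (rows, cols)), shape=(n, n))


def shortest_path_matrix(
    graph: nx.Graph, lengths: Optional[Mapping[Edge, Fraction]] = None
) -> pd.DataFrame:
    """All-pairs shortest-path lengths (Dijkstra); inf for unreachable pairs."""
    nodes = sorted(graph.nodes())
    if not nodes:
        return pd.DataFrame()
    dist = dijkstra(_length_matrix(graph, nodes, lengths), directed=False)
    return pd.DataFrame(dist, index=nodes, columns=nodes)


def network_efficiency(
    graph: nx.Graph, lengths: Optional[Mapping[Edge, Fraction]] = None
) -> float:
    """NE = sum over unordered node pairs of 1/d_mn.

    d_mn are weighted shortest-path lengths (unit lengths by default);
    unreachable pairs contribute zero.
    """
    nodes = sorted(graph.nodes())
    if len(nodes) < 2:
        return 0.0
    dist = dijkstra(_length_matrix(graph, nodes, lengths), directed=False)
    iu = np.triu_indices(len(nodes), k=1)
    d = dist[iu]
    finite = np.isfinite(d) & (d > 0)
    return float(np.sum(1.0 / d[finite]))


def perturbed_lengths(
    graph: nx.Graph, bmap: BipartiteMap, target: str
) -> Tuple[Dict[str, Fraction], Dict[Edge, EdgeState]]:
    """Pathway efficacies and per-edge states after knocking out ``target``."""
    pe = {
        p: pathway_efficacy(bmap.pathway_size(p), target in bmap.members(p))
        for p in bmap.pathways
    }
    states: Dict[Edge, EdgeState] = {}
    for u, v, data in graph.edges(data=True):
        pathways = data["pathways"]
        affected = [p for p in pathways if pe[p] != 1]
        ee = ONE
        for p in affected:
            ee *= pe[p]
        length = 1 / ee if ee != 0 else Fraction(0)
        states[(u, v)] = EdgeState(
            n_affected=len(affected), efficacy=ee, length=length
        )
    return pe, states


def knockout(
    graph: nx.Graph,
    bmap: BipartiteMap,
    target: str,
    ne_baseline: Optional[float] = None,
) -> PerturbationResult:
    """Set off one target and measure the network-efficiency decrease.

    The knocked node is retained; only edge lengths change. ``ne_baseline``
    (NE_0 on the same graph at unit lengths) is computed if not supplied.
    """
    if target not in graph:
        raise KeyError(f"target {target!r} is not a node of the TPT network")
    if ne_baseline is None:
        ne_baseline = network_efficiency(graph)
    pe, states = perturbed_lengths(graph, bmap, target)
    lengths = {edge: s.length for edge, s in states.items()}
    ne_i = network_efficiency(graph, lengths)
    return PerturbationResult(
        knocked_target=target,
        pathway_efficacies=pe,
        edge_states=states,
        ne_baseline=ne_baseline,
        ne_perturbed=ne_i,
        ned=ne_baseline - ne_i,
    )


def rank_all(graph: nx.Graph, bmap: BipartiteMap) -> List[PerturbationResult]:
    """Knock out every target in turn; rank by descending NED.

    NE_0 is computed once and shared. Ties break by ascending target id so
    the ranking is deterministic.
    """
    ne0 = network_efficiency(graph)
    results = [knockout(graph, bmap, t, ne_baseline=ne0) for t in sorted(graph.nodes())]
    results.sort(key=lambda r: (-r.ned, r.knocked_target))
    return results


def top_fraction(
    ranked: Sequence[PerturbationResult], fraction: float = 0.10
) -> List[PerturbationResult]:
    """The top ceil(fraction * n) entries of a ranking (main targets)."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not ranked:
        return []
    k = math.ceil(fraction * len(ranked))
    return list(ranked[:k])


def ranking_table(ranked: Sequence[PerturbationResult], fraction: float = 0.10) -> pd.DataFrame:
    """Tabulate a ranking: target, NE_i, NED, rank, main-target flag."""
    main = {r.knocked_target for r in top_fraction(ranked, fraction)} if ranked else set()
    return pd.DataFrame(
        {
            "target": [r.knocked_target for r in ranked],
            "ne_i": [r.ne_perturbed for r in ranked],
            "ned": [r.ned for r in ranked],
            "rank": range(1, len(ranked) + 1),
            "is_main_target": [r.knocked_target in main for r in ranked],
        }
    )
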