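"""Centrality baselines and the Spearman literature-co-occurrence validation.

Degree centrality (raw degree) and unnormalized Brandes betweenness are the
two classical scores the knockout ranking is compared against. Validation
correlates each score with literature co-occurrence counts using Spearman's
rank test (mid-ranks for ties, two-tailed p from the t approximation with
n - 2 degrees of freedom); an exact permutation p is available for small
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def degree_centrality(graph: nx.Graph) -> Dict[str, int]:
    """Raw degree (number of incident edges) per node."""
    return {n: int(d) for n, d in graph.degree()}


def betweenness_centrality(graph: nx.Graph) -> Dict[str, float]:
    """Unnormalized shortest-path betweenness on the unit-length graph.

    Equal-length shortest paths share credit fractionally (Brandes
    semantics); each unordered pair is counted once.
    """
    return nx.betweenness_centrality(graph, normalized=False)


def centrality_table(graph: nx.Graph) -> pd.DataFrame:
    dc = degree_centrality(graph)
    bc = betweenness_centrality(graph)
    nodes = sorted(graph.nodes())
    return pd.DataFrame(
        {"target": nodes, "dc": [dc[n] for n in nodes], "bc": [bc[n] for n in nodes]}
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    flagged: bool = False  # constant input: correlation undefined

    def __iter__(self):
        return iter((self.rho, self.p_value))


def spearman_test(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> SpearmanResult:
    """Spearman rank correlation with a two-tailed p-value.

    rho is the Pearson correlation of mid-ranks; p comes from the
    t approximation with n - 2 degrees of freedom, or, with ``exact=True``
    (n <= 8 only), from full enumeration of the permutation distribution.
    Constant x or y yields a flagged result with NaN statistics rather than
    an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(math.nan, math.nan, flagged=True)
    if exact:
        if n > 8:
            raise ValueError("exact permutation p-value supported only for n <= 8")
        return _exact_spearman(x, y)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p))


def _mid_rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_spearman(x: np.ndarray, y: np.ndarray) -> SpearmanResult:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = _mid_rank_rho(rx, ry)
    hits = total = 0
    for perm in permutations(range(len(x))):
        r = _mid_rank_rho(rx, ry[list(perm)])
        total += 1
        if abs(r) >= abs(observed) - 1e-12:
            hits += 1
    return SpearmanResult(observed, hits / total)


_SCORE_COLUMNS = ("ned", "dc", "bc")
_COUNT_COLUMNS = ("fulltext_count", "abstract_count")


def validate(table: pd.DataFrame, exact: bool = False) -> Dict[str, Dict[str, SpearmanResult]]:
    """Correlate each score (NED, DC, BC) with each co-occurrence count.

    ``table`` needs columns ned, dc, bc, fulltext_count, abstract_count and
    at least 3 complete rows. Returns {score: {count column: result}} — six
    (rho, p) pairs in total.
    """
    missing = [c for c in (*_SCORE_COLUMNS, *_COUNT_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"validation table is missing columns: {', '.join(missing)}")
    if table[list(_SCORE_COLUMNS) + list(_COUNT_COLUMNS)].isna().any().any():
        raise ValueError("validation table has missing values")
    if len(table) < 3:
        raise ValueError(
            f"Spearman validation needs at least 3 targets, got {len(table)}"
        )
    return {
        score: {
            counts: spearman_test(table[score], table[counts], exact=exact)
            for counts in _COUNT_COLUMNS
        }
        for score in _SCORE_COLUMNS
    }
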