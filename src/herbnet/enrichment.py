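"""Pathway over-representation analysis for a predicted-target set.

One-sided hypergeometric upper-tail test per pathway, Benjamini-Hochberg
control of the false discovery rate, and the q < alpha (default 0.05)
retention rule. The universe defaults to every target appearing in the
annotation; pathway sets are intersected with the universe before testing.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Set

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_model import BipartiteMap, EnrichmentResult
from .errors import ConfigError


def hypergeometric_p(k: int, K: int, n_query: int, N_universe: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N_universe, K, n_query).

    k is the observed overlap between a query of size n_query and a pathway
    annotated to K of the N_universe genes.
    """
    if not (0 <= k <= min(K, n_query)):
        raise ValueError(
            f"impossible overlap k={k} for K={K}, n_query={n_query}"
        )
    if K > N_universe or n_query > N_universe:
        raise ValueError("pathway or query larger than the universe")
    # sf(k-1) = P(X >= k); exact for k = 0 (probability 1).
    p = float(hypergeom.sf(k - 1, N_universe, K, n_query))
    return min(max(p, 5e-324), 1.0)


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    ps = list(p_values)
    if not ps:
        return []
    if any(not (0.0 < p <= 1.0) for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return [float(min(v, 1.0)) for v in q]


def enrich(
    targets: Iterable[str],
    annotation: BipartiteMap,
    universe: Optional[Set[str]] = None,
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Test every overlapping pathway; retain those with q < alpha.

    Returns one :class:`EnrichmentResult` per pathway with overlap k >= 1
    and q below the threshold, sorted by (q, p, pathway_id).
    """
    universe = set(universe) if universe is not None else set(annotation.targets)
    if not universe:
        raise ConfigError("enrichment universe is empty")
    query = set(targets) & universe
    if set(targets) - universe:
        missing = sorted(set(targets) - universe)[:5]
        raise ConfigError(
            f"query targets outside the universe (e.g. {', '.join(missing)})"
        )

    rows = []
    for pathway in sorted(annotation.pathways):
        members = annotation.members(pathway) & universe
        k = len(query & members)
        if k >= 1:
            p = hypergeometric_p(k, len(members), len(query), len(universe))
            rows.append((pathway, k, len(members), p))
    if not rows:
        return []
    qs = bh_fdr([p for _, _, _, p in rows])
    results = [
        EnrichmentResult(
            pathway_id=pathway,
            overlap=k,
            pathway_size=K,
            query_size=len(query),
            universe_size=len(universe),
            p_value=p,
            q_value=q,
            pathway_name=annotation.pathway_name(pathway),
        )
        for (pathway, k, K, p), q in zip(rows, qs)
        if q < alpha
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.pathway_id))
    return results
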