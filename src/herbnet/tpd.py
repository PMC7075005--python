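"""Directed targets-pathways-diseases (TPD) network and indegree analysis.

Edges run main-target -> pathway (membership) and pathway -> ICD-11 disease
class (annotation table), so the graph is a three-layer DAG. A pathway's
indegree counts the distinct main targets acting through it; a disease's
indegree counts the distinct pathways leading to it. Main pathways and
diseases are those with indegree strictly above a threshold (defaults 10
and 20).
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Tuple

import networkx as nx
import pandas as pd

from .data_model import BipartiteMap

PATHWAY_INDEGREE_DEFAULT = 10
DISEASE_INDEGREE_DEFAULT = 20


def build_tpd(
    main_targets: Iterable[str],
    bmap: BipartiteMap,
    disease_map: pd.DataFrame,
) -> nx.DiGraph:
    """Assemble the tripartite directed graph for a main-target set.

    ``disease_map`` has columns pathway_id, icd11_class_code and optionally
    icd11_class_name. Only pathways reached by at least one main target get
    disease edges; rows naming unknown pathways are skipped with a warning.
    Duplicate (pathway, disease) rows collapse to one edge.
    """
    main_targets = set(main_targets)
    unknown = main_targets - bmap.targets
    if unknown:
        raise KeyError(
            f"main targets absent from the annotation: {', '.join(sorted(unknown))}"
        )
    g = nx.DiGraph()
    for t in main_targets:
        g.add_node(t, category="target")
        for p in bmap.pathways_of(t):
            g.add_node(p, category="pathway")
            g.add_edge(t, p)

    reached = {n for n, d in g.nodes(data=True) if d.get("category") == "pathway"}
    has_names = "icd11_class_name" in disease_map.columns
    for _, row in disease_map.iterrows():
        p = row["pathway_id"]
        if p not in bmap.pathways:
            warnings.warn(
                f"disease mapping references unknown pathway {p!r}; row skipped",
                stacklevel=2,
            )
            continue
        if p not in reached:
            continue
        code = row["icd11_class_code"]
        name = row["icd11_class_name"] if has_names else code
        g.add_node(code, category="disease", icd11_class_name=name)
        g.add_edge(p, code)
    return g


def _by_category(tpd: nx.DiGraph, category: str) -> List[str]:
    return [n for n, d in tpd.nodes(data=True) if d.get("category") == category]


def _high_indegree(tpd: nx.DiGraph, nodes: List[str], threshold: int) -> List[Tuple[str, int]]:
    kept = [(n, tpd.in_degree(n)) for n in nodes if tpd.in_degree(n) > threshold]
    kept.sort(key=lambda item: (-item[1], item[0]))
    return kept


def main_pathways(
    tpd: nx.DiGraph, threshold: int = PATHWAY_INDEGREE_DEFAULT
) -> List[Tuple[str, int]]:
    """Pathways targeted by strictly more than ``threshold`` main targets."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return _high_indegree(tpd, _by_category(tpd, "pathway"), threshold)


def main_diseases(
    tpd: nx.DiGraph, threshold: int = DISEASE_INDEGREE_DEFAULT
) -> List[Tuple[str, int]]:
    """Disease classes fed by strictly more than ``threshold`` pathways."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return _high_indegree(tpd, _by_category(tpd, "disease"), threshold)


def tpd_summary(tpd: nx.DiGraph) -> pd.DataFrame:
    """Per-node category and indegree, sorted by category then -indegree."""
    rows = [
        {"node": n, "category": d.get("category", ""), "indegree": tpd.in_degree(n)}
        for n, d in tpd.nodes(data=True)
    ]
    df = pd.DataFrame(rows, columns=["node", "category", "indegree"])
    return df.sort_values(
        ["category", "indegree", "node"], ascending=[True, False, True]
    ).reset_index(drop=True)
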