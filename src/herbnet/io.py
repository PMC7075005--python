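"""Readers and writers for the tabular and graph formats the pipeline touches.

TSV is the canonical exchange dialect; CSV is accepted for compound tables
via the ``dialect`` flag. Graphs are exported as GraphML (edge pathway sets
joined into a ``|``-separated string attribute) or as a plain edge list.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Dict, List, Tuple, Union

import networkx as nx
import pandas as pd

from .data_model import BipartiteMap, CompoundRecord
from .errors import FormatError

PathLike = Union[str, Path]

_PATHWAY_SEP = "|"


def _read_table(path: PathLike, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (expected a header row)")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


def read_compound_table(path: PathLike, dialect: str = "tsv") -> List[CompoundRecord]:
    """Read a compound table; duplicates by compound_id merge herb sets.

    Required columns: compound_id, rotatable_bonds, tpsa. Optional: name,
    smiles, herb. Non-numeric descriptors raise a row-level error citing the
    file line (header is line 1).
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    df = _read_table(path, sep)
    _require_columns(df, ("compound_id", "rotatable_bonds", "tpsa"), path)

    merged: Dict[str, CompoundRecord] = {}
    order: List[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        cid = row["compound_id"].strip()
        if not cid:
            raise FormatError(f"{path}: empty compound_id on line {line}")
        try:
            bonds = int(float(row["rotatable_bonds"]))
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric rotatable_bonds "
                f"{row['rotatable_bonds']!r} on line {line}"
            )
        try:
            tpsa = float(row["tpsa"])
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric tpsa {row['tpsa']!r} on line {line}"
            )
        herb = row.get("herb", "").strip() if "herb" in df.columns else ""
        rec = CompoundRecord(
            compound_id=cid,
            name=row.get("name", "") if "name" in df.columns else "",
            smiles=(row.get("smiles") or None) if "smiles" in df.columns else None,
            herbs={herb} if herb else set(),
            rotatable_bonds=bonds,
            tpsa=tpsa,
        )
        if cid in merged:
            merged[cid] = merged[cid].merge(rec)
        else:
            merged[cid] = rec
            order.append(cid)
    return [merged[cid] for cid in order]


def read_bipartite_table(path: PathLike) -> BipartiteMap:
    """Read a target-pathway membership TSV into a :class:`BipartiteMap`.

    Columns: target_id, pathway_id, optional pathway_name. Duplicate pairs
    collapse; a pathway id seen with two different names keeps the first and
    emits a warning.
    """
    df = _read_table(path, "\t")
    _require_columns(df, ("target_id", "pathway_id"), path)
    pairs = []
    names: Dict[str, str] = {}
    for _, row in df.iterrows():
        t, p = row["target_id"].strip(), row["pathway_id"].strip()
        if not t or not p:
            continue
        pairs.append((t, p))
        if "pathway_name" in df.columns:
            name = row["pathway_name"].strip()
            if name:
                if p in names and names[p] != name:
                    warnings.warn(
                        f"pathway {p!r} has conflicting names "
                        f"({names[p]!r} vs {name!r}); keeping the first",
                        stacklevel=2,
                    )
                else:
                    names.setdefault(p, name)
    return BipartiteMap(pairs, pathway_names=names)


def write_bipartite_table(bmap: BipartiteMap, path: PathLike) -> None:
    rows = sorted(bmap.pairs)
    df = pd.DataFrame(rows, columns=["target_id", "pathway_id"])
    if bmap.pathway_names:
        df["pathway_name"] = [bmap.pathway_name(p) for _, p in rows]
    df.to_csv(path, sep="\t", index=False)


def read_disease_table(path: PathLike) -> pd.DataFrame:
    """Pathway -> ICD-11 disease-class mapping table."""
    df = _read_table(path, "\t")
    _require_columns(df, ("pathway_id", "icd11_class_code"), path)
    if "icd11_class_name" not in df.columns:
        df["icd11_class_name"] = df["icd11_class_code"]
    return df[["pathway_id", "icd11_class_code", "icd11_class_name"]]


def read_cooccurrence_table(path: PathLike) -> pd.DataFrame:
    """Per-target literature co-occurrence counts (full text and abstract)."""
    df = _read_table(path, "\t")
    _require_columns(df, ("target_id", "fulltext_count", "abstract_count"), path)
    for col in ("fulltext_count", "abstract_count"):
        try:
            df[col] = df[col].astype(int)
        except ValueError:
            raise FormatError(f"{path}: non-integer values in column '{col}'")
        if (df[col] < 0).any():
            raise FormatError(f"{path}: negative counts in column '{col}'")
    return df[["target_id", "fulltext_count", "abstract_count"]]


# ---------------------------------------------------------------------------
# Graph export / import


def _edge_pathways_to_str(pathways) -> str:
    return _PATHWAY_SEP.join(sorted(pathways))


def _edge_pathways_from_str(s: str) -> frozenset:
    return frozenset(s.split(_PATHWAY_SEP)) if s else frozenset()


def write_graph(graph: nx.Graph, path: PathLike, format: str = "graphml") -> None:
    """Write a TPT or TPD graph; round-trips exactly through :func:`read_graph`."""
    if format == "graphml":
        out = graph.__class__()
        out.add_nodes_from(graph.nodes(data=True))
        for u, v, data in graph.edges(data=True):
            attrs = dict(data)
            if "pathways" in attrs:
                attrs["pathways"] = _edge_pathways_to_str(attrs["pathways"])
            out.add_edge(u, v, **attrs)
        nx.write_graphml(out, str(path))
    elif format == "edgelist":
        with open(path, "w") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                tag = _edge_pathways_to_str(data.get("pathways", ()))
                fh.write(f"{u}\t{v}\t{tag}\n")
            for node in sorted(nx.isolates(graph)):
                fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path: PathLike, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        g = nx.read_graphml(str(path))
        for _, _, data in g.edges(data=True):
            if "pathways" in data:
                data["pathways"] = _edge_pathways_from_str(data["pathways"])
        return g
    elif format == "edgelist":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) >= 2:
                    u, v = parts[0], parts[1]
                    pw = _edge_pathways_from_str(parts[2]) if len(parts) > 2 else frozenset()
                    g.add_edge(u, v, pathways=pw)
        return g
    raise ValueError(f"unknown graph format {format!r}")


def write_distance_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    """Export a shortest-path-length matrix; unreachable pairs as "inf"."""
    out = matrix.map(lambda x: "inf" if math.isinf(x) else repr(float(x)))
    out.to_csv(path, sep="\t")
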