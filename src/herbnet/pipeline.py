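"""End-to-end pipeline orchestration.

Runs the stages in order — screen, enrich, build-tpt, ned, centrality, tpd,
validate — skipping optional stages whose inputs are not configured, and
writes every artifact plus a run manifest into an output directory.
Screening and enrichment are optional because a pre-enriched target-pathway
table may enter the pipeline directly.

Config layout (YAML or a plain dict)::

    inputs:
      compounds: compounds.tsv      # optional -> screening stage
      annotation: pairs.tsv         # or fixture: true
      fixture: false
      targets: targets.txt          # optional -> enrichment stage
      diseases: pathway_disease.tsv # optional -> TPD stage
      counts: cooccurrence.tsv      # optional -> validation stage
    params:
      alpha: 0.05
      top_fraction: 0.10
      pathway_indegree: 10
      disease_indegree: 20
      compound_dialect: tsv
    seed: 0
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .baselines import centrality_table, validate
from .data_model import BipartiteMap
from .enrichment import enrich
from .errors import ConfigError
from .io import (
    read_bipartite_table,
    read_compound_table,
    read_cooccurrence_table,
    read_disease_table,
    write_graph,
)
from .ned import network_efficiency, rank_all, ranking_table, top_fraction
from .screening import screen_compounds
from .synthetic import sample_network
from .tpd import build_tpd, tpd_summary
from .tpt import graph_stats, project

logger = logging.getLogger(__name__)

_DEFAULT_PARAMS = {
    "alpha": 0.05,
    "top_fraction": 0.10,
    "pathway_indegree": 10,
    "disease_indegree": 20,
    "compound_dialect": "tsv",
}


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def run_pipeline(config: dict, outdir: Union[str, Path]) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = dict(config.get("inputs") or {})
    params = {**_DEFAULT_PARAMS, **(config.get("params") or {})}
    seed = int(config.get("seed", 0))
    stages = []
    counts: Dict[str, object] = {}

    if not inputs.get("fixture") and not inputs.get("annotation"):
        raise ConfigError(
            "no target-pathway annotation: set inputs.annotation or inputs.fixture"
        )

    # --- screen -----------------------------------------------------------
    if inputs.get("compounds"):
        logger.info("stage: screen")
        records = read_compound_table(
            inputs["compounds"], dialect=params["compound_dialect"]
        )
        passing, report = screen_compounds(records)
        pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in passing],
                "name": [r.name for r in passing],
                "rotatable_bonds": [r.rotatable_bonds for r in passing],
                "tpsa": [r.tpsa for r in passing],
            }
        ).to_csv(outdir / "compounds_passing.tsv", sep="\t", index=False)
        (outdir / "screen_report.json").write_text(
            json.dumps(
                {"n_input": report.n_input, "n_pass": report.n_pass}, indent=2
            )
        )
        counts["compounds_in"] = report.n_input
        counts["compounds_pass"] = report.n_pass
        stages.append("screen")

    # --- annotation / enrich ---------------------------------------------
    if inputs.get("fixture"):
        bmap = sample_network()
    else:
        bmap = read_bipartite_table(inputs["annotation"])

    if inputs.get("targets"):
        logger.info("stage: enrich")
        query = [
            line.strip()
            for line in Path(inputs["targets"]).read_text().splitlines()
            if line.strip()
        ]
        results = enrich(query, bmap, alpha=params["alpha"])
        pd.DataFrame([asdict(r) for r in results]).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        retained = {r.pathway_id for r in results}
        bmap = BipartiteMap(
            [(t, p) for t, p in bmap.pairs if p in retained],
            pathway_names=bmap.pathway_names,
        )
        counts["pathways_retained"] = len(retained)
        stages.append("enrich")

    # --- build-tpt --------------------------------------------------------
    logger.info("stage: build-tpt")
    graph = project(bmap)
    write_graph(graph, outdir / "tpt.graphml")
    n_nodes, n_edges, n_comp = graph_stats(graph)
    counts.update(n_nodes=n_nodes, n_edges=n_edges, n_components=n_comp)
    stages.append("build-tpt")

    # --- ned --------------------------------------------------------------
    logger.info("stage: ned (%d knockouts)", n_nodes)
    ranked = rank_all(graph, bmap)
    ne0 = ranked[0].ne_baseline if ranked else network_efficiency(graph)
    table = ranking_table(ranked, fraction=params["top_fraction"])
    with open(outdir / "ned.tsv", "w") as fh:
        fh.write(f"# NE_0 = {ne0!r}\n")
        table.to_csv(fh, sep="\t", index=False)
    main_targets = [r.knocked_target for r in top_fraction(ranked, params["top_fraction"])]
    counts["ne_0"] = ne0
    counts["n_ranked"] = len(ranked)
    counts["n_main_targets"] = len(main_targets)
    stages.append("ned")

    # --- centrality -------------------------------------------------------
    logger.info("stage: centrality")
    cent = centrality_table(graph)
    cent.to_csv(outdir / "centrality.tsv", sep="\t", index=False)
    stages.append("centrality")

    # --- tpd --------------------------------------------------------------
    if inputs.get("diseases"):
        logger.info("stage: tpd")
        disease_map = read_disease_table(inputs["diseases"])
        tpd = build_tpd(main_targets, bmap, disease_map)
        write_graph(tpd, outdir / "tpd.graphml")
        tpd_summary(tpd).to_csv(outdir / "tpd.tsv", sep="\t", index=False)
        counts["tpd_nodes"] = tpd.number_of_nodes()
        stages.append("tpd")

    # --- validate ---------------------------------------------------------
    if inputs.get("counts"):
        logger.info("stage: validate")
        cooc = read_cooccurrence_table(inputs["counts"])
        scores = table.rename(columns={"target": "target_id"})[["target_id", "ned"]]
        merged = scores.merge(
            cent.rename(columns={"target": "target_id"}), on="target_id"
        ).merge(cooc, on="target_id")
        results = validate(merged)
        payload = {
            score: {
                kind: {"rho": r.rho, "p_value": r.p_value, "flagged": r.flagged}
                for kind, r in per.items()
            }
            for score, per in results.items()
        }
        (outdir / "validation.json").write_text(json.dumps(payload, indent=2))
        stages.append("validate")

    manifest = {
        "version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "params": params,
        "seed": seed,
        "stages": stages,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
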