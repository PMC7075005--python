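# herbnet

Network-pharmacology target prioritization for multi-component herbal
formulas. A formula acts through many compounds, targets and pathways at
once; `herbnet` identifies the *main* therapeutic targets by asking, for
each candidate target, how much the pathway-derived target network falls
apart when that target is assumed undruggable.

It is a library (with a thin `herbnet` CLI) for researchers who already
have a compound table and a target–pathway annotation — typically the
output of target prediction plus pathway enrichment — and want a
transparent, reproducible ranking pipeline instead of a chain of web tools.

## The method

From the bipartite target–pathway relation, the **targets–pathways–targets
(TPT) network** joins two targets iff they share at least one pathway; each
edge stores its set of shared pathways and has baseline length 1. Knocking
out a target *i* reduces every pathway *j* containing it (with *N_j*
members) to efficacy

&nbsp;&nbsp;&nbsp;&nbsp;PE_j = (N_j − 1) / N_j,

an edge carrying *t* affected pathways drops to edge efficacy
EE = ∏ (N_k − 1)/N_k and stretches to length L = 1/EE, and the network
efficiency

&nbsp;&nbsp;&nbsp;&nbsp;NE = Σ_{pairs {m,n}} 1 / d_mn

(weighted shortest paths, unordered pairs) is recomputed. The score

&nbsp;&nbsp;&nbsp;&nbsp;**NED_i = NE₀ − NE_i ≥ 0**

ranks targets; the top 10 % (ceiling) are the main targets. Around this
core the package provides Veber oral-bioavailability screening
(rotatable bonds ≤ 10 and TPSA ≤ 140 Å²), hypergeometric pathway
enrichment with Benjamini–Hochberg FDR, degree/betweenness baselines, the
directed targets–pathways–diseases (TPD) network with indegree thresholds,
and Spearman validation against literature co-occurrence counts. See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/worked_example.py` traces the whole calculation on a 7-target,
6-pathway demonstration network:

```python
from herbnet import knockout, network_efficiency, project, rank_all, sample_network

bmap = sample_network()
graph = project(bmap)              # 7 targets, 8 edges
network_efficiency(graph)          # 13.8333  <- NE_0
res = knockout(graph, bmap, "C")   # set off the hub target
```

which prints

```
baseline network efficiency NE_0 = 13.8333
knock out target C:
  pathway a (N=3): efficacy 2/3 = 67%
  pathway d (N=2): efficacy 1/2 = 50%
  ...
    C-B: L = 2.25  (2 affected pathways)
  NE_C = 8.4761, NED_C = NE_0 - NE_C = 5.3572
full ranking: C (5.3572), B (3.3668), F (2.4500), E (1.9286), ...
```

Pathways that lose their most-connected member stretch many edges at once,
so the hub C tops the ranking. The remaining examples cover screening,
enrichment, the TPD network, validation and the one-shot pipeline; each
prints its numbers with a line on what they mean.

## Command line

```bash
herbnet simulate fixture --out pairs.tsv
herbnet build-tpt --annotation pairs.tsv --out tpt.graphml --stats stats.json
herbnet ned --annotation pairs.tsv --out ned.tsv            # NE_0 echoed in a header
herbnet run --config run.yaml --outdir artifacts/           # full pipeline + manifest
```

Every subcommand is a thin wrapper over a library function; `run` executes
screen → enrich → build-tpt → ned → centrality → tpd → validate (optional
stages skip when their inputs are not configured) and writes a JSON
manifest of inputs, parameters, seed and counts.

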