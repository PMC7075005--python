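"""Pathway over-representation of a target set, hypergeometric + BH-FDR.

Plants one pathway whose members dominate the query and checks that it is
the pathway retained at FDR < 0.05.
"""

from herbnet import BipartiteMap, enrich
from herbnet.synthetic import SyntheticSpec, random_bipartite

background = random_bipartite(
    SyntheticSpec(n_targets=200, n_pathways=20, membership_prob=0.05, seed=42)
)
planted = [(f"T{i + 1:03d}", "planted") for i in range(10)]
annotation = BipartiteMap(list(background.pairs) + planted)

query = [t for t, _ in planted][:8] + ["T150", "T160"]
results = enrich(query, annotation, alpha=0.05)

print(f"query of {len(query)} targets against {len(annotation.pathways)} pathways")
print("pathways retained at FDR < 0.05 (overlap k / pathway size K, p, q):")
for r in results:
    print(
        f"  {r.pathway_id}: k={r.overlap}/K={r.pathway_size}  "
        f"p={r.p_value:.3g}  q={r.q_value:.3g}"
    )
print("the planted pathway should lead this list; chance overlaps are filtered out")
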