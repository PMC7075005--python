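"""Build a targets-pathways-diseases network and read off the main pathways.

Uses the demonstration map: with main targets {B, C}, pathways shared by
both get indegree 2; disease classes inherit edges only from reached
pathways.
"""

import pandas as pd

from herbnet import build_tpd, main_diseases, main_pathways, sample_network, tpd_summary

bmap = sample_network()
disease_map = pd.DataFrame(
    [
        ("a", "02", "neoplasms"),
        ("b", "08", "diseases of the nervous system"),
        ("d", "05", "endocrine, nutritional or metabolic diseases"),
        ("f", "05", "endocrine, nutritional or metabolic diseases"),
    ],
    columns=["pathway_id", "icd11_class_code", "icd11_class_name"],
)

tpd = build_tpd({"B", "C"}, bmap, disease_map)
print(f"TPD network: {tpd.number_of_nodes()} nodes, {tpd.number_of_edges()} directed edges")
print(tpd_summary(tpd).to_string(index=False))
print("\npathways with indegree > 1 (targeted by more than one main target):")
for pathway, indeg in main_pathways(tpd, threshold=1):
    print(f"  {pathway}: indegree {indeg}")
print("disease classes fed by at least one pathway:")
for disease, indeg in main_diseases(tpd, threshold=0):
    print(f"  {disease} ({tpd.nodes[disease]['icd11_class_name']}): indegree {indeg}")
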