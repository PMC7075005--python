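"""Screen a synthetic compound table with Veber's oral-bioavailability rule.

A compound passes when it has at most 10 rotatable bonds and a topological
polar surface area of at most 140 square angstroms (both inclusive).
"""

import numpy as np

from herbnet import CompoundRecord, screen_compounds

rng = np.random.default_rng(0)
records = [
    CompoundRecord(
        compound_id=f"CID{i:04d}",
        rotatable_bonds=int(rng.integers(0, 21)),
        tpsa=float(rng.uniform(0, 280)),
    )
    for i in range(500)
]
# a boundary compound: exactly 10 bonds and 140 A^2 still passes
records.append(CompoundRecord(compound_id="boundary", rotatable_bonds=10, tpsa=140.0))

passing, report = screen_compounds(records)
print(f"{report.n_pass} of {report.n_input} compounds predicted orally bioavailable")
labels = list(report.failing_criterion.values())
for label in ("bonds", "tpsa", "both"):
    print(f"  failed on {label}: {labels.count(label)}")
print("boundary compound passes:", report.failing_criterion["boundary"] == "none")
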