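"""Curate a small synthetic bioactivity table into a set of potent actives.

Generates a ChEMBL-like table (including deliberately dirty rows), applies
the cell-record filter clauses, deduplicates to the most potent record per
compound and cell line, and selects the "highly active" compounds (sub-1 µM
on at least one line, 180-850 Da).
"""

import chemcascade as cc
from chemcascade import curation

config = cc.SimulationConfig(seed=42)
compounds = cc.build_compound_library(config)
cell_records, _, _ = cc.plant_bioactivities(compounds, config)

filtered = curation.filter_cell_bioactivities(cell_records)
deduped = curation.dedup_best(filtered)
comp_map = {c.compound_id: c for c in compounds}
actives = curation.select_actives(deduped, comp_map)

print(f"raw records:        {len(cell_records)}")
print(f"after clause filter:{len(filtered):5d}   (dirty rows removed)")
print(f"after dedup:        {len(deduped):5d}   (one per compound x cell line)")
print(f"highly active:      {len(actives):5d}   compounds sub-1 uM on >=1 line")

example = comp_map[actives[0]]
d = cc.compute_descriptors(example)
print(f"\nexample active {example.compound_id}: {example.structure_key}")
print(f"  MW {d.mw:.1f} Da, LogP {d.logp:.2f}, PSA {d.psa:.1f} A^2, "
      f"HBD {d.hbd}, HBA {d.hba}, volume {d.volume:.0f} A^3, ovality {d.ovality:.2f}")
print("(ovality 1.0 = perfect sphere; drug-like scaffolds sit around 1.2-1.5)")
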