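"""Screen a drug library against actives with the 2D fingerprint cascade.

Scores every (drug, active) pair with MACCS and ECFP4 Tanimoto coefficients
and keeps pairs clearing both thresholds (MACCS >= 0.8 AND ECFP4 >= 0.3).
Planted analog drugs should survive; unrelated distractors should not.
"""

import chemcascade as cc

study = cc.simulate_study(cc.SimulationConfig(seed=7, n_analog_drugs=10, n_distractor_drugs=10))
actives = [c for c in study.compounds if c.compound_id in set(study.ground_truth.analog_map.values())]

pairs = cc.all_against_all_2d(study.drugs, actives)
survivors = cc.cascade_filter_2d(pairs)  # defaults: 0.8 / 0.3

print(f"{len(study.drugs)} drugs x {len(actives)} actives = {len(pairs)} pairs scored")
print(f"{len(survivors)} pairs pass the dual-threshold cascade\n")
print(f"{'drug':10s} {'active':10s} {'Tc(MACCS)':>9s} {'Tc(ECFP4)':>9s}  planted?")
for p in survivors[:8]:
    planted = study.ground_truth.analog_map.get(p.drug_id) == p.active_id
    print(f"{p.drug_id:10s} {p.active_id:10s} {p.tc_maccs:9.3f} {p.tc_ecfp4:9.3f}  {planted}")
print("\nTc = |A n B| / |A u B| over fingerprint bits; 1.0 = identical bit patterns.")
print("Surviving pairs are near-analogs of known actives, the 3D stage's input.")
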