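# chemcascade

A ligand-based virtual-screening cascade for drug repurposing, built for
computational chemists who want to triage an approved/clinical drug library
against compounds with known activity on cancer cell lines — and to do it
reproducibly, with every threshold explicit and every stage testable
offline on synthetic data with planted ground truth.

The workflow, end to end:

1. **Curation** — standardize structures (salt stripping, canonical
   identity keys), filter bioactivity records (standard type ∈
   {GI50, EC50, IC50}, relation ∈ {<, >, =}, unit `nM`), deduplicate to the
   most potent record per compound × cell line, and keep "highly active"
   compounds: certified sub-1 µM on ≥ 1 cell line and MW ∈ [180, 850] Da.
2. **2D similarity** — all-against-all MACCS (166 keys) and ECFP4
   (radius-2 circular, 2048 bits) Tanimoto
   `Tc = |A∩B| / |A∪B|`, retaining pairs with Tc_MACCS ≥ 0.8 **and**
   Tc_ECFP4 ≥ 0.3.
3. **3D similarity** — seeded conformer ensembles, first-order Gaussian
   shape overlay (atoms as Gaussians of amplitude 2.7 matched to their
   van-der-Waals volume), pharmacophore "color" overlap at the
   shape-optimal pose, and
   `TanimotoCombo = ShapeTanimoto + ColorTanimoto ∈ [0, 2]`,
   with `ShapeTanimoto = V_AB / (V_AA + V_BB − V_AB)`; pairs with
   TCc ≥ 1.5 survive.
4. **Target mining** — per (target, cell line), Spearman ρ between target
   potency and cell potency over compounds annotated on both; selected when
   ρ ≥ 0.40, p ≤ 0.05 (t-approximation, n−2 df) and the Bonett–Wright
   Fisher-z CI lower bound ≥ 0.40.
5. **Integration** — each surviving drug gets potency-class annotations
   (≤ 1 µM highly active, 1–10 µM scarcely active, ≥ 10 µM inactive), four
   objective evidence flags (in-vitro cell activity, in-vivo evidence,
   disease trial, potent on a correlated target) and a deterministic rank.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```bash
python examples/03_shape_overlay.py
```

compares a 2-arylbenzimidazole active against its single-methyl analog and
against an unrelated aliphatic sulfonamide:

```
active vs analog:
  shape Tanimoto 0.971  (volume overlap after optimal rigid alignment)
  color Tanimoto 0.760  (donor/acceptor/ring features, same pose)
  TanimotoCombo  1.731  -> PASS at the 1.5 bar
active vs unrelated:
  shape Tanimoto 0.764
  color Tanimoto 0.035
  TanimotoCombo  0.799  -> fail at the 1.5 bar
```

The analog nearly reproduces the active's volume and feature pattern, so it
clears the 1.5 similarity bar; the sulfonamide overlaps in bulk shape only
(shape Tanimoto is never small for two blobs of similar size) and its
feature mismatch keeps the combined score far below threshold — exactly the
behavior that makes the combined score a better analog detector than shape
alone.

The other example scripts walk each capability: `01` curation and the
descriptor panel, `02` the 2D cascade on planted analogs, `04` target
correlation mining (drivers selected, permuted decoys rejected, with ρ, p
and CI printed per cell line), `05` the full pipeline producing the ranked
candidate report:

```
 rank drug_id best_active_id  best_tanimoto_combo  n_flags ...
    1 DRG0000        CMP0141             1.977           2
    2 DRG0006        CMP0046             1.972           2
```

Every ranked candidate is a 3D-cascade survivor; `n_flags` counts the
evidence classes backing it. Intermediate tables (2D scores, overlays,
correlations) and fixture files are written alongside the report.

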