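# Methods

`chemcascade` implements a ligand-based drug-repurposing workflow: starting
from a bioactivity database of compounds assayed on cancer cell lines and a
library of approved/clinical drugs, it (1) curates and standardizes both
sides, (2) screens every drug against every "highly active" compound with a
2D-fingerprint similarity cascade followed by a 3D shape/pharmacophore
overlay, (3) mines biological targets whose potency correlates with the
cell-level antiproliferative phenotype, and (4) integrates similarity,
potency-class and clinical evidence into a ranked candidate report. This
note records the model choices, defaults and limitations.

## Curation

Structures are standardized by keeping the largest covalent fragment
(dropping salt counterions), neutralizing charges where chemically possible,
and keying identity on the canonical SMILES of that parent. All potencies
are nanomolar; lower = more potent.

Cell records are retained when the standard type is GI50/EC50/IC50, the
relation is one of `<`, `>`, `=`, and the unit is the literal string `nM`
(other spellings are rejected and logged). Duplicates within a
(compound, cell line) group keep the numerically smallest value, comparing
GI50/EC50/IC50 directly without normalization since the three are pooled.
A compound is "highly active" when at least one record *certifies* sub-1 µM
potency and its MW lies in the closed window [180, 850] Da. Certification
honors the logic of censored values: `=` and `<` records at or below the
cutoff certify; `>` records never do, because a lower bound cannot prove
potency. Drugs structurally identical to a curated active (same canonical
parent key) are removed before screening.

The descriptor panel (LogP, TPSA, HBD, HBA, MW, volume, ovality) uses the
toolkit's standard 2D definitions plus two 3D estimates on the
lowest-energy embedded conformer: volume as a 0.2 Å grid count over Bondi
van-der-Waals spheres (lattice anchored on the centroid; single-sphere
error ≲ 1.3%), and ovality as molecular surface area (Shrake–Rupley sphere
sampling at probe radius 0, 512 points per atom) divided by the surface
area of the equal-volume sphere. By this convention ovality ≥ 1 (exactly 1
for one atom); some toolkits report the reciprocal (≤ 1), which is
available via `ovality_convention="reciprocal"`. Note the standard HBD
SMARTS counts O with *exactly one* H, so bare water scores 0 donors;
methanol is the minimal donor example.

## 2D similarity cascade

Fingerprints: the public 166-key MACCS set (the toolkit's unused leading
bit is dropped so indices run 0–165) and the radius-2 circular (ECFP4)
fingerprint folded to 2048 bits (configurable power of two; folding
collisions are accepted as inherent). Tanimoto Tc = |A∩B|/|A∪B|, with the
conventions empty-vs-empty = 1 and empty-vs-nonempty = 0 — unreachable in
practice given the 180 Da MW floor. The cascade retains pairs with
Tc(MACCS) ≥ 0.8 **and** Tc(ECFP4) ≥ 0.3 (both inclusive). The conjunction
is deliberate: MACCS alone saturates on decorated analogs of a shared
scaffold, while ECFP4 alone is too strict across scaffold families; the
pair of thresholds is the standard operating point for analog retrieval.
All-against-all scoring is brute force — at desk scale (10²–10⁴ pairs) no
indexing structure is warranted.

## 3D shape stage

The 3D stage is an open first-order Gaussian-overlay method in the style of
Grant & Pickup. Each heavy atom (hydrogens excluded, for robustness to
protonation conventions) is an isotropic Gaussian of amplitude p = 2.7
whose integral equals its hard-sphere volume, giving width
α = π(3p/4πR³)^{2/3}. The pairwise overlap

    V_AB = Σ_ij p² (π/(α_i+α_j))^{3/2} exp(−α_iα_j d_ij²/(α_i+α_j))

equals the exact integral of the product of the two Gaussian densities
(no second-order triple-overlap corrections), which is what the
grid-integration oracle in the tests verifies to 2%. ShapeTanimoto =
V_AB/(V_AA+V_BB−V_AB) is maximized over rigid poses by canonicalizing both
molecules to centroid + principal axes (deterministic sign convention),
trying the four 180° axis-flip starts, and refining each with Nelder–Mead
over the 6 rigid-body parameters (≤ 200 iterations, tolerance 1e-4).
Internal canonicalization makes the score invariant to any rigid
pre-transformation of either input.

Color (pharmacophore) scoring uses a minimal public SMARTS dictionary —
donor (N/O bearing H), acceptor (neutral N/O with lone pair), cation/anion
by formal charge, hydrophobe (aliphatic C with no heteroatom neighbor,
scored per atom rather than per cluster), aromatic ring centroid per SSSR
ring — each feature a Gaussian of radius 1 Å and amplitude 2.7, overlapped
only with same-type features at the shape-optimal pose and normalized the
same way. TanimotoCombo = shape + color ∈ [0, 2]; ensembles are scored by
exhaustive max over conformer pairs, and pairs with TCc ≥ 1.5 survive.

Conformers: seeded distance-geometry embedding (ETKDGv3), MMFF minimization,
energy-sorted greedy pruning to pairwise heavy-atom best-fit RMSD ≥ 0.5 Å,
at most n = 10 per molecule by default (the library compounds here are
rigid scaffolds and typically collapse to 1–4). The ensemble size is a
cost/coverage dial: pipeline-level runs in the examples and the acceptance
script use 3–5 conformers, which is ample for the rigid chemistry the
generator emits. No claim of numerical parity with proprietary overlay
programs is made — only the score semantics (shape+color in [0,2], 1.5
threshold) are preserved.

## Target–phenotype correlation

Target annotations are retained under six conjunctive clauses (IC50/Ki/Kd/
EC50; relation `=` only; unit `nM`; target type "Single protein"; organism
"Homo Sapiens"; assay type "B"), deduplicated per (compound, target) by
best value, and targets with fewer than 10 distinct annotated compounds are
dropped. Each (target, cell line) pair is analyzed separately: an inner
join on compound id yields paired potency vectors, scored with tie-aware
(average-rank) Spearman ρ and the t-approximation p-value on n−2 df.
Working on raw nM is deliberate — ρ is invariant under strictly monotone
transforms, so raw and −log10 scales give identical results, and the
positive-ρ sign convention means "potent on target ↔ potent on cells".

The confidence interval is the Fisher-z interval with the Bonett–Wright
standard error for Spearman, se = √((1+ρ²/2)/(n−3)) — the method is not
dictated by the statistic itself, so a seeded percentile bootstrap (2000
resamples) is provided as an alternative. Selection requires ρ ≥ 0.40,
p ≤ 0.05 and (by default) CI lower bound ≥ 0.40; the p threshold is
configurable because reasonable analyses also use 0.001. Degenerate vectors
(n < 3, zero variance) are reported as not-selected with a diagnostic
rather than raised, so a sweep over many targets never aborts. No
multiple-testing correction is applied (the report footer says so);
correlations use all deduplicated pairs by default, with a config flag left
open for restricting to highly active compounds only.

## Integration and ranking

Potency classes: ≤ 1000 nM highly active, strictly between 1000 and
10000 nM scarcely active, ≥ 10000 nM inactive (the exact 10 µM boundary
goes to inactive, honoring the literal inactive clause of the class
definition). The four objective triage flags per drug are: (i) a
non-inactive record on a disease cell line; (ii) in-vivo evidence rows;
(iii) a clinical-trial row whose disease matches the configured terms
(default: prostate / solid tumor); (iv) a non-inactive record on a target
that passed correlation selection. In-vivo and trial evidence share one
annotation table distinguished by a `source` column, since trial registries
are not scraped. Ranking is an explicit deterministic convention — flag
count, then best TanimotoCombo, then max clinical phase, then drug id — not
a claim about the relative weight of evidence classes; final scientific
triage (novelty, toxicity) is left to the user. Reports are written as CSV
and JSON with total ordering and fixed float formatting, so identical
inputs give byte-identical files.

## Synthetic data generator

The generator emulates the *statistical shape* of the real data sources,
not their chemistry. The compound library enumerates six drug-like scaffold
cores (2-arylbenzimidazole, 2-arylquinazolinone, flavone, piperazine
benzamide, naphthamide, 2-arylbenzoxazole) with 25 para decorations —
MW ≈ 210–370, LogP ≈ 2–4, matching the descriptor ranges typical of
cell-screening datasets. Each compound draws a latent log10 potency
~ U[1.5, 4.5] (≈ 30 nM – 30 µM) on each of 3 driver targets; its cell-line
potency is the *minimum* of the slope-scaled driver potencies plus
N(0, 0.3) log10 noise per line (best target drives the phenotype — a
mechanism, not a claim about real biology). Driver annotations are emitted
for the ≤ 40 compounds whose minimum that driver achieves (its assay
series, the realistic situation in which a target's SAR series is also the
cell-active series); decoy targets receive a seeded permutation of a
driver's values, which preserves the marginal distribution while destroying
the pairing. Dirty rows (µM units, `<`/`>`/`~` relations, rat orthologs,
protein complexes, functional assays) are marked i.i.d. at 20% and cycle
through the clause list so every filter clause has work to do.

The drug fixture plants near-analogs (single seeded edits of sub-µM
actives) and distractors from a disjoint aliphatic family (dicyclohexyl
ureas, morpholine sulfonamides, adamantane esters). The default edit-op set
is {add_methyl, halogen_swap}: ring saturation is implemented and
selectable, but collapsing an aromatic ring routinely drops MACCS Tc below
0.8 and would break the planted-signal contract the generator promises
(analog MACCS Tc ≥ 0.8 in ≥ 90% of cases, self-verified at generation time
and recorded in `GroundTruth`). Metadata assigns clinical phases 1–4 and
seeded trial/in-vivo/bioactivity evidence so every report flag is
exercised.

What passing tests on this generator do **not** show: robustness to real
assay heterogeneity (inter-lab shifts, censored-value pile-ups, activity
cliffs), to chemistry outside the scaffold grammar, or to the much larger
and sparser join structure of real databases. They do show that the
filtering logic, the similarity arithmetic, the correlation statistics and
the integration bookkeeping are correct and deterministic, and that planted
signal of realistic strength is recovered at the published thresholds.

## Numerical choices and degenerate inputs

- Seeds: every stochastic component (embedding, generator, bootstrap)
  takes an explicit integer seed; the pipeline derives all of them from one
  master seed. Two runs with the same config are byte-identical.
- Ties in dedup keep the first-seen record; ranking ties break on drug id.
- Shape optimizer tolerance 1e-4 on the objective; symmetry of the combo
  score holds to 1e-3, the optimizer's documented guarantee.
- Overlap kernels clip Tanimoto values into their theoretical ranges to
  absorb last-digit float excursions.
- Problem sizes in tests/examples (ensembles of 1–10 conformers, libraries
  of 100–150 compounds, 200-pair recovery experiments) are desk-scale
  choices that keep a full run in minutes on one core while leaving every
  code path exercised.

## Known limitations

- First-order Gaussian overlap underestimates the self-volume of fused-ring
  systems relative to hard-sphere volume; since both numerator and
  denominator of ShapeTanimoto share the approximation, rankings are
  stable, but absolute overlap volumes should not be quoted as Å³ volumes.
- The rigid-body optimizer is local after principal-axes starts; strongly
  non-convex overlays (near-symmetric molecules) can settle 1e-3 below the
  global pose. Exhaustive rotational search is out of scope.
- Feature typing is SMARTS-minimal: no tautomer awareness, no pKa model,
  no projected (directional) features.
- The report's four flags are evidence bookkeeping, not effect estimates;
  no attempt is made to reproduce manual literature triage.
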