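"""Synthetic bioactivity-database generator with planted ground truth.

Emulates the two data sources the cascade consumes — a ChEMBL-like
bioactivity table and a DrugBank-like drug library — entirely from an
embedded scaffold grammar, so every pipeline stage is testable offline:

* a compound library enumerated from drug-like scaffold × decoration
  SMILES (MW roughly 200–450, LogP 2–4);
* per-compound latent log10 potencies on "driver" targets, with cell-line
  potency driven by the best (minimum) driver potency plus log-normal
  noise — so each driver correlates with the phenotype on the compounds
  designed against it — and "decoy" targets whose potencies are permuted
  to destroy the compound-level pairing;
* a drug fixture of near-analog drugs (seeded single structural edits of
  potent actives) and structurally unrelated distractors, plus metadata
  and clinical-annotation tables;
* deliberately dirty rows (micromolar units, bound relations, non-human
  organisms, protein complexes, non-binding assays) at a configured
  fraction, so every curation filter clause has removable rows.

Everything is a pure function of the master seed; the planted statistical
structure is self-verified at generation time and recorded in
:class:`GroundTruth` so downstream tests assert recovery, not regeneration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import DataStructs, MACCSkeys
from scipy import stats

from .curation import BioactivityRecord, CompoundRecord, Source, standardize_structure

#: Drug-like scaffold cores, each with one para decoration point.
SCAFFOLD_CORES = (
    "c1ccc2[nH]c(-c3ccc({R})cc3)nc2c1",  # 2-arylbenzimidazole
    "O=C1NC(=Nc2ccccc12)c1ccc({R})cc1",  # 2-arylquinazolinone
    "O=c1cc(-c2ccc({R})cc2)oc2ccccc12",  # flavone
    "O=C(N1CCN(C)CC1)c1ccc({R})cc1",  # piperazine benzamide
    "O=C(Nc1ccc({R})cc1)c1ccc2ccccc2c1",  # naphthamide
    "c1ccc2oc(-c3ccc({R})cc3)nc2c1",  # 2-arylbenzoxazole
)

DECORATIONS = (
    "F", "Cl", "Br", "I", "C", "CC", "CCC", "C(C)C", "C(C)(C)C",
    "OC", "OCC", "OC(C)C", "N", "NC", "N(C)C", "NCC", "O", "CO", "CCO",
    "C#N", "C(F)(F)F", "C(=O)C", "C(=O)OC", "C(=O)N", "S(C)(=O)=O",
)

#: Distractor family: aliphatic ureas/sulfonamides/adamantane esters,
#: deliberately disjoint from the active scaffolds.
DISTRACTOR_CORES = (
    "O=C(NC1CCCCC1)N(C1CCCCC1)C{R}",
    "O=S(=O)(N1CCOCC1)CC{R}",
    "O=C(OC{R})C12CC3CC(CC(C3)C1)C2",
)
DISTRACTOR_DECORATIONS = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "CCO", "CCN(C)C", "CC(C)C", "CCOC", "CCCO",
)

DEFAULT_CELL_LINES = ("PC-3", "DU-145", "LNCaP")

EDIT_OPS = ("add_methyl", "halogen_swap", "ring_saturation")

# Clause-violating field values, cycled through when a row is marked dirty.
_CELL_DIRTY_KINDS = ("bad_type", "bad_relation", "bad_unit")
_TARGET_DIRTY_KINDS = (
    "bad_type", "bad_relation", "bad_unit", "bad_target_type", "bad_organism", "bad_assay",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic repurposing dataset."""

    seed: int = 0
    n_scaffolds: int = 6
    n_decorations: int = 25
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    driver_targets: tuple[tuple[str, float, float], ...] = (
        ("T-DRV-1", 1.0, 0.3),
        ("T-DRV-2", 1.0, 0.3),
        ("T-DRV-3", 1.0, 0.3),
    )  # (target_id, link_slope, noise_sd_log10)
    decoy_targets: tuple[str, ...] = ("T-DEC-1", "T-DEC-2", "T-DEC-3")
    n_annotations_per_target: int = 40
    n_analog_drugs: int = 20
    n_distractor_drugs: int = 20
    analog_edit_ops: tuple[str, ...] = ("add_methyl", "halogen_swap")
    dirty_fraction: float = 0.2

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)


@dataclass
class GroundTruth:
    """What was planted, plus generation-time self-verification stats."""

    analog_map: dict[str, str] = field(default_factory=dict)  # drug -> source active
    driver_set: tuple[str, ...] = ()
    decoy_set: tuple[str, ...] = ()
    driver_rho: dict[str, float] = field(default_factory=dict)
    decoy_rho: dict[str, float] = field(default_factory=dict)
    analog_maccs_tc: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "analog_map": self.analog_map,
            "driver_set": list(self.driver_set),
            "decoy_set": list(self.decoy_set),
            "driver_rho": self.driver_rho,
            "decoy_rho": self.decoy_rho,
            "analog_maccs_tc": self.analog_maccs_tc,
        }


def build_compound_library(config: SimulationConfig) -> list[CompoundRecord]:
    """Enumerate scaffold × decoration structures as standardized records.

    Deterministic: ids are CMP0000... in grammar order. Every structure
    parses and lies in the 180–850 Da window by construction (asserted).
    """
    cores = SCAFFOLD_CORES[: config.n_scaffolds]
    decs = DECORATIONS[: config.n_decorations]
    out = []
    i = 0
    seen = set()
    for core in cores:
        for dec in decs:
            smi = core.format(R=dec)
            rec = standardize_structure(smi, compound_id=f"CMP{i:04d}")
            if rec.structure_key in seen:
                continue
            seen.add(rec.structure_key)
            assert 180.0 <= rec.mw <= 850.0, smi
            out.append(rec)
            i += 1
    return out


def _make_record(
    compound_id: str,
    scope: str,
    scope_id: str,
    value_nm: float,
    rng: np.random.Generator,
    dirty_kind: str | None,
) -> BioactivityRecord:
    if scope == "cell":
        std_type = str(rng.choice(["GI50", "EC50", "IC50"]))
        relation, units = "=", "nM"
        assay, ttype, organism = "F", "Cell-line", "Homo Sapiens"
        if dirty_kind == "bad_type":
            std_type = "Ki"
        elif dirty_kind == "bad_relation":
            relation = "~"
        elif dirty_kind == "bad_unit":
            units = "uM"
            value_nm = value_nm / 1000.0
    else:
        std_type = str(rng.choice(["IC50", "Ki", "Kd", "EC50"]))
        relation, units = "=", "nM"
        assay, ttype, organism = "B", "Single protein", "Homo Sapiens"
        if dirty_kind == "bad_type":
            std_type = "GI50"
        elif dirty_kind == "bad_relation":
            relation = str(rng.choice(["<", ">"]))
        elif dirty_kind == "bad_unit":
            units = "uM"
            value_nm = value_nm / 1000.0
        elif dirty_kind == "bad_target_type":
            ttype = "Protein complex"
        elif dirty_kind == "bad_organism":
            organism = "Rattus norvegicus"
        elif dirty_kind == "bad_assay":
            assay = "F"
    return BioactivityRecord(
        compound_id=compound_id,
        activity_scope=scope,
        scope_id=scope_id,
        standard_type=std_type,
        standard_relation=relation,
        standard_value=round(float(value_nm), 4),
        standard_units=units,
        assay_type=assay,
        target_type=ttype,
        target_organism=organism,
    )


def plant_bioactivities(
    compounds: list[CompoundRecord],
    config: SimulationConfig,
) -> tuple[list[BioactivityRecord], list[BioactivityRecord], GroundTruth]:
    """Plant per-target and per-cell potencies with a known monotone link.

    Each compound draws a latent log10 potency ~ U[1.5, 4.5] (log10 nM) on
    every driver target; its cell-line potency is the minimum of
    slope-scaled driver potencies plus N(0, noise_sd_log10) per line
    (best target drives the phenotype). Target annotations for a driver are
    emitted for the compounds whose minimum it achieves (its "assay
    series"), capped at ``n_annotations_per_target``; each decoy target
    receives a seeded permutation of a driver's annotated values, which
    destroys the compound-level pairing. Dirty rows are marked i.i.d. at
    ``dirty_fraction`` and violate one filter clause each, cycling through
    the clause list so every clause occurs.
    """
    rng = np.random.default_rng(int(config.seed))
    n = len(compounds)
    drivers = config.driver_targets
    n_drv = len(drivers)
    latent = rng.uniform(1.5, 4.5, size=(n, n_drv))  # log10 nM on each driver
    scaled = latent * np.array([d[1] for d in drivers])[None, :]
    argmin = scaled.argmin(axis=1)
    base = scaled.min(axis=1)

    cell_records: list[BioactivityRecord] = []
    target_records: list[BioactivityRecord] = []
    cell_dirty_cycle = 0
    target_dirty_cycle = 0

    for li, line in enumerate(config.cell_lines):
        # noise sd of the phenotype: use the (shared) driver noise level
        sd = float(np.mean([d[2] for d in drivers]))
        noisy = base + rng.normal(0.0, sd, size=n)
        for ci, comp in enumerate(compounds):
            dirty = rng.random() < config.dirty_fraction
            kind = None
            if dirty:
                kind = _CELL_DIRTY_KINDS[cell_dirty_cycle % len(_CELL_DIRTY_KINDS)]
                cell_dirty_cycle += 1
            cell_records.append(
                _make_record(comp.compound_id, "cell", line, 10.0 ** noisy[ci], rng, kind)
            )

    gt = GroundTruth(
        driver_set=tuple(d[0] for d in drivers),
        decoy_set=tuple(config.decoy_targets),
    )

    annotated: dict[str, list[tuple[str, float]]] = {}
    for di, (tid, slope, noise_sd) in enumerate(drivers):
        series = [ci for ci in range(n) if argmin[ci] == di]
        rng.shuffle(series)
        series = sorted(series[: config.n_annotations_per_target])
        annotated[tid] = [
            (compounds[ci].compound_id, 10.0 ** latent[ci, di]) for ci in series
        ]
    for di, tid in enumerate(config.decoy_targets):
        src = drivers[di % n_drv][0]
        ids = [cid for cid, _ in annotated[src]]
        vals = np.array([v for _, v in annotated[src]])
        perm = rng.permutation(len(vals))
        annotated[tid] = [(cid, float(vals[p])) for cid, p in zip(ids, perm)]

    for tid, rows in annotated.items():
        for cid, val in rows:
            dirty = rng.random() < config.dirty_fraction
            kind = None
            if dirty:
                kind = _TARGET_DIRTY_KINDS[target_dirty_cycle % len(_TARGET_DIRTY_KINDS)]
                target_dirty_cycle += 1
            target_records.append(_make_record(cid, "target", tid, val, rng, kind))

    # self-verification: planted rho on clean values against the first line
    clean_cell = {
        r.compound_id: r.standard_value
        for r in cell_records
        if r.scope_id == config.cell_lines[0] and r.standard_units == "nM"
        and r.standard_relation == "="
        and r.standard_type in ("GI50", "EC50", "IC50")
    }
    for tid in list(gt.driver_set) + list(gt.decoy_set):
        pairs = [(v, clean_cell[cid]) for cid, v in annotated[tid] if cid in clean_cell]
        if len(pairs) >= 3:
            x, y = zip(*pairs)
            rho = float(stats.spearmanr(x, y).statistic)
        else:
            rho = float("nan")
        (gt.driver_rho if tid in gt.driver_set else gt.decoy_rho)[tid] = rho
    return cell_records, target_records, gt


def _apply_edit(mol: Chem.Mol, op: str, rng: np.random.Generator) -> Chem.Mol | None:
    """One structural edit; returns None if the op is not applicable."""
    rw = Chem.RWMol(mol)
    if op == "add_methyl":
        cands = [
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
        ]
        if not cands:
            return None
        idx = int(rng.choice(cands))
        new = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(idx, new, Chem.BondType.SINGLE)
    elif op == "halogen_swap":
        halos = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() in (9, 17, 35, 53)]
        if halos:
            idx = int(rng.choice(halos))
            current = rw.GetAtomWithIdx(idx).GetAtomicNum()
            choices = [z for z in (9, 17, 35) if z != current]
            rw.GetAtomWithIdx(idx).SetAtomicNum(int(rng.choice(choices)))
        else:
            cands = [
                a.GetIdx()
                for a in rw.GetAtoms()
                if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
            ]
            if not cands:
                return None
            idx = int(rng.choice(cands))
            new = rw.AddAtom(Chem.Atom(9))
            rw.AddBond(idx, new, Chem.BondType.SINGLE)
    elif op == "ring_saturation":
        ri = rw.GetRingInfo()
        rings = [
            ring
            for ring in ri.AtomRings()
            if len(ring) == 6
            and all(
                rw.GetAtomWithIdx(i).GetIsAromatic()
                and rw.GetAtomWithIdx(i).GetSymbol() == "C"
                for i in ring
            )
        ]
        if not rings:
            return None
        ring = rings[int(rng.integers(len(rings)))]
        ring_set = set(ring)
        for i in ring:
            rw.GetAtomWithIdx(i).SetIsAromatic(False)
        for b in rw.GetBonds():
            if b.GetBeginAtomIdx() in ring_set and b.GetEndAtomIdx() in ring_set:
                b.SetIsAromatic(False)
                b.SetBondType(Chem.BondType.SINGLE)
    else:
        raise ValueError(f"unknown edit op: {op!r}")
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def make_drug_fixture(
    compounds: list[CompoundRecord],
    active_ids: list[str],
    config: SimulationConfig,
    ground_truth: GroundTruth,
) -> tuple[list[CompoundRecord], pd.DataFrame, pd.DataFrame, list[BioactivityRecord]]:
    """Build the DrugBank-like side: analogs, distractors, metadata, evidence.

    Analog drugs are seeded single edits (from ``config.analog_edit_ops``)
    of sampled potent actives; distractors come from the disjoint aliphatic
    scaffold family. Metadata assigns a max clinical phase 1–4; a seeded
    subset of drugs receives clinical-annotation rows (trial and in-vivo
    evidence) and own bioactivity records on cells and targets so every
    triage flag is exercised. Returns (drugs, metadata, clinical table,
    drug bioactivity records) and fills ``ground_truth.analog_map`` and the
    analog MACCS self-check.
    """
    rng = np.random.default_rng(int(config.seed) + 1)
    by_id = {c.compound_id: c for c in compounds}
    drugs: list[CompoundRecord] = []
    meta_rows = []
    clinical_rows = []
    bio_records: list[BioactivityRecord] = []

    sources = [active_ids[int(i)] for i in rng.integers(0, len(active_ids), config.n_analog_drugs)]
    for k, src_id in enumerate(sources):
        src = by_id[src_id]
        drug_id = f"DRG{k:04d}"
        edited = None
        ops = list(config.analog_edit_ops)
        order = list(rng.permutation(len(ops)))
        for oi in order:
            edited = _apply_edit(src.structure, ops[oi], rng)
            if edited is not None:
                break
        if edited is None:  # exhausted ops: keep an unedited copy, still an analog
            edited = Chem.Mol(src.structure)
        rec = standardize_structure(
            Chem.MolToSmiles(edited), compound_id=drug_id, source=Source.DRUG_SET
        )
        drugs.append(rec)
        ground_truth.analog_map[drug_id] = src_id
        tc = DataStructs.TanimotoSimilarity(
            MACCSkeys.GenMACCSKeys(src.structure), MACCSkeys.GenMACCSKeys(rec.structure)
        )
        ground_truth.analog_maccs_tc[drug_id] = float(tc)
        meta_rows.append(
            {
                "drug_id": drug_id,
                "name": f"analogdrug-{k}",
                "max_phase": int(rng.integers(1, 5)),
                "indication": "oncology",
            }
        )

    for k in range(config.n_distractor_drugs):
        core = DISTRACTOR_CORES[k % len(DISTRACTOR_CORES)]
        dec = DISTRACTOR_DECORATIONS[(k // len(DISTRACTOR_CORES)) % len(DISTRACTOR_DECORATIONS)]
        drug_id = f"DST{k:04d}"
        rec = standardize_structure(
            core.format(R=dec), compound_id=drug_id, source=Source.DRUG_SET
        )
        drugs.append(rec)
        meta_rows.append(
            {
                "drug_id": drug_id,
                "name": f"distractor-{k}",
                "max_phase": int(rng.integers(1, 5)),
                "indication": "other",
            }
        )

    diseases = ("prostate cancer", "solid tumor", "breast cancer", "arthritis")
    all_targets = list(ground_truth.driver_set) + list(ground_truth.decoy_set)
    for row in meta_rows:
        drug_id = row["drug_id"]
        if rng.random() < 0.5:
            clinical_rows.append(
                {
                    "drug_id": drug_id,
                    "trial_id": f"TRIAL-{drug_id}",
                    "disease": diseases[int(rng.integers(len(diseases)))],
                    "phase": int(rng.integers(1, 4)),
                    "source": "trial",
                }
            )
        if rng.random() < 0.3:
            clinical_rows.append(
                {
                    "drug_id": drug_id,
                    "trial_id": f"VIVO-{drug_id}",
                    "disease": diseases[int(rng.integers(len(diseases)))],
                    "phase": 0,
                    "source": "in_vivo",
                }
            )
        if rng.random() < 0.5:
            line = config.cell_lines[int(rng.integers(len(config.cell_lines)))]
            bio_records.append(
                _make_record(drug_id, "cell", line, 10.0 ** rng.uniform(1.5, 4.8), rng, None)
            )
        if rng.random() < 0.5:
            tid = all_targets[int(rng.integers(len(all_targets)))]
            bio_records.append(
                _make_record(drug_id, "target", tid, 10.0 ** rng.uniform(0.5, 4.8), rng, None)
            )

    meta = pd.DataFrame(meta_rows)
    clinical = pd.DataFrame(
        clinical_rows, columns=["drug_id", "trial_id", "disease", "phase", "source"]
    )
    return drugs, meta, clinical, bio_records


@dataclass
class SyntheticStudy:
    """Everything one simulated repurposing study produced."""

    config: SimulationConfig
    compounds: list[CompoundRecord]
    cell_records: list[BioactivityRecord]
    target_records: list[BioactivityRecord]
    drugs: list[CompoundRecord]
    drug_meta: pd.DataFrame
    clinical: pd.DataFrame
    drug_bioactivities: list[BioactivityRecord]
    ground_truth: GroundTruth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run the full generator: library, planted activities, drug fixture."""
    from .curation import dedup_best, filter_cell_bioactivities, select_actives

    compounds = build_compound_library(config)
    cell_records, target_records, gt = plant_bioactivities(compounds, config)
    comp_map = {c.compound_id: c for c in compounds}
    deduped = dedup_best(filter_cell_bioactivities(cell_records))
    active_ids = select_actives(deduped, comp_map)
    if not active_ids:  # extreme noise settings: fall back to all compounds
        active_ids = [c.compound_id for c in compounds]
    drugs, meta, clinical, drug_bio = make_drug_fixture(compounds, active_ids, config, gt)
    return SyntheticStudy(
        config=config,
        compounds=compounds,
        cell_records=cell_records,
        target_records=target_records,
        drugs=drugs,
        drug_meta=meta,
        clinical=clinical,
        drug_bioactivities=drug_bio,
        ground_truth=gt,
    )


def write_fixtures(study: SyntheticStudy, out_dir) -> dict:
    """Write all fixture files and return a manifest (also saved as JSON)."""
    from .io import records_to_frame, write_compounds_sdf, write_smiles

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    bio = records_to_frame(
        study.cell_records + study.target_records + study.drug_bioactivities
    )
    paths["bioactivities"] = str(out / "bioactivities.csv")
    bio.to_csv(paths["bioactivities"], index=False)

    comp = pd.DataFrame(
        [
            {"compound_id": c.compound_id, "smiles": c.structure_key, "source": c.source.value}
            for c in study.compounds
        ]
    )
    paths["compounds"] = str(out / "compounds.csv")
    comp.to_csv(paths["compounds"], index=False)

    paths["drugs_smi"] = str(out / "drugs.smi")
    write_smiles(study.drugs, paths["drugs_smi"])
    paths["drugs_sdf"] = str(out / "drugs.sdf")
    write_compounds_sdf(study.drugs, paths["drugs_sdf"])

    paths["drug_meta"] = str(out / "drug_meta.csv")
    study.drug_meta.to_csv(paths["drug_meta"], index=False)
    paths["clinical"] = str(out / "clinical.csv")
    study.clinical.to_csv(paths["clinical"], index=False)

    paths["ground_truth"] = str(out / "ground_truth.json")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(study.ground_truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {"seed": study.config.seed, "paths": paths}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
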