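"""Reading and writing the delimited-table and SDF interchange formats.

The bioactivity table is a superset of a ChEMBL activity export with header
columns: compound_id, activity_scope, scope_id, standard_type,
standard_relation, standard_value, standard_units, assay_type, target_type,
target_organism (plus an optional smiles column on compound tables).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .curation import BioactivityRecord, CompoundRecord, Source, standardize_structure

BIOACTIVITY_COLUMNS = [
    "compound_id",
    "activity_scope",
    "scope_id",
    "standard_type",
    "standard_relation",
    "standard_value",
    "standard_units",
    "assay_type",
    "target_type",
    "target_organism",
]


def records_to_frame(records: Sequence[BioactivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in BIOACTIVITY_COLUMNS} for r in records],
        columns=BIOACTIVITY_COLUMNS,
    )


def read_bioactivities(path, sep: str = ",") -> list[BioactivityRecord]:
    """Read a delimited bioactivity table into records."""
    from .curation import records_from_frame

    df = pd.read_csv(path, sep=sep, dtype={"standard_relation": str})
    return records_from_frame(df)


def read_compounds(path, sep: str = ",", source: Source = Source.CELL_ACTIVE_SET) -> list[CompoundRecord]:
    """Read a compound table (compound_id, smiles[, source]) and standardize."""
    df = pd.read_csv(path, sep=sep)
    out = []
    for row in df.itertuples(index=False):
        src = Source(getattr(row, "source", source))
        out.append(standardize_structure(str(row.smiles), str(row.compound_id), src))
    return out


def write_smiles(compounds: Sequence[CompoundRecord], path) -> None:
    """Write a two-column SMILES file (smiles, id)."""
    with open(path, "w") as fh:
        for c in compounds:
            fh.write(f"{c.structure_key}\t{c.compound_id}\n")


def read_smiles(path, source: Source = Source.DRUG_SET) -> list[CompoundRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            cid = parts[1] if len(parts) > 1 else ""
            out.append(standardize_structure(parts[0], cid, source))
    return out


def write_compounds_sdf(compounds: Sequence[CompoundRecord], path) -> None:
    """Write compounds as a (2D-coordinate) SD file with id properties."""
    writer = Chem.SDWriter(str(path))
    try:
        for c in compounds:
            mol = Chem.Mol(c.structure)
            AllChem.Compute2DCoords(mol)
            mol.SetProp("_Name", c.compound_id)
            mol.SetProp("compound_id", c.compound_id)
            writer.write(mol)
    finally:
        writer.close()


def read_compounds_sdf(path, source: Source = Source.DRUG_SET) -> list[CompoundRecord]:
    out = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        cid = mol.GetProp("compound_id") if mol.HasProp("compound_id") else mol.GetProp("_Name")
        out.append(standardize_structure(Chem.MolToSmiles(mol), cid, source))
    return out


def write_conformers_sdf(conformer_set, path) -> None:
    """Write a conformer ensemble as a multi-conformer SD file."""
    writer = Chem.SDWriter(str(path))
    try:
        mol = conformer_set.mol
        for conf in mol.GetConformers():
            m = Chem.Mol(mol, confId=conf.GetId())
            m.SetProp("_Name", conformer_set.compound_id)
            m.SetProp("compound_id", conformer_set.compound_id)
            m.SetProp("seed", str(conformer_set.seed))
            writer.write(m, confId=conf.GetId())
    finally:
        writer.close()


def read_conformers_sdf(path):
    """Re-read a multi-conformer SD file written by :func:`write_conformers_sdf`.

    Consecutive entries with the same compound id are merged back into one
    multi-conformer molecule; returns a :class:`~chemcascade.shape.ConformerSet`.
    """
    from .shape import ConformerSet, _heavy_atom_arrays, extract_features, Conformer

    mols = [m for m in Chem.SDMolSupplier(str(path), removeHs=False) if m is not None]
    if not mols:
        raise ValueError(f"no molecules in {path}")
    cid = mols[0].GetProp("compound_id")
    seed = int(mols[0].GetProp("seed")) if mols[0].HasProp("seed") else 0
    base = Chem.Mol(mols[0])
    base.RemoveAllConformers()
    confs = []
    for m in mols:
        conf = m.GetConformer()
        new_id = base.AddConformer(conf, assignId=True)
        coords, radii, elements = _heavy_atom_arrays(base, new_id)
        ftypes, fcoords = extract_features(base, new_id)
        confs.append(
            Conformer(
                coords=coords,
                radii=radii,
                elements=elements,
                feature_types=ftypes,
                feature_coords=fcoords,
            )
        )
    return ConformerSet(
        compound_id=cid,
        conformers=tuple(confs),
        max_conformers=len(confs),
        seed=seed,
        mol=base,
    )


def pair2d_to_frame(pairs, survivors=None) -> pd.DataFrame:
    """Tabulate 2D pair scores; flags cascade survivors when provided."""
    df = pd.DataFrame(
        [
            {
                "drug_id": p.drug_id,
                "active_id": p.active_id,
                "tc_maccs": p.tc_maccs,
                "tc_ecfp4": p.tc_ecfp4,
            }
            for p in pairs
        ]
    )
    if survivors is not None:
        keys = {(s.drug_id, s.active_id) for s in survivors}
        df["passes_2d"] = [
            (r.drug_id, r.active_id) in keys for r in df.itertuples(index=False)
        ]
    return df


def overlay_to_frame(scores) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug_id": s.drug_id,
                "active_id": s.active_id,
                "shape_tanimoto": s.shape_tanimoto,
                "color_tanimoto": s.color_tanimoto,
                "tanimoto_combo": s.tanimoto_combo,
                "drug_conformer": s.best_conformer_pair[0],
                "active_conformer": s.best_conformer_pair[1],
            }
            for s in scores
        ]
    )
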