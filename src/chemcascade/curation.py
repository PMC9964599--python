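"""Compound and bioactivity curation.

Implements the dataset-preparation stage of the repurposing cascade: SMILES
standardization (salt stripping, hydrogen completion, canonical identity
keys), the cell-bioactivity filter clauses, per-group best-value
deduplication, selection of "highly active" compounds, and removal of drug
records structurally identical to curated actives.

Potency semantics throughout: all standard values are in nanomolar and lower
means more potent.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import KeyMissingError, ParseError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Standard types accepted for cell-based (antiproliferative) records.
CELL_STANDARD_TYPES = frozenset({"GI50", "EC50", "IC50"})
#: Standard types accepted for target-based (binding/functional) records.
TARGET_STANDARD_TYPES = frozenset({"IC50", "Ki", "Kd", "EC50"})
#: Relations retained in the cell dataset.
CELL_RELATIONS = frozenset({"<", ">", "="})
#: Only the literal nanomolar unit string is accepted.
NANOMOLAR = "nM"


class Source(str, Enum):
    """Provenance of a compound record."""

    CELL_ACTIVE_SET = "cell_active_set"
    DRUG_SET = "drug_set"


@dataclass(frozen=True)
class CompoundRecord:
    """One standardized chemical structure.

    ``structure`` is the desalted, hydrogen-complete RDKit molecule;
    ``structure_key`` is its canonical SMILES and serves as the identity key
    used for overlap removal and deduplication across encodings.
    """

    compound_id: str
    structure: Chem.Mol = field(compare=False, repr=False)
    structure_key: str = ""
    source: Source = Source.CELL_ACTIVE_SET
    mw: float = 0.0


@dataclass(frozen=True)
class BioactivityRecord:
    """One activity measurement on a cell line or a molecular target."""

    compound_id: str
    activity_scope: str  # "cell" | "target"
    scope_id: str  # cell-line name or target id
    standard_type: str  # GI50 | EC50 | IC50 | Ki | Kd
    standard_relation: str  # "<" | ">" | "="
    standard_value: float  # nanomolar
    standard_units: str
    assay_type: str = ""  # single-letter ChEMBL assay code
    target_type: str = ""
    target_organism: str = ""


from rdkit.Chem.MolStandardize import rdMolStandardize

_UNCHARGER = rdMolStandardize.Uncharger()


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def standardize_structure(
    raw_smiles: str,
    compound_id: str = "",
    source: Source = Source.CELL_ACTIVE_SET,
) -> CompoundRecord:
    """Parse and standardize a SMILES string into a :class:`CompoundRecord`.

    Standardization keeps the largest covalent fragment (salt counterions are
    dropped), completes implicit hydrogens, and derives a canonical SMILES
    identity key that is stable across atom-order permutations of the input.

    Raises
    ------
    ParseError
        If the SMILES is empty or does not parse to a valid molecule.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise ParseError("empty SMILES string", offending=raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {raw_smiles!r}", offending=raw_smiles)
    if mol.GetNumHeavyAtoms() == 0:
        raise ParseError(f"no heavy atoms in SMILES: {raw_smiles!r}", offending=raw_smiles)
    mol = _largest_fragment(mol)
    Chem.SanitizeMol(mol)
    mol = _UNCHARGER.uncharge(mol)  # neutral parent where chemically possible
    key = Chem.MolToSmiles(mol)  # canonical
    from rdkit.Chem import Descriptors

    return CompoundRecord(
        compound_id=compound_id or key,
        structure=mol,
        structure_key=key,
        source=source,
        mw=Descriptors.MolWt(mol),
    )


def filter_cell_bioactivities(
    records: Sequence[BioactivityRecord],
) -> list[BioactivityRecord]:
    """Apply the three cell-record retention clauses.

    A record survives iff its standard type is GI50/EC50/IC50, its relation
    is one of ``<``, ``>``, ``=`` and its unit is the literal string ``nM``.
    Order is preserved; the input is not mutated.
    """
    out = [
        r
        for r in records
        if r.standard_type in CELL_STANDARD_TYPES
        and r.standard_relation in CELL_RELATIONS
        and r.standard_units == NANOMOLAR
    ]
    logger.info("filter_cell_bioactivities: %d in, %d out", len(records), len(out))
    return out


def dedup_best(
    records: Sequence[BioactivityRecord],
) -> list[BioactivityRecord]:
    """Keep one record per (compound_id, scope_id) group: the most potent.

    "Best" means the numerically smallest standard value in nanomolar; ties
    are broken by input order (first wins), making the output deterministic.
    Output is ordered by first appearance of each group.
    """
    best: dict[tuple[str, str], BioactivityRecord] = {}
    for r in records:
        key = (r.compound_id, r.scope_id)
        cur = best.get(key)
        if cur is None or r.standard_value < cur.standard_value:
            best[key] = r
    out = list(best.values())
    logger.info("dedup_best: %d in, %d out (%d groups)", len(records), len(out), len(best))
    return out


def certifies_potency(record: BioactivityRecord, cutoff_nm: float) -> bool:
    """Whether a record proves activity at or below ``cutoff_nm``.

    ``=`` and ``<`` records with value <= cutoff certify potency; ``>``
    records never do (a lower bound cannot prove a compound is potent).
    """
    if record.standard_relation == ">":
        return False
    return record.standard_value <= cutoff_nm


def select_actives(
    records: Sequence[BioactivityRecord],
    compounds: Mapping[str, CompoundRecord],
    potency_cutoff_nm: float = 1000.0,
    mw_range: tuple[float, float] = (180.0, 850.0),
) -> list[str]:
    """Select "highly active" compound ids from deduplicated cell records.

    A compound qualifies when at least one cell record certifies sub-cutoff
    potency (see :func:`certifies_potency`) and its molecular weight lies in
    the closed ``mw_range``. Returned ids are ordered by first qualifying
    appearance, without duplicates.

    Raises
    ------
    KeyMissingError
        If a record's compound_id has no entry in ``compounds``.
    """
    lo, hi = mw_range
    seen: set[str] = set()
    out: list[str] = []
    for r in records:
        if r.compound_id in seen:
            continue
        if not certifies_potency(r, potency_cutoff_nm):
            continue
        comp = compounds.get(r.compound_id)
        if comp is None:
            raise KeyMissingError(f"compound_id not resolvable: {r.compound_id!r}")
        if lo <= comp.mw <= hi:
            seen.add(r.compound_id)
            out.append(r.compound_id)
    logger.info("select_actives: %d records in, %d compounds selected", len(records), len(out))
    return out


def remove_overlap(
    drug_set: Sequence[CompoundRecord],
    active_set: Sequence[CompoundRecord],
) -> list[CompoundRecord]:
    """Drop drugs whose standardized structure occurs among the actives.

    Identity is the canonical ``structure_key`` of the desalted parent, so
    two different SMILES encodings of one molecule collide as intended.
    """
    active_keys = {c.structure_key for c in active_set}
    out = [d for d in drug_set if d.structure_key not in active_keys]
    logger.info("remove_overlap: %d drugs in, %d out", len(drug_set), len(out))
    return out


def apply_cell_line_aliases(
    records: Sequence[BioactivityRecord],
    aliases: Mapping[str, str],
) -> list[BioactivityRecord]:
    """Pool cell-line name variants (e.g. a clone onto its parent line).

    ``aliases`` maps variant name -> canonical name. No pooling happens
    unless a mapping is supplied; records not mentioned pass through
    unchanged (the input list is never mutated).
    """
    if not aliases:
        return list(records)
    out = []
    for r in records:
        if r.activity_scope == "cell" and r.scope_id in aliases:
            r = dataclasses.replace(r, scope_id=aliases[r.scope_id])
        out.append(r)
    return out


def records_from_frame(df) -> list[BioactivityRecord]:
    """Build :class:`BioactivityRecord` objects from a bioactivity table.

    Expects the delimited-table header documented in :mod:`chemcascade.io`.
    """
    return [
        BioactivityRecord(
            compound_id=str(row.compound_id),
            activity_scope=str(row.activity_scope),
            scope_id=str(row.scope_id),
            standard_type=str(row.standard_type),
            standard_relation=str(row.standard_relation),
            standard_value=float(row.standard_value),
            standard_units=str(row.standard_units),
            assay_type=str(row.assay_type),
            target_type=str(row.target_type),
            target_organism=str(row.target_organism),
        )
        for row in df.itertuples(index=False)
    ]
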