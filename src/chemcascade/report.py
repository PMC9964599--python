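"""Candidate integration and ranked reporting.

Joins the 3D-cascade survivors with drug metadata, target potency-class
annotations, correlated-target membership and clinical evidence, sets the
four objective triage flags —

  (i)   in-vitro activity on a disease cell line,
  (ii)  in-vivo activity evidence,
  (iii) a clinical trial on the disease (or solid tumors including its
        patients),
  (iv)  a non-inactive bioactivity record on a target correlated with the
        disease phenotype —

and emits a deterministically ranked candidate report. The final scientific
triage (novelty, toxicity) is intentionally left to the user; the ranking
here is an explicit reproducible convention, not a claim about the relative
weight of the four evidence classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .curation import BioactivityRecord
from .errors import DomainError
from .fingerprints import Pair2DScore
from .shape import OverlayScore

logger = logging.getLogger(__name__)

HIGHLY_ACTIVE_MAX_NM = 1000.0
INACTIVE_MIN_NM = 10000.0

#: Case-insensitive substrings of a trial "disease" field counting as
#: disease-relevant evidence.
DEFAULT_DISEASE_TERMS = ("prostate", "solid tumor", "solid tumour")


class ActivityLabel(str, Enum):
    HIGHLY_ACTIVE = "highly_active"
    SCARCELY_ACTIVE = "scarcely_active"
    INACTIVE = "inactive"


@dataclass(frozen=True)
class ActivityClass:
    value_nm: float
    label: ActivityLabel


@dataclass(frozen=True)
class TargetAnnotation:
    target_id: str
    value_nm: float
    label: ActivityLabel
    is_correlated_target: bool


@dataclass(frozen=True)
class CandidateReport:
    drug_id: str
    name: str
    max_phase: int
    best_active_id: str
    best_tc_maccs: float
    best_tc_ecfp4: float
    best_tanimoto_combo: float
    target_annotations: tuple[TargetAnnotation, ...]
    in_vitro_pc: bool
    in_vivo_pc: bool
    pc_trial: bool
    pc_target: bool
    rank: int = 0

    @property
    def n_flags(self) -> int:
        return sum((self.in_vitro_pc, self.in_vivo_pc, self.pc_trial, self.pc_target))


def classify_activity(value_nm: float) -> ActivityClass:
    """Potency class: <=1000 nM highly active, (1000, 10000) scarcely, >=10000 inactive.

    The exact 10 µM boundary is resolved to inactive.

    Raises
    ------
    DomainError
        If ``value_nm`` is not strictly positive.
    """
    if not value_nm > 0:
        raise DomainError(f"potency must be positive, got {value_nm}")
    if value_nm <= HIGHLY_ACTIVE_MAX_NM:
        label = ActivityLabel.HIGHLY_ACTIVE
    elif value_nm < INACTIVE_MIN_NM:
        label = ActivityLabel.SCARCELY_ACTIVE
    else:
        label = ActivityLabel.INACTIVE
    return ActivityClass(value_nm=value_nm, label=label)


def _disease_match(disease: str, terms: Sequence[str]) -> bool:
    d = str(disease).lower()
    return any(t in d for t in terms)


def annotate_candidates(
    hits: Sequence[OverlayScore],
    pair2d: Sequence[Pair2DScore],
    drug_meta: pd.DataFrame,
    drug_bioactivities: Sequence[BioactivityRecord],
    correlated_targets: Iterable[str],
    clinical_table: pd.DataFrame | None = None,
    disease_cell_lines: Iterable[str] = (),
    disease_terms: Sequence[str] = DEFAULT_DISEASE_TERMS,
) -> list[CandidateReport]:
    """Build one annotated report per distinct drug among the 3D survivors.

    ``drug_meta`` needs columns drug_id, name, max_phase; ``clinical_table``
    (optional) needs drug_id, disease and a ``source`` column distinguishing
    "trial" rows from "in_vivo" evidence rows. ``drug_bioactivities`` are
    the drugs' own measured records: cell-scope rows on a disease cell line
    set the in-vitro flag, target-scope rows become potency-class
    annotations and, on a correlated target with a non-inactive class, set
    the target flag. Missing drug metadata is logged and reported as nulls.
    """
    correlated = set(correlated_targets)
    cells = set(disease_cell_lines)
    meta = {str(r.drug_id): r for r in drug_meta.itertuples(index=False)}
    by_drug_bio: dict[str, list[BioactivityRecord]] = {}
    for r in drug_bioactivities:
        by_drug_bio.setdefault(r.compound_id, []).append(r)
    tc2d = {(p.drug_id, p.active_id): p for p in pair2d}

    best_hit: dict[str, OverlayScore] = {}
    for h in hits:
        cur = best_hit.get(h.drug_id)
        if cur is None or h.tanimoto_combo > cur.tanimoto_combo:
            best_hit[h.drug_id] = h

    trial_rows: dict[str, list] = {}
    invivo_rows: dict[str, list] = {}
    if clinical_table is not None:
        for row in clinical_table.itertuples(index=False):
            source = str(getattr(row, "source", "trial"))
            bucket = invivo_rows if source == "in_vivo" else trial_rows
            bucket.setdefault(str(row.drug_id), []).append(row)

    reports = []
    for drug_id in sorted(best_hit):
        hit = best_hit[drug_id]
        m = meta.get(drug_id)
        if m is None:
            logger.warning("no metadata for drug %s; emitting nulls", drug_id)
        p2d = tc2d.get((drug_id, hit.active_id))
        annotations: list[TargetAnnotation] = []
        in_vitro = False
        pc_target = False
        for rec in by_drug_bio.get(drug_id, []):
            if rec.activity_scope == "cell":
                if rec.scope_id in cells and classify_activity(
                    rec.standard_value
                ).label != ActivityLabel.INACTIVE:
                    in_vitro = True
            elif rec.activity_scope == "target":
                cls = classify_activity(rec.standard_value)
                is_corr = rec.scope_id in correlated
                annotations.append(
                    TargetAnnotation(
                        target_id=rec.scope_id,
                        value_nm=rec.standard_value,
                        label=cls.label,
                        is_correlated_target=is_corr,
                    )
                )
                if is_corr and cls.label != ActivityLabel.INACTIVE:
                    pc_target = True
        pc_trial = any(
            _disease_match(getattr(row, "disease", ""), disease_terms)
            for row in trial_rows.get(drug_id, [])
        )
        in_vivo = any(
            _disease_match(getattr(row, "disease", ""), disease_terms)
            for row in invivo_rows.get(drug_id, [])
        )
        reports.append(
            CandidateReport(
                drug_id=drug_id,
                name=str(m.name) if m is not None else "",
                max_phase=int(m.max_phase) if m is not None else 0,
                best_active_id=hit.active_id,
                best_tc_maccs=p2d.tc_maccs if p2d else float("nan"),
                best_tc_ecfp4=p2d.tc_ecfp4 if p2d else float("nan"),
                best_tanimoto_combo=hit.tanimoto_combo,
                target_annotations=tuple(
                    sorted(annotations, key=lambda a: (a.target_id, a.value_nm))
                ),
                in_vitro_pc=in_vitro,
                in_vivo_pc=in_vivo,
                pc_trial=pc_trial,
                pc_target=pc_target,
            )
        )
    return reports


def rank_candidates(reports: Sequence[CandidateReport]) -> list[CandidateReport]:
    """Assign a deterministic total order.

    Sort key: number of true criteria flags (desc), best TanimotoCombo
    (desc), max clinical phase (desc), then drug id (asc) as the final tie
    break. Ranks start at 1.
    """
    ordered = sorted(
        reports,
        key=lambda r: (-r.n_flags, -r.best_tanimoto_combo, -r.max_phase, r.drug_id),
    )
    return [
        CandidateReport(**{**_as_shallow_dict(r), "rank": i + 1})
        for i, r in enumerate(ordered)
    ]


def _as_shallow_dict(r: CandidateReport) -> dict:
    return {
        "drug_id": r.drug_id,
        "name": r.name,
        "max_phase": r.max_phase,
        "best_active_id": r.best_active_id,
        "best_tc_maccs": r.best_tc_maccs,
        "best_tc_ecfp4": r.best_tc_ecfp4,
        "best_tanimoto_combo": r.best_tanimoto_combo,
        "target_annotations": r.target_annotations,
        "in_vitro_pc": r.in_vitro_pc,
        "in_vivo_pc": r.in_vivo_pc,
        "pc_trial": r.pc_trial,
        "pc_target": r.pc_target,
        "rank": r.rank,
    }


def reports_to_frame(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    """Flatten ranked reports to a table (one row per drug)."""
    rows = []
    for r in reports:
        d = _as_shallow_dict(r)
        d["n_flags"] = r.n_flags
        d["n_target_annotations"] = len(r.target_annotations)
        d["correlated_targets_hit"] = ";".join(
            sorted({a.target_id for a in r.target_annotations if a.is_correlated_target})
        )
        del d["target_annotations"]
        rows.append(d)
    return pd.DataFrame(rows)


def write_report(reports: Sequence[CandidateReport], csv_path, json_path) -> None:
    """Write the ranked report as both delimited text and structured JSON.

    Output is byte-identical across runs on identical inputs: ordering is
    total and floats are serialized with repr-stable formatting. The report
    applies no multiple-testing correction anywhere upstream; the JSON
    footer records that.
    """
    frame = reports_to_frame(reports)
    frame.to_csv(csv_path, index=False, float_format="%.6f")
    doc = {
        "candidates": [
            {
                **_as_shallow_dict(r),
                "target_annotations": [
                    {
                        "target_id": a.target_id,
                        "value_nm": a.value_nm,
                        "label": a.label.value,
                        "is_correlated_target": a.is_correlated_target,
                    }
                    for a in r.target_annotations
                ],
                "n_flags": r.n_flags,
            }
            for r in reports
        ],
        "notes": "no multiple-testing correction applied in target correlation",
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
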