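"""End-to-end cascade: simulate/curate -> 2D -> 3D -> correlate -> report.

``run_all`` glues the stages together with one config object holding every
threshold of the method (2D Tanimoto cutoffs 0.8/0.3, TanimotoCombo 1.5,
the 1 µM activity cutoff, the 10-annotation floor, and the rho/p selection
criteria). All randomness flows from the master seed, so two runs with the
same config produce byte-identical report files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import correlation, curation, fingerprints, report, shape
from .simulate import SimulationConfig, SyntheticStudy, simulate_study, write_fixtures


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the cascade, with the method's defaults."""

    t_maccs: float = 0.8
    t_ecfp4: float = 0.3
    t_combo: float = 1.5
    potency_cutoff_nm: float = 1000.0
    mw_range: tuple[float, float] = (180.0, 850.0)
    min_annotations: int = 10
    rho_min: float = 0.40
    p_max: float = 0.05
    require_ci: bool = True
    n_conformers: int = 10
    ecfp4_length: int = 2048
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "mw_range" in raw:
            raw["mw_range"] = tuple(raw["mw_range"])
        return PipelineConfig(simulation=sim, **raw)


@dataclass
class PipelineResult:
    """Intermediate and final artifacts of one cascade run."""

    study: SyntheticStudy
    active_ids: list[str]
    drugs_screened: list
    pairs_2d: list
    survivors_2d: list
    overlays: list
    survivors_3d: list
    correlation_results: list
    selected_targets: list
    reports: list

    @property
    def counts(self) -> dict:
        return {
            "n_compounds": len(self.study.compounds),
            "n_actives": len(self.active_ids),
            "n_drugs_screened": len(self.drugs_screened),
            "n_pairs_2d": len(self.pairs_2d),
            "n_survivors_2d": len(self.survivors_2d),
            "n_survivors_3d": len(self.survivors_3d),
            "n_targets_tested": len(self.correlation_results),
            "n_targets_selected": len(self.selected_targets),
            "n_candidates": len(self.reports),
        }


def curate_study(study: SyntheticStudy, config: PipelineConfig):
    """Cell-record filtering, dedup and active selection on one study."""
    comp_map = {c.compound_id: c for c in study.compounds}
    cell = curation.dedup_best(curation.filter_cell_bioactivities(study.cell_records))
    active_ids = curation.select_actives(
        cell, comp_map, config.potency_cutoff_nm, config.mw_range
    )
    actives = [comp_map[cid] for cid in active_ids]
    drugs = curation.remove_overlap(study.drugs, actives)
    return cell, active_ids, actives, drugs


def run_all(
    config: PipelineConfig,
    out_dir=None,
    study: SyntheticStudy | None = None,
) -> PipelineResult:
    """Run every stage; optionally write fixtures and the ranked report.

    When ``study`` is None a synthetic study is generated from
    ``config.simulation``. With ``out_dir`` set, fixture files plus
    ``report.csv``/``report.json`` are written there.
    """
    if study is None:
        study = simulate_study(config.simulation)
    comp_map = {c.compound_id: c for c in study.compounds}
    cell_dedup, active_ids, actives, drugs = curate_study(study, config)

    pairs = fingerprints.all_against_all_2d(drugs, actives, config.ecfp4_length)
    survivors_2d = fingerprints.cascade_filter_2d(pairs, config.t_maccs, config.t_ecfp4)

    seed = int(study.config.seed)
    conf_cache: dict[str, shape.ConformerSet] = {}

    def conformers_for(compound):
        key = compound.compound_id
        if key not in conf_cache:
            conf_cache[key] = shape.generate_conformers(
                compound, n=config.n_conformers, seed=seed
            )
        return conf_cache[key]

    drug_map = {d.compound_id: d for d in drugs}
    overlays = []
    for p in survivors_2d:
        ov = shape.tanimoto_combo(
            conformers_for(drug_map[p.drug_id]), conformers_for(comp_map[p.active_id])
        )
        overlays.append(ov)
    survivors_3d = shape.cascade_filter_3d(overlays, config.t_combo)

    target_clean = correlation.filter_target_bioactivities(study.target_records)
    kept_targets = correlation.min_annotation_filter(target_clean, config.min_annotations)
    by_target = {
        t: [r for r in target_clean if r.scope_id == t] for t in kept_targets
    }
    results = []
    for t in kept_targets:
        for line in study.config.cell_lines:
            vec = correlation.build_pairs(by_target[t], cell_dedup, line)
            results.append(
                correlation.correlate(
                    vec, config.rho_min, config.p_max, config.require_ci
                )
            )
    selected = correlation.select_targets(
        results, config.rho_min, config.p_max, config.require_ci
    )
    selected_ids = sorted({r.target_id for r in selected})

    reports = report.rank_candidates(
        report.annotate_candidates(
            hits=survivors_3d,
            pair2d=pairs,
            drug_meta=study.drug_meta,
            drug_bioactivities=study.drug_bioactivities,
            correlated_targets=selected_ids,
            clinical_table=study.clinical,
            disease_cell_lines=study.config.cell_lines,
        )
    )

    result = PipelineResult(
        study=study,
        active_ids=active_ids,
        drugs_screened=drugs,
        pairs_2d=pairs,
        survivors_2d=survivors_2d,
        overlays=overlays,
        survivors_3d=survivors_3d,
        correlation_results=results,
        selected_targets=selected,
        reports=reports,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fixtures(study, out / "fixtures")
        report.write_report(reports, out / "report.csv", out / "report.json")
        from .io import overlay_to_frame, pair2d_to_frame

        pair2d_to_frame(pairs, survivors_2d).to_csv(
            out / "similarity_2d.csv", index=False, float_format="%.6f"
        )
        overlay_to_frame(overlays).to_csv(
            out / "similarity_3d.csv", index=False, float_format="%.6f"
        )
        corr_rows = [
            {
                "target_id": r.target_id,
                "cell_line": r.cell_line,
                "n": r.n,
                "rho": r.rho,
                "p_value": r.p_value,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "selected": r.selected,
            }
            for r in results
        ]
        import pandas as pd

        pd.DataFrame(corr_rows).to_csv(
            out / "target_correlations.csv", index=False, float_format="%.6g"
        )
    return result
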