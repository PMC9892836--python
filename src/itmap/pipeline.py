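"""End-to-end runs: inputs -> mapping -> scoring -> statistics -> report.

A run takes a reference mesh (built parametrically or loaded from
OBJ/PLY + sidecar), per-patient lesion and landmark tables, and a
clinical cohort table; it standardizes every evaluable patient onto the
reference, scores drainage concordance, tabulates match patterns by
site, compares sites, optionally measures primary-to-ITM skin-surface
distances, runs the cohort risk-factor statistics, and writes all
tables plus a self-describing JSON report (package version, seed,
config hash).  Reruns with identical config and seed produce a
byte-identical report body.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import compare_sites, score_concordance, tabulate_patterns
from .drainage import UnevaluablePatientError, map_patient
from .geodesic import GeodesicEngine, distance_summary
from .io import (
    SchemaError,
    read_cohort_csv,
    read_landmarks_csv,
    read_lesions_csv,
    write_cohort_csv,
    write_landmarks_csv,
    write_lesions_csv,
)
from .leg_model import (
    LegShapeParams,
    LegSurface,
    build_reference_leg,
    load_leg,
    project_views,
    save_leg,
    segment_zones,
)
from .cohort_stats import estimates_to_frame, logistic_risk_model
from .registration import PatientLesionSet
from .synthetic import SimulationConfig, paper_like_config, simulate_cohort, simulate_lesions


@dataclass
class PipelineConfig:
    """Run options; file values override defaults, CLI flags override both."""

    seed: int = 0
    resolution: int = 24
    refinement: int = 2
    snap_threshold_cm: float = 3.0
    phi_leg: float | None = None  # None -> solved preset values
    phi_foot: float | None = None
    include_distances: bool = True
    boundary_meridians_deg: tuple = (0.0, 90.0, 180.0, 270.0)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_zoned_reference(config: PipelineConfig) -> LegSurface:
    leg = build_reference_leg(LegShapeParams(), resolution=config.resolution)
    return segment_zones(leg, boundary_spec=config.boundary_meridians_deg)


def _sim_config(config: PipelineConfig) -> SimulationConfig:
    cfg = paper_like_config(seed=config.seed)
    overrides = {}
    if config.phi_leg is not None:
        overrides["phi_leg"] = config.phi_leg
    if config.phi_foot is not None:
        overrides["phi_foot"] = config.phi_foot
    if overrides:
        from dataclasses import replace

        cfg = replace(cfg, **overrides)
    return cfg


def write_fixture(outdir: str | Path, config: PipelineConfig | None = None) -> dict:
    """Write a complete demo dataset: mesh + template + tables + config.

    The lesion/landmark tables contain the simulated ITM patients with
    melanoma of the foot or lower leg (the evaluable subset); the cohort
    table contains the full simulated case-control cohort.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = build_zoned_reference(config)
    save_leg(reference, outdir / "reference_leg.obj")
    template = project_views(reference)
    (outdir / "zone_template.json").write_text(template.to_json())

    sim = _sim_config(config)
    cohort = simulate_cohort(sim)
    write_cohort_csv(cohort, outdir / "cohort.csv")

    evaluable = cohort[cohort["has_itm"] & cohort["site"].isin(["foot", "lower_leg"])]
    patients, landmarks = [], {}
    for i, (_idx, row) in enumerate(evaluable.iterrows()):
        sp = simulate_lesions(sim, row, reference, index=i)
        patients.append(sp.observed)
        landmarks[sp.observed.patient_id] = sp.observed.landmarks
    write_lesions_csv(patients, outdir / "lesions.csv")
    write_landmarks_csv(landmarks, outdir / "landmarks.csv")
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=1, default=list))
    return {
        "outdir": str(outdir),
        "n_cohort": len(cohort),
        "n_evaluable": len(evaluable),
        "files": sorted(p.name for p in outdir.iterdir()),
    }


def run_pipeline(
    config: PipelineConfig,
    mesh_path: str | Path | None = None,
    lesions_path: str | Path | None = None,
    landmarks_path: str | Path | None = None,
    cohort_path: str | Path | None = None,
    outdir: str | Path = "itmap_run",
) -> dict:
    """Execute the full analysis and write tables + JSON report.

    Without input paths, a synthetic dataset at the configured seed is
    generated in memory (the demo mode).  Validation failures (unknown
    patient ids, schema violations) raise ``SchemaError``; patients
    without exactly one primary are listed as unevaluable and excluded,
    mirroring the evaluability screen of a clinical photo archive.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if mesh_path is not None:
        reference = load_leg(mesh_path)
        if reference.zone_of_face is None:
            reference = segment_zones(reference, boundary_spec=config.boundary_meridians_deg)
    else:
        reference = build_zoned_reference(config)

    sim = _sim_config(config)
    if lesions_path is not None:
        lesion_groups = read_lesions_csv(lesions_path)
        landmark_groups = read_landmarks_csv(landmarks_path) if landmarks_path else {}
        cohort = read_cohort_csv(cohort_path) if cohort_path else None
        patients = [
            PatientLesionSet(
                patient_id=pid,
                side=lesions[0].side,
                lesions=lesions,
                landmarks=landmark_groups.get(pid, {}),
            )
            for pid, lesions in lesion_groups.items()
        ]
    else:
        cohort = simulate_cohort(sim)
        evaluable = cohort[cohort["has_itm"] & cohort["site"].isin(["foot", "lower_leg"])]
        patients = []
        for i, (_idx, row) in enumerate(evaluable.iterrows()):
            sp = simulate_lesions(sim, row, reference, index=i)
            patients.append(sp.observed)

    if cohort is not None:
        known = set(cohort["patient_id"].astype(str))
        for ps in patients:
            if ps.patient_id not in known:
                raise SchemaError(
                    f"lesion table references unknown patient {ps.patient_id!r}"
                )

    site_of = {}
    if cohort is not None:
        site_of = dict(zip(cohort["patient_id"].astype(str), cohort["site"]))

    engine = GeodesicEngine(reference, refinement=config.refinement) if config.include_distances else None
    results, unevaluable, tables, dist_rows = [], [], [], []
    for ps in patients:
        try:
            pm = map_patient(ps, reference, snap_threshold_cm=config.snap_threshold_cm)
        except UnevaluablePatientError as exc:
            unevaluable.append({"patient_id": ps.patient_id, "reason": str(exc)})
            continue
        site = site_of.get(ps.patient_id, ps.lesions[0].site)
        itm_zones = pm.itm_zones()
        if itm_zones:
            results.append(
                score_concordance(pm.primary_zone, itm_zones, ps.patient_id, site)
            )
        tables.append(pm.table)
        if engine is not None:
            prim = [l for l in pm.lesions if l.role == "primary"][0]
            itms = [l for l in pm.lesions if l.role == "itm" and not l.unmappable]
            if itms:
                d = engine.distances_from(prim, itms)
                dist_rows.extend(
                    {
                        "patient_id": l.patient_id,
                        "lesion_id": l.lesion_id,
                        "site": site,
                        "distance_cm": round(float(dd), 1),
                    }
                    for l, dd in zip(itms, d)
                )

    mapped = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    mapped.to_csv(outdir / "mapped_lesions.csv", index=False)
    pattern = tabulate_patterns(results)
    pattern.counts.to_csv(outdir / "pattern_counts.csv")
    pattern.percentages.to_csv(outdir / "pattern_percentages.csv")
    report: dict = {
        "itmap_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_patients_mapped": len(tables),
        "unevaluable": unevaluable,
        "patterns": pattern.to_json_dict(),
    }
    if len(pattern.counts.columns) == 2:
        cmp_res = compare_sites(pattern)
        report["site_comparison"] = {
            "u": cmp_res.u,
            "z": round(cmp_res.z, 3),
            "p": round(cmp_res.p, 3),
        }
    if dist_rows:
        dist_df = pd.DataFrame(dist_rows)
        dist_df.to_csv(outdir / "distances.csv", index=False)
        report["distance_summary"] = distance_summary(dist_df)
    if cohort is not None:
        uni = logistic_risk_model(cohort, mode="univariate")
        multi = logistic_risk_model(cohort, mode="multivariate")
        or_table = pd.concat([estimates_to_frame(uni), estimates_to_frame(multi)])
        or_table.to_csv(outdir / "odds_ratios.csv", index=False)
        report["odds_ratios"] = or_table.round(4).to_dict(orient="records")
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
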