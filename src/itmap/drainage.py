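"""Assignment of mapped lesions to lymphatic drainage territories.

A lesion anchored on the zoned reference mesh inherits the zone of its
anchoring face (3D route).  On a 2D template view, a point takes the
zone of the polygon containing it (2D route); the two routes agree for
points whose faces are front-facing in the view, because the template
polygons are projections of exactly those faces.

``map_patient`` composes the full standardization chain for one
patient: mirror (right legs) -> rigid landmark registration -> surface
transfer -> zone assignment -> template projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .leg_model import VIEW_AXES, LegSurface, ZoneTemplate, project_point
from .registration import (
    Lesion,
    PatientLesionSet,
    fit_rigid_transform,
    mirror_to_left,
    transfer_lesions,
)
from .zones import ZoneId


class UnanchoredLesionError(RuntimeError):
    """3D zone lookup on a lesion without a surface anchor."""


class OutOfTemplateError(ValueError):
    """2D point outside the view silhouette."""


class UnevaluablePatientError(ValueError):
    """Patient without exactly one primary melanoma."""


def assign_zone_3d(mesh: LegSurface, lesion: Lesion) -> ZoneId:
    """Drainage territory of an anchored lesion: zone of its face."""
    if not lesion.anchored:
        raise UnanchoredLesionError(f"lesion {lesion.lesion_id} is not anchored")
    if mesh.zone_of_face is None:
        raise UnanchoredLesionError("mesh has no zone assignment")
    return ZoneId(int(mesh.zone_of_face[lesion.face]))


def assign_zone_2d(point, view: str, template: ZoneTemplate) -> ZoneId:
    """Drainage territory of a 2D template point.

    Zones are probed in enumeration order and boundaries are inclusive,
    so a point on a shared polygon edge resolves to the zone with the
    lower enumeration value (documented tie-break).
    """
    p = Point(float(point[0]), float(point[1]))
    zones_here = dict(template.views[view])
    for zone in ZoneId:
        geom = zones_here.get(zone)
        if geom is not None and geom.covers(p):
            return zone
    raise OutOfTemplateError(
        f"point ({p.x:.2f}, {p.y:.2f}) lies outside the {view} silhouette"
    )


def best_view(mesh: LegSurface, lesion: Lesion) -> str:
    """View in which the lesion's face is most front-facing."""
    normal = mesh.face_normals()[lesion.face]
    scores = {v: float(normal @ d) for v, (d, _u) in VIEW_AXES.items()}
    return max(sorted(scores), key=scores.get)


@dataclass
class PatientMap:
    """Outcome of mapping one patient onto the reference."""

    patient_id: str
    table: pd.DataFrame  # lesion_id, role, site, view, u_cm, v_cm, zone, snap_cm, unmappable
    lesions: list[Lesion]  # anchored on the reference, analysis order
    registration_rms: float

    @property
    def primary_zone(self) -> ZoneId:
        row = self.table[self.table["role"] == "primary"].iloc[0]
        return ZoneId[row["zone"].upper()]

    def itm_zones(self) -> list[ZoneId]:
        sel = (self.table["role"] == "itm") & (~self.table["unmappable"])
        return [ZoneId[z.upper()] for z in self.table.loc[sel, "zone"]]


def map_patient(
    patient: PatientLesionSet,
    reference: LegSurface,
    template: ZoneTemplate | None = None,
    snap_threshold_cm: float = 3.0,
    allow_scale: bool = False,
) -> PatientMap:
    """Standardize one patient's lesions onto the reference leg.

    Requires exactly one primary melanoma; otherwise the patient is
    unevaluable and an error is raised (such patients are excluded from
    concordance analysis, mirroring the evaluability screen applied to
    clinical photographs).
    """
    n_primary = len(patient.primaries)
    if n_primary != 1:
        raise UnevaluablePatientError(
            f"patient {patient.patient_id}: {n_primary} primaries (need exactly 1)"
        )
    lesions, landmarks = mirror_to_left(patient.lesions, patient.landmarks)
    transform, rms = fit_rigid_transform(
        landmarks, {k: reference.landmark_point(k) for k in reference.landmarks},
        allow_scale=allow_scale,
    )
    anchored = transfer_lesions(
        lesions, transform, reference, snap_threshold_cm=snap_threshold_cm
    )

    rows = []
    for l in anchored:
        zone = assign_zone_3d(reference, l)
        view = best_view(reference, l)
        u, v = project_point(l.location(reference), view)
        rows.append(
            {
                "patient_id": l.patient_id,
                "lesion_id": l.lesion_id,
                "role": l.role,
                "site": l.site,
                "view": view,
                "u_cm": round(u, 3),
                "v_cm": round(v, 3),
                "zone": zone.name.lower(),
                "snap_cm": round(l.snap_distance, 3),
                "unmappable": l.unmappable,
            }
        )
    table = pd.DataFrame(rows)
    return PatientMap(
        patient_id=patient.patient_id,
        table=table,
        lesions=anchored,
        registration_rms=rms,
    )


def render_template(
    template: ZoneTemplate,
    patient_maps: list[PatientMap] | None = None,
    path=None,
):
    """Draw the four views with zone colors and optional lesions.

    Primary lesions are drawn black, in-transit metastases red (the
    conventional display).  Returns the matplotlib figure; saves to
    ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .zones import ZONE_COLORS

    fig, axes = plt.subplots(1, 4, figsize=(16, 6), sharey=True)
    order = ["lateral", "medial", "anterior", "dorsal"]
    for ax, view in zip(axes, order):
        for zone, geom in template.views[view]:
            polys = getattr(geom, "geoms", [geom])
            for pp in polys:
                x, y = pp.exterior.xy
                ax.fill(x, y, color=ZONE_COLORS[zone], alpha=0.45, lw=0.3)
        if patient_maps:
            for pm in patient_maps:
                sel = pm.table[pm.table["view"] == view]
                for _i, row in sel.iterrows():
                    ax.plot(
                        row["u_cm"],
                        row["v_cm"],
                        "o",
                        ms=5,
                        color="black" if row["role"] == "primary" else "red",
                    )
        ax.set_title(view)
        ax.set_aspect("equal")
        ax.set_xlabel("u (cm)")
    axes[0].set_ylabel("z (cm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
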