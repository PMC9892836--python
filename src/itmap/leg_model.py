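"""Canonical left lower-limb surface model.

The reference leg is a parametric triangle mesh: a tube of elliptical
cross-sections swept along an L-shaped centerline (foot -> ankle bend ->
lower leg -> thigh), capped at the toes and the proximal thigh.  It is a
deliberately simplified, fully reproducible stand-in for a photographic
3D body-surface template: zones, areas, surface distances and landmark
positions are all computable in closed form or by deterministic mesh
operations.

Canonical frame (left leg): +z proximal (toes to knee), +y anterior,
+x medial; units cm.  Right-sided patient data are mirrored (x -> -x)
before any analysis so a left leg is always analyzed.

Bone landmarks placed analytically on the surface: patella,
medial_malleolus, lateral_malleolus, toe_tip_1 (hallux, medial) and
toe_tip_5 (little toe, lateral).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .zones import (
    DEFAULT_MERIDIANS_DEG,
    ZoneId,
    classify_angle,
    sectors_from_meridians,
)

REQUIRED_LANDMARKS = frozenset(
    {"patella", "medial_malleolus", "lateral_malleolus", "toe_tip_1", "toe_tip_5"}
)

SITES = ("foot", "lower_leg", "thigh")

#: Orthographic views: name -> (unit direction from surface toward the
#: viewer, horizontal screen axis).  The vertical screen axis is always +z.
VIEW_AXES = {
    "anterior": (np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0])),
    "dorsal": (np.array([0.0, -1.0, 0.0]), np.array([-1.0, 0.0, 0.0])),
    "medial": (np.array([1.0, 0.0, 0.0]), np.array([0.0, -1.0, 0.0])),
    "lateral": (np.array([-1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])),
}


class GeometryParameterError(ValueError):
    """Invalid leg-shape parameters."""


@dataclass(frozen=True)
class LegShapeParams:
    """Segment lengths and radii of the parametric leg, in cm.

    Defaults approximate an adult lower limb: 24 cm foot, 38 cm shank
    with a calf bulge, 40 cm thigh.
    """

    foot_length: float = 24.0
    foot_half_width: float = 4.5
    foot_half_height: float = 3.5
    ankle_radius: float = 4.0
    lower_leg_length: float = 38.0
    calf_radius: float = 5.5
    knee_radius: float = 5.0
    thigh_length: float = 40.0
    thigh_radius: float = 7.5
    toe_taper: float = 0.75
    toe_fraction: float = 0.25

    def validate(self) -> None:
        positive = (
            self.foot_length,
            self.foot_half_width,
            self.foot_half_height,
            self.ankle_radius,
            self.lower_leg_length,
            self.calf_radius,
            self.knee_radius,
            self.thigh_length,
            self.thigh_radius,
            self.toe_taper,
        )
        if any(v <= 0 for v in positive):
            raise GeometryParameterError("all lengths, radii and taper must be positive")
        if not 0.0 < self.toe_fraction < 1.0:
            raise GeometryParameterError("toe_fraction must be in (0, 1)")
        if self.foot_length <= 2.0 * self.ankle_radius:
            raise GeometryParameterError("foot_length must exceed the ankle bend radius")


@dataclass
class LegSurface:
    """Triangle mesh of the canonical left leg with anatomy annotations.

    ``zone_of_face`` is ``None`` until :func:`segment_zones` runs.
    """

    vertices: np.ndarray  # (n, 3) float, cm
    faces: np.ndarray  # (m, 3) int
    landmarks: dict[str, int]
    site_of_face: np.ndarray  # (m,) str in SITES
    toe_face_mask: np.ndarray  # (m,) bool
    plantar_face_mask: np.ndarray  # (m,) bool
    stations: np.ndarray  # (k, 3) centerline ring centers
    station_frames: np.ndarray  # (k, 2, 3): rows (x_hat medial, n_hat anterior)
    zone_of_face: np.ndarray | None = None  # (m,) int ZoneId values
    shape_params: LegShapeParams | None = None
    _trimesh: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    # -- basic geometry -------------------------------------------------
    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def landmark_point(self, name: str) -> np.ndarray:
        return self.vertices[self.landmarks[name]]

    # -- cross-sectional angle ------------------------------------------
    def sector_angle_deg(self, points: np.ndarray) -> np.ndarray:
        """Cross-sectional angle of surface points around the limb axis.

        Each point is referred to its nearest centerline station; the
        angle is measured in that station's cross-section plane from the
        medial axis (+x) counter-clockwise toward the anterior axis, in
        [0, 360).  This is the coordinate in which drainage sectors are
        angular intervals.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.stations[None, :, :]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)
        rel = pts - self.stations[idx]
        x_hat = self.station_frames[idx, 0]
        n_hat = self.station_frames[idx, 1]
        ang = np.degrees(
            np.arctan2((rel * n_hat).sum(axis=1), (rel * x_hat).sum(axis=1))
        )
        return ang % 360.0

    def zones_present(self) -> set[ZoneId]:
        if self.zone_of_face is None:
            return set()
        return {ZoneId(z) for z in np.unique(self.zone_of_face)}


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _ring_count(length: float, spacing: float) -> int:
    return max(3, int(round(length / spacing)))


def build_reference_leg(
    params: LegShapeParams | None = None, resolution: int = 24
) -> LegSurface:
    """Build the canonical left-leg mesh.

    ``resolution`` is the number of circumferential segments per ring; it
    must be a multiple of 4 and at least 8 so that the medial, anterior,
    lateral and posterior meridians pass through mesh vertices — landmark
    positions are then closed-form and independent of resolution.

    The returned mesh is watertight, connected and deterministic for
    fixed parameters.  Zones are not yet assigned; see
    :func:`segment_zones`.
    """
    p = params or LegShapeParams()
    p.validate()
    if resolution < 8 or resolution % 4 != 0:
        raise GeometryParameterError("resolution must be a multiple of 4, >= 8")

    fw, fh = p.foot_half_width, p.foot_half_height
    z_f = fh  # foot centerline height above the sole plane z=0
    rb = p.ankle_radius  # ankle bend radius
    z_ankle = z_f + rb
    z_knee = z_ankle + p.lower_leg_length
    z_top = z_knee + p.thigh_length
    spacing = 2.0 * np.pi * 5.0 / resolution  # axial ~ circumferential edge

    # stations: (center, tangent, a, b, site, is_toe)
    stations: list[tuple[np.ndarray, np.ndarray, float, float, str, bool]] = []

    # foot: straight from toe (y = foot_length) to bend start (y = rb)
    L_straight = p.foot_length - rb
    nf = _ring_count(L_straight, spacing)
    toe_len = p.toe_fraction * p.foot_length
    for i in range(nf + 1):
        s = i / nf * L_straight  # arc distance from the toe ring
        y = p.foot_length - s
        scale = p.toe_taper + (1 - p.toe_taper) * min(1.0, s / (0.5 * L_straight))
        if i == 0:
            scale = p.toe_taper  # exact, resolution-independent toe ring
        stations.append(
            (
                np.array([0.0, y, z_f]),
                np.array([0.0, -1.0, 0.0]),
                fw * scale,
                fh * scale,
                "foot",
                s < toe_len,
            )
        )

    # ankle bend: quarter arc, tangent -y -> +z, center (0, rb, z_ankle)
    nb = _ring_count(rb * np.pi / 2, spacing)
    for i in range(1, nb + 1):
        t = i / nb * (np.pi / 2)
        c = np.array([0.0, rb - rb * np.sin(t), z_ankle - rb * np.cos(t)])
        tangent = np.array([0.0, -np.cos(t), np.sin(t)])
        a = fw + (p.ankle_radius - fw) * (i / nb)
        b = fh + (p.ankle_radius - fh) * (i / nb)
        stations.append((c, tangent, a, b, "foot", False))

    # lower leg: ankle -> knee, calf bulge at 40 % of shank height
    ns = _ring_count(p.lower_leg_length, spacing)
    for i in range(1, ns + 1):
        f = i / ns
        r = np.interp(f, [0.0, 0.4, 1.0], [p.ankle_radius, p.calf_radius, p.knee_radius])
        stations.append(
            (
                np.array([0.0, 0.0, z_ankle + f * p.lower_leg_length]),
                np.array([0.0, 0.0, 1.0]),
                r,
                r,
                "lower_leg",
                False,
            )
        )
    knee_station_index = len(stations) - 1

    # thigh: knee -> proximal cap
    nt = _ring_count(p.thigh_length, spacing)
    for i in range(1, nt + 1):
        f = i / nt
        r = np.interp(f, [0.0, 0.7, 1.0], [p.knee_radius, p.thigh_radius, p.thigh_radius])
        stations.append(
            (
                np.array([0.0, 0.0, z_knee + f * p.thigh_length]),
                np.array([0.0, 0.0, 1.0]),
                r,
                r,
                "thigh",
                False,
            )
        )

    # rings of vertices
    K = resolution
    theta = np.arange(K) * (2.0 * np.pi / K)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    verts: list[np.ndarray] = []
    frames = np.empty((len(stations), 2, 3))
    centers = np.empty((len(stations), 3))
    x_hat = np.array([1.0, 0.0, 0.0])
    for k, (c, tangent, a, b, _site, _toe) in enumerate(stations):
        n_hat = np.cross(tangent, x_hat)
        n_hat /= np.linalg.norm(n_hat)
        ring = c + np.outer(a * cos_t, x_hat) + np.outer(b * sin_t, n_hat)
        verts.append(ring)
        centers[k] = c
        frames[k, 0] = x_hat
        frames[k, 1] = n_hat
    vertices = np.vstack(verts)

    faces: list[tuple[int, int, int]] = []
    f_site: list[str] = []
    f_toe: list[bool] = []
    for k in range(len(stations) - 1):
        base0, base1 = k * K, (k + 1) * K
        site = stations[k][4]
        toe = stations[k][5] and stations[k + 1][5]
        for j in range(K):
            jn = (j + 1) % K
            # outward orientation: rings wind CCW seen along the tangent
            faces.append((base0 + j, base0 + jn, base1 + j))
            faces.append((base0 + jn, base1 + jn, base1 + j))
            f_site.extend((site, site))
            f_toe.extend((toe, toe))

    # toe cap (fan around the toe ring center) and proximal thigh cap
    toe_center_idx = len(vertices)
    vertices = np.vstack([vertices, centers[0]])
    for j in range(K):
        faces.append((toe_center_idx, (j + 1) % K, j))
        f_site.append("foot")
        f_toe.append(True)
    top_center_idx = len(vertices)
    vertices = np.vstack([vertices, centers[-1]])
    top_base = (len(stations) - 1) * K
    for j in range(K):
        faces.append((top_center_idx, top_base + j, top_base + (j + 1) % K))
        f_site.append("thigh")
        f_toe.append(False)

    faces_arr = np.asarray(faces, dtype=int)
    site_arr = np.asarray(f_site)
    toe_arr = np.asarray(f_toe, dtype=bool)

    leg = LegSurface(
        vertices=vertices,
        faces=faces_arr,
        landmarks={},
        site_of_face=site_arr,
        toe_face_mask=toe_arr,
        plantar_face_mask=np.zeros(len(faces_arr), dtype=bool),
        stations=centers,
        station_frames=frames,
        shape_params=p,
    )

    # plantar: foot faces whose centroid sits in the lower half of the
    # cross-section (sole and heel)
    cent = leg.face_centroids()
    ang = leg.sector_angle_deg(cent)
    leg.plantar_face_mask = (site_arr == "foot") & (np.sin(np.radians(ang)) < 0)

    # landmarks at analytic meridian vertices (theta = 0 medial, 90 anterior,
    # 180 lateral); ring 0 is the toe rim, the ankle ring ends the bend arc
    q = K // 4
    ankle_ring = nf + nb
    leg.landmarks = {
        "toe_tip_1": 0,  # (fw*taper, foot_length, z_f)
        "toe_tip_5": 2 * q,  # (-fw*taper, foot_length, z_f)
        "medial_malleolus": ankle_ring * K,
        "lateral_malleolus": ankle_ring * K + 2 * q,
        "patella": knee_station_index * K + q,
    }
    return leg


def expected_landmark_positions(params: LegShapeParams | None = None) -> dict[str, np.ndarray]:
    """Closed-form landmark coordinates implied by the shape parameters.

    Independent of mesh resolution; used to validate construction.
    """
    p = params or LegShapeParams()
    z_f = p.foot_half_height
    z_ankle = z_f + p.ankle_radius
    z_knee = z_ankle + p.lower_leg_length
    a_toe = p.foot_half_width * p.toe_taper
    return {
        "toe_tip_1": np.array([a_toe, p.foot_length, z_f]),
        "toe_tip_5": np.array([-a_toe, p.foot_length, z_f]),
        "medial_malleolus": np.array([p.ankle_radius, 0.0, z_ankle]),
        "lateral_malleolus": np.array([-p.ankle_radius, 0.0, z_ankle]),
        "patella": np.array([0.0, p.knee_radius, z_knee]),
    }


# ---------------------------------------------------------------------------
# zone segmentation
# ---------------------------------------------------------------------------


def segment_zones(
    mesh: LegSurface,
    boundary_spec=DEFAULT_MERIDIANS_DEG,
    plantar_zone: ZoneId | None = ZoneId.ANTEROMEDIAL,
) -> LegSurface:
    """Assign every face to a drainage territory.

    Faces are classified by the cross-sectional angle of their centroid
    into the four sectors delimited by ``boundary_spec`` meridians.  Two
    overrides reflect the anatomy of the distal limb: toe-region faces
    always drain anteromedially, and plantar faces drain to
    ``plantar_zone`` (default anteromedial; pass ``None`` to disable —
    plantar drainage is not well characterized anatomically).

    Fills ``mesh.zone_of_face`` in place and returns the mesh.
    """
    sectors = sectors_from_meridians(boundary_spec)
    ang = mesh.sector_angle_deg(mesh.face_centroids())
    zones = classify_angle(ang, sectors)
    zones[mesh.toe_face_mask] = int(ZoneId.ANTEROMEDIAL)
    if plantar_zone is not None:
        zones[mesh.plantar_face_mask] = int(plantar_zone)
    mesh.zone_of_face = zones
    return mesh


# ---------------------------------------------------------------------------
# 2D templates
# ---------------------------------------------------------------------------


class TemplateStateError(RuntimeError):
    """Template requested from a mesh without zone assignment."""


@dataclass
class ZoneTemplate:
    """Four orthographic 2D views of the zoned leg.

    Per view: interior-disjoint zone polygons (built in ``ZoneId`` order,
    later zones clipped against earlier ones, so their union is exactly
    the view silhouette) and the visible landmark points.  Coordinates
    (u, v) in cm; v is always the axial coordinate z.
    """

    views: dict[str, list[tuple[ZoneId, Polygon | MultiPolygon]]]
    silhouettes: dict[str, Polygon | MultiPolygon]
    landmarks_2d: dict[str, dict[str, tuple[float, float]]]

    def to_json(self) -> str:
        def geom_coords(g):
            polys = g.geoms if isinstance(g, MultiPolygon) else [g]
            return [list(map(list, pp.exterior.coords)) for pp in polys]

        payload = {
            "views": {
                v: [[z.name.lower(), geom_coords(g)] for z, g in zones]
                for v, zones in self.views.items()
            },
            "silhouettes": {v: geom_coords(g) for v, g in self.silhouettes.items()},
            "landmarks_2d": self.landmarks_2d,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ZoneTemplate":
        raw = json.loads(text)

        def build(rings):
            polys = [Polygon(r) for r in rings]
            return polys[0] if len(polys) == 1 else MultiPolygon(polys)

        views = {
            v: [(ZoneId[name.upper()], build(rings)) for name, rings in zones]
            for v, zones in raw["views"].items()
        }
        sil = {v: build(r) for v, r in raw["silhouettes"].items()}
        lm = {
            v: {k: tuple(pt) for k, pt in d.items()}
            for v, d in raw["landmarks_2d"].items()
        }
        return cls(views=views, silhouettes=sil, landmarks_2d=lm)


def project_point(point: np.ndarray, view: str) -> tuple[float, float]:
    """Orthographic (u, v) coordinates of a 3D point in a view."""
    _d, u_axis = VIEW_AXES[view]
    p = np.asarray(point, dtype=float)
    return float(p @ u_axis), float(p[2])


def project_views(mesh: LegSurface, min_area: float = 1e-9) -> ZoneTemplate:
    """Project the zoned mesh into the four standard views.

    Only front-facing faces (outward normal toward the viewer) contribute
    to a view.  Zone polygons are unions of projected triangles, clipped
    in ``ZoneId`` order so that within a view they are interior-disjoint
    and tile the silhouette exactly.
    """
    if mesh.zone_of_face is None:
        raise TemplateStateError("segment_zones must run before project_views")
    normals = mesh.face_normals()
    views: dict[str, list[tuple[ZoneId, Polygon | MultiPolygon]]] = {}
    silhouettes: dict[str, Polygon | MultiPolygon] = {}
    landmarks_2d: dict[str, dict[str, tuple[float, float]]] = {}

    tri3 = mesh.vertices[mesh.faces]  # (m, 3, 3)
    # vertex visibility via incident faces
    for view, (d, u_axis) in VIEW_AXES.items():
        front = (normals @ d) > 0.0
        uv = np.stack([tri3 @ u_axis, tri3[:, :, 2]], axis=-1)  # (m, 3, 2)
        claimed = None
        zone_polys: list[tuple[ZoneId, Polygon | MultiPolygon]] = []
        for zone in ZoneId:
            sel = front & (mesh.zone_of_face == int(zone))
            if not sel.any():
                continue
            tris = [Polygon(t) for t in uv[sel] if Polygon(t).area > 0]
            merged = unary_union(tris).buffer(0)
            if claimed is not None:
                merged = merged.difference(claimed)
            merged = _clean_polygonal(merged, min_area)
            if merged is None:
                continue
            claimed = merged if claimed is None else unary_union([claimed, merged])
            zone_polys.append((zone, merged))
        views[view] = zone_polys
        silhouettes[view] = unary_union([g for _z, g in zone_polys]).buffer(0)

        vis: dict[str, tuple[float, float]] = {}
        for name, vi in mesh.landmarks.items():
            incident = np.any(mesh.faces == vi, axis=1)
            if (normals[incident] @ d > 0).any():
                vis[name] = project_point(mesh.vertices[vi], view)
        landmarks_2d[view] = vis

    return ZoneTemplate(views=views, silhouettes=silhouettes, landmarks_2d=landmarks_2d)


def _clean_polygonal(geom, min_area: float):
    """Keep only polygonal parts above a tiny area floor."""
    if geom.is_empty:
        return None
    if isinstance(geom, Polygon):
        return geom if geom.area > min_area else None
    parts = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon) and g.area > min_area]
    if not parts:
        return None
    return parts[0] if len(parts) == 1 else MultiPolygon(parts)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_leg(mesh: LegSurface, mesh_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write the mesh as ASCII OBJ/PLY plus a JSON sidecar of annotations."""
    mesh_path = Path(mesh_path)
    if mesh_path.suffix.lower() == ".ply":
        mesh.trimesh.export(mesh_path, encoding="ascii")
    else:
        mesh.trimesh.export(mesh_path)
    sidecar = Path(sidecar_path) if sidecar_path else mesh_path.with_suffix(".json")
    payload = {
        "landmarks": mesh.landmarks,
        "zone_of_face": None
        if mesh.zone_of_face is None
        else [int(z) for z in mesh.zone_of_face],
        "site_of_face": mesh.site_of_face.tolist(),
        "toe_face_mask": mesh.toe_face_mask.astype(int).tolist(),
        "plantar_face_mask": mesh.plantar_face_mask.astype(int).tolist(),
        "stations": mesh.stations.tolist(),
        "station_frames": mesh.station_frames.tolist(),
    }
    sidecar.write_text(json.dumps(payload))


def load_leg(mesh_path: str | Path, sidecar_path: str | Path | None = None) -> LegSurface:
    mesh_path = Path(mesh_path)
    tm = trimesh.load(mesh_path, process=False, force="mesh")
    sidecar = Path(sidecar_path) if sidecar_path else mesh_path.with_suffix(".json")
    raw = json.loads(sidecar.read_text())
    return LegSurface(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=int),
        landmarks={k: int(v) for k, v in raw["landmarks"].items()},
        site_of_face=np.asarray(raw["site_of_face"]),
        toe_face_mask=np.asarray(raw["toe_face_mask"], dtype=bool),
        plantar_face_mask=np.asarray(raw["plantar_face_mask"], dtype=bool),
        stations=np.asarray(raw["stations"], dtype=float),
        station_frames=np.asarray(raw["station_frames"], dtype=float),
        zone_of_face=None
        if raw["zone_of_face"] is None
        else np.asarray(raw["zone_of_face"], dtype=int),
    )
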