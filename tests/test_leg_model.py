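"""Parametric leg surface: landmarks, zones, templates, serialization."""

import numpy as np
import pytest
from shapely.geometry import Point

from itmap.leg_model import (
    GeometryParameterError,
    LegShapeParams,
    ZoneTemplate,
    build_reference_leg,
    expected_landmark_positions,
    load_leg,
    project_views,
    save_leg,
    segment_zones,
)
from itmap.zones import DEFAULT_MERIDIANS_DEG, ZoneId


def test_mesh_is_watertight_connected_with_required_landmarks(reference):
    tm = reference.trimesh
    assert tm.is_watertight and tm.is_winding_consistent and tm.volume > 0
    assert {"patella", "medial_malleolus", "lateral_malleolus", "toe_tip_1", "toe_tip_5"} <= set(
        reference.landmarks
    )
    assert len(reference.zones_present()) == 4


def test_landmarks_match_closed_form_and_survive_resolution_doubling():
    params = LegShapeParams()
    expected = expected_landmark_positions(params)
    for res in (16, 32):
        leg = build_reference_leg(params, resolution=res)
        for name, pos in expected.items():
            np.testing.assert_allclose(leg.landmark_point(name), pos, atol=1e-6)


def test_build_is_deterministic():
    a = build_reference_leg(resolution=16)
    b = build_reference_leg(resolution=16)
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.faces, b.faces)


@pytest.mark.parametrize(
    "kwargs",
    [dict(foot_length=-1), dict(thigh_radius=0), dict(toe_fraction=1.5)],
)
def test_invalid_shape_parameters_rejected(kwargs):
    with pytest.raises(GeometryParameterError):
        build_reference_leg(LegShapeParams(**kwargs))


def test_invalid_resolution_rejected():
    with pytest.raises(GeometryParameterError):
        build_reference_leg(resolution=6)
    with pytest.raises(GeometryParameterError):
        build_reference_leg(resolution=18)  # not a multiple of 4


@pytest.mark.parametrize(
    "meridians", [DEFAULT_MERIDIANS_DEG, (45, 135, 225, 315), (30, 120, 210, 300)]
)
def test_zones_partition_total_area(meridians):
    leg = segment_zones(build_reference_leg(resolution=16), boundary_spec=meridians)
    areas = leg.face_areas()
    total = areas.sum()
    by_zone = sum(areas[leg.zone_of_face == int(z)].sum() for z in ZoneId)
    assert abs(by_zone - total) / total < 1e-9


@pytest.mark.parametrize("meridians", [DEFAULT_MERIDIANS_DEG, (45, 135, 225, 315)])
def test_toe_faces_always_anteromedial(meridians):
    leg = segment_zones(build_reference_leg(resolution=16), boundary_spec=meridians)
    assert (leg.zone_of_face[leg.toe_face_mask] == int(ZoneId.ANTEROMEDIAL)).all()
    for name in ("toe_tip_1", "toe_tip_5"):
        vi = leg.landmarks[name]
        for f in np.flatnonzero((leg.faces == vi).any(axis=1)):
            assert ZoneId(int(leg.zone_of_face[f])) == ZoneId.ANTEROMEDIAL


def test_midcalf_anterior_face_zone_matches_direct_angle_rule(reference):
    # oracle: mid-calf centroids satisfy angle = atan2(y, x) directly
    cent = reference.face_centroids()
    mid = (cent[:, 2] > 20) & (cent[:, 2] < 35)
    ang = np.degrees(np.arctan2(cent[mid, 1], cent[mid, 0])) % 360.0
    sector = (ang // 90).astype(int)
    zone_by_sector = {
        0: ZoneId.ANTEROMEDIAL,
        1: ZoneId.ANTEROLATERAL,
        2: ZoneId.POSTEROLATERAL,
        3: ZoneId.POSTEROMEDIAL,
    }
    got = reference.zone_of_face[mid]
    for s, z in zip(sector, got):
        assert zone_by_sector[s] == ZoneId(int(z))


def test_segment_zones_requires_four_distinct_meridians(reference):
    with pytest.raises(ValueError):
        segment_zones(build_reference_leg(resolution=16), boundary_spec=[0, 90, 90, 180])


def test_anterior_view_has_no_posterior_zones(template):
    zones = {z for z, _g in template.views["anterior"]}
    assert ZoneId.ANTEROMEDIAL in zones and ZoneId.ANTEROLATERAL in zones
    assert ZoneId.POSTEROLATERAL not in zones
    assert ZoneId.POSTEROMEDIAL not in zones


def test_projection_preserves_axial_landmark_distance(reference, template):
    lat = template.landmarks_2d["lateral"]
    assert "patella" in lat and "lateral_malleolus" in lat
    dz_2d = abs(lat["patella"][1] - lat["lateral_malleolus"][1])
    dz_3d = abs(
        reference.landmark_point("patella")[2]
        - reference.landmark_point("lateral_malleolus")[2]
    )
    assert abs(dz_2d - dz_3d) < 1e-6


def test_zone_polygons_tile_silhouette_disjointly(template):
    for view, zone_polys in template.views.items():
        sil = template.silhouettes[view]
        union_area = sum(g.area for _z, g in zone_polys)
        assert abs(union_area - sil.area) / sil.area < 1e-6
        for i in range(len(zone_polys)):
            for j in range(i + 1, len(zone_polys)):
                inter = zone_polys[i][1].intersection(zone_polys[j][1])
                assert inter.area < 1e-6 * sil.area


def test_zone_polygon_vertices_lie_in_silhouette(template):
    for view, zone_polys in template.views.items():
        sil = template.silhouettes[view].buffer(1e-9)
        for _z, geom in zone_polys:
            for poly in getattr(geom, "geoms", [geom]):
                xs, ys = poly.exterior.xy
                for x, y in list(zip(xs, ys))[::7]:
                    assert sil.covers(Point(x, y))


def test_template_json_round_trip(template):
    text = template.to_json()
    back = ZoneTemplate.from_json(text)
    for view in template.views:
        orig = {z: g.area for z, g in template.views[view]}
        rec = {z: g.area for z, g in back.views[view]}
        assert set(orig) == set(rec)
        for z in orig:
            assert abs(orig[z] - rec[z]) < 1e-6


@pytest.mark.parametrize("fmt", ["obj", "ply"])
def test_mesh_save_load_round_trip(tmp_path, reference, fmt):
    save_leg(reference, tmp_path / f"leg.{fmt}")
    back = load_leg(tmp_path / f"leg.{fmt}")
    np.testing.assert_allclose(back.vertices, reference.vertices, atol=1e-4)
    assert np.array_equal(back.faces, reference.faces)
    assert back.landmarks == reference.landmarks
    assert np.array_equal(back.zone_of_face, reference.zone_of_face)
    assert np.array_equal(back.site_of_face, reference.site_of_face)


def test_template_rendering_smoke(tmp_path, reference, template):
    from itmap.drainage import render_template

    out = tmp_path / "views.png"
    render_template(template, path=out)
    assert out.exists() and out.stat().st_size > 0
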