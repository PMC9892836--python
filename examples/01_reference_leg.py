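"""Build the canonical leg surface and its drainage-zone template.

Constructs the parametric left-leg mesh, assigns the four lymphatic
drainage territories, and projects the four 2D template views.
"""

from itmap import build_reference_leg, project_views, segment_zones
from itmap.zones import ZONE_COLORS, ZoneId

leg = segment_zones(build_reference_leg(resolution=16))

print(f"mesh: {len(leg.vertices)} vertices, {leg.n_faces} faces, "
      f"area {leg.total_area():.0f} cm^2")
print("landmarks (cm, canonical frame: +z proximal, +y anterior, +x medial):")
for name in sorted(leg.landmarks):
    x, y, z = leg.landmark_point(name)
    print(f"  {name:18s} ({x:6.2f}, {y:6.2f}, {z:6.2f})")

areas = leg.face_areas()
print("drainage territory surface shares:")
for zone in ZoneId:
    share = areas[leg.zone_of_face == int(zone)].sum() / areas.sum()
    print(f"  {zone.name.lower():15s} ({ZONE_COLORS[zone]:6s}) {100 * share:5.1f} %")

template = project_views(leg)
for view, zones in template.views.items():
    names = ", ".join(z.name.lower() for z, _g in zones)
    print(f"view {view:8s}: {names}")

# Each view shows only the territories whose surface faces that camera;
# the anterior view, for instance, contains no posterior territory.
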