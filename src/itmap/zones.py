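"""Lymphatic drainage sectors of the distal lower limb.

The distal lower extremity drains along four anatomically defined vessel
bundles, each with a cutaneous territory: posterolateral, posteromedial,
anterolateral and anteromedial (the last including the toes).  Lesions on
the skin surface are assigned to whichever territory contains them.

Angular convention (canonical left leg): angles are measured in the
cross-sectional plane around the limb axis, from the medial direction
(+x) counter-clockwise toward the anterior direction (+y), in degrees in
[0, 360).  Each sector is a half-open angular interval between two
boundary meridians.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class ZoneId(IntEnum):
    """Drainage territory of the distal lower limb.

    Enumeration order is the documented tie-break order for points that
    fall on shared territory boundaries in 2D templates.
    """

    POSTEROLATERAL = 0
    POSTEROMEDIAL = 1
    ANTEROLATERAL = 2
    ANTEROMEDIAL = 3

    @property
    def color(self) -> str:
        return ZONE_COLORS[self]


#: Display colors fixed by convention.
ZONE_COLORS = {
    ZoneId.POSTEROLATERAL: "red",
    ZoneId.POSTEROMEDIAL: "yellow",
    ZoneId.ANTEROLATERAL: "green",
    ZoneId.ANTEROMEDIAL: "blue",
}

#: Canonical center direction of each territory, degrees from +x (medial)
#: CCW toward +y (anterior).  Anteromedial is centered between medial and
#: anterior, and so on around the limb.
ZONE_CENTER_DEG = {
    ZoneId.ANTEROMEDIAL: 45.0,
    ZoneId.ANTEROLATERAL: 135.0,
    ZoneId.POSTEROLATERAL: 225.0,
    ZoneId.POSTEROMEDIAL: 315.0,
}

#: Default boundary meridians: four equal 90-degree sectors centered on the
#: canonical directions above.
DEFAULT_MERIDIANS_DEG = (0.0, 90.0, 180.0, 270.0)


def sectors_from_meridians(meridians_deg) -> list[tuple[float, float, ZoneId]]:
    """Partition the circle into four labeled sectors.

    ``meridians_deg`` are four distinct angles in [0, 360).  The circle is
    cut at the sorted meridians into half-open sectors [m_i, m_{i+1});
    each sector is labeled with the territory whose canonical center
    direction falls inside it.  A point exactly on a meridian therefore
    belongs to the sector counter-clockwise of that meridian.

    Raises ``ValueError`` if fewer than four distinct meridians are given
    or if the sectors do not pick up the four territories one-to-one.
    """
    m = np.asarray(sorted(float(a) % 360.0 for a in meridians_deg))
    if len(m) != 4 or len(np.unique(m)) != 4:
        raise ValueError("boundary_spec must contain four distinct meridian angles")
    sectors: list[tuple[float, float, ZoneId]] = []
    for i in range(4):
        lo = m[i]
        hi = m[(i + 1) % 4] + (360.0 if i == 3 else 0.0)
        inside = [
            z
            for z, c in ZONE_CENTER_DEG.items()
            if lo <= c < hi or lo <= c + 360.0 < hi
        ]
        if len(inside) != 1:
            raise ValueError(
                "each sector must contain exactly one canonical territory "
                f"direction; sector [{lo}, {hi}) contains {inside}"
            )
        sectors.append((lo, hi, inside[0]))
    return sectors


def classify_angle(angle_deg, sectors) -> np.ndarray:
    """Map cross-sectional angles (degrees) to territory ids.

    Vectorized; ``sectors`` is the output of :func:`sectors_from_meridians`.
    """
    a = np.asarray(angle_deg, dtype=float) % 360.0
    out = np.full(a.shape, -1, dtype=int)
    for lo, hi, zone in sectors:
        hit = ((a >= lo) & (a < hi)) | ((a + 360.0 >= lo) & (a + 360.0 < hi))
        out[hit] = int(zone)
    if (out < 0).any():  # pragma: no cover - sectors tile the circle
        raise RuntimeError("angle fell outside all sectors")
    return out
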