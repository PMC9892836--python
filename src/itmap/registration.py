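"""Standardization of patient lesion coordinates onto the reference leg.

Patient coordinates from photographs live in an arbitrary frame.  They
are brought into the canonical reference frame in three steps: mirror
right-sided limbs so a left leg is always analyzed, fit a rigid
(6-degree-of-freedom: translation + rotation) transform from the
patient's bone landmarks to the reference landmarks, then snap each
transformed lesion point to the nearest point of the reference surface.

The rigid fit is the closed-form orthogonal least-squares (Kabsch)
solution: centroid alignment plus rotation from the SVD of the
cross-covariance matrix, reflection-corrected.  No scaling by default;
an optional 7-DOF uniform-scale mode exists for cohorts with large
anatomical size variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .leg_model import LegSurface

ROLES = ("primary", "itm")
SIDES = ("left", "right")


class DegenerateLandmarkError(ValueError):
    """Fewer than three non-collinear common landmarks."""


class LesionInputError(ValueError):
    """Malformed lesion records (e.g. mixed sides in one patient)."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (proper orthonormal) plus translation, in cm."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    scale: float = 1.0  # 1.0 in the default rigid mode

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be a proper orthonormal 3x3 matrix")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return self.scale * (p @ self.rotation.T) + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            Rinv, -Rinv @ self.translation / self.scale, 1.0 / self.scale
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.scale * (self.rotation @ other.translation) + self.translation,
            self.scale * other.scale,
        )


@dataclass
class Lesion:
    """A surface lesion (primary melanoma or in-transit metastasis).

    The position is either a raw 3D point (``point``) or an anchor on a
    mesh surface (``face`` index plus barycentric coordinates ``bary``).
    Anchored lesions are the canonical form used downstream.
    """

    lesion_id: str
    patient_id: str
    role: str  # "primary" | "itm"
    side: str  # "left" | "right"
    site: str  # "foot" | "lower_leg" | "thigh"
    point: np.ndarray | None = None
    face: int | None = None
    bary: np.ndarray | None = None
    snap_distance: float | None = None
    unmappable: bool = False

    def __post_init__(self):
        if self.role not in ROLES:
            raise LesionInputError(f"role must be one of {ROLES}: {self.role!r}")
        if self.side not in SIDES:
            raise LesionInputError(f"side must be one of {SIDES}: {self.side!r}")
        if self.point is not None:
            self.point = np.asarray(self.point, dtype=float)
        if self.bary is not None:
            b = np.asarray(self.bary, dtype=float)
            if (b < -1e-9).any() or abs(b.sum() - 1.0) > 1e-9:
                raise LesionInputError(
                    "barycentric coordinates must be non-negative and sum to 1"
                )
            self.bary = b

    @property
    def anchored(self) -> bool:
        return self.face is not None and self.bary is not None

    def location(self, mesh: LegSurface) -> np.ndarray:
        """3D position, resolving the surface anchor if present."""
        if self.anchored:
            return self.bary @ mesh.vertices[mesh.faces[self.face]]
        if self.point is None:
            raise LesionInputError(f"lesion {self.lesion_id} has no position")
        return self.point


@dataclass
class PatientLesionSet:
    """All lesions of one patient, sharing one side."""

    patient_id: str
    side: str
    lesions: list[Lesion]
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def primaries(self) -> list[Lesion]:
        return [l for l in self.lesions if l.role == "primary"]

    @property
    def itm(self) -> list[Lesion]:
        return [l for l in self.lesions if l.role == "itm"]


# ---------------------------------------------------------------------------
# mirroring
# ---------------------------------------------------------------------------

_MIRROR = np.array([-1.0, 1.0, 1.0])


def mirror_to_left(
    lesions: list[Lesion], landmarks: dict[str, np.ndarray]
) -> tuple[list[Lesion], dict[str, np.ndarray]]:
    """Reflect right-sided data across the sagittal plane (x -> -x).

    Left-sided inputs are returned unchanged (new list, same values).
    All lesions must share one side; mirroring twice restores the input
    (the ``side`` field keeps recording the anatomical side of origin —
    only coordinates are reflected).  Surface anchors are dropped on
    mirroring (the mirrored point is no longer on the original patient
    surface); raw points are reflected.
    """
    sides = {l.side for l in lesions}
    if len(sides) > 1:
        raise LesionInputError(f"mixed sides within one patient: {sorted(sides)}")
    if not lesions or sides == {"left"}:
        return [replace(l) for l in lesions], {k: np.array(v) for k, v in landmarks.items()}
    out = []
    for l in lesions:
        pt = l.point
        out.append(
            replace(
                l,
                point=None if pt is None else pt * _MIRROR,
                face=None,
                bary=None,
            )
        )
    mirrored_lm = {k: np.asarray(v, dtype=float) * _MIRROR for k, v in landmarks.items()}
    return out, mirrored_lm


# ---------------------------------------------------------------------------
# rigid fit
# ---------------------------------------------------------------------------


def fit_rigid_transform(
    source_landmarks: dict[str, np.ndarray],
    target_landmarks: dict[str, np.ndarray],
    allow_scale: bool = False,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid alignment of labeled landmark sets.

    Returns the transform mapping source onto target and the RMS residual
    over the common landmarks.  Requires at least three non-collinear
    common labels.  With ``allow_scale`` a uniform scale factor is also
    estimated (7 DOF); off by default — the standardization protocol is
    rigid.
    """
    labels = sorted(set(source_landmarks) & set(target_landmarks))
    if len(labels) < 3:
        raise DegenerateLandmarkError(
            f"need >= 3 common landmark labels, got {len(labels)}"
        )
    src = np.array([source_landmarks[k] for k in labels], dtype=float)
    tgt = np.array([target_landmarks[k] for k in labels], dtype=float)
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    # collinearity: second singular value of the centered source
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateLandmarkError("landmark configuration is collinear")

    H = src_c.T @ tgt_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scale:
        # Umeyama similarity solution: trace(S.D) over source variance
        scale = float((S * np.diag(D)).sum() / (src_c ** 2).sum())
    else:
        scale = 1.0
    t = tgt.mean(axis=0) - scale * R @ src.mean(axis=0)
    tf = RigidTransform(R, t, scale)
    rms = float(np.sqrt(((tf.apply(src) - tgt) ** 2).sum(axis=1).mean()))
    return tf, rms


# ---------------------------------------------------------------------------
# surface transfer
# ---------------------------------------------------------------------------


def transfer_lesions(
    lesions: list[Lesion],
    transform: RigidTransform,
    reference: LegSurface,
    snap_threshold_cm: float = 3.0,
) -> list[Lesion]:
    """Map lesions through ``transform`` and anchor them on the reference.

    Each transformed point is snapped to its nearest point on the
    reference surface; the snap distance is recorded.  Points farther
    than ``snap_threshold_cm`` from the surface are flagged unmappable
    (kept in the output, excluded from analysis) rather than silently
    assigned.  Input order is preserved.
    """
    if not lesions:
        return []
    pts = np.array([l.location(reference) if l.anchored else l.point for l in lesions])
    moved = transform.apply(pts)
    # exhaustive nearest-point query: exact, needs no spatial index, and
    # the reference meshes are small (a few thousand faces)
    closest, dist, tri_id = trimesh.proximity.closest_point_naive(
        reference.trimesh, moved
    )
    bary = trimesh.triangles.points_to_barycentric(
        reference.vertices[reference.faces[tri_id]], closest
    )
    bary = np.clip(bary, 0.0, None)
    bary /= bary.sum(axis=1, keepdims=True)
    out = []
    for l, f, b, d in zip(lesions, tri_id, bary, dist):
        out.append(
            replace(
                l,
                point=None,
                face=int(f),
                bary=b,
                snap_distance=float(d),
                unmappable=bool(d > snap_threshold_cm),
            )
        )
    return out
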