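"""Delimited-text input and output.

Lesion tables carry one row per lesion with either a raw 3D position
(columns ``x_cm, y_cm, z_cm``) or a surface anchor (``face, b0, b1,
b2``).  Landmark tables carry one labeled 3D point per row.  Cohort
tables follow the clinical covariate schema.  All tables are plain CSV
with headers; schema violations are reported with row numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .registration import Lesion, PatientLesionSet

LESION_COLUMNS = ["patient_id", "lesion_id", "role", "side", "site"]
COHORT_COLUMNS = [
    "patient_id",
    "gender",
    "age",
    "subtype",
    "thickness_mm",
    "ulceration",
    "site",
    "has_itm",
    "n_itm_category",
    "months_to_itm",
]


class SchemaError(ValueError):
    """Input table violates the expected schema."""


def write_lesions_csv(patients: list[PatientLesionSet], path: str | Path) -> None:
    rows = []
    for ps in patients:
        for l in ps.lesions:
            row = {
                "patient_id": l.patient_id,
                "lesion_id": l.lesion_id,
                "role": l.role,
                "side": l.side,
                "site": l.site,
            }
            if l.anchored:
                row.update(face=l.face, b0=l.bary[0], b1=l.bary[1], b2=l.bary[2])
            else:
                row.update(x_cm=l.point[0], y_cm=l.point[1], z_cm=l.point[2])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lesions_csv(path: str | Path) -> dict[str, list[Lesion]]:
    """Lesions grouped by patient id, input order preserved."""
    df = pd.read_csv(path)
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"lesion table missing columns {missing}")
    has_xyz = {"x_cm", "y_cm", "z_cm"}.issubset(df.columns)
    has_anchor = {"face", "b0", "b1", "b2"}.issubset(df.columns)
    if not (has_xyz or has_anchor):
        raise SchemaError("lesion table needs x_cm,y_cm,z_cm or face,b0,b1,b2")
    out: dict[str, list[Lesion]] = {}
    for i, row in df.iterrows():
        try:
            kwargs = dict(
                lesion_id=str(row["lesion_id"]),
                patient_id=str(row["patient_id"]),
                role=str(row["role"]),
                side=str(row["side"]),
                site=str(row["site"]),
            )
            if has_anchor and not pd.isna(row.get("face")):
                kwargs["face"] = int(row["face"])
                kwargs["bary"] = np.array([row["b0"], row["b1"], row["b2"]], dtype=float)
            else:
                kwargs["point"] = np.array(
                    [row["x_cm"], row["y_cm"], row["z_cm"]], dtype=float
                )
            lesion = Lesion(**kwargs)
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"lesion table row {i + 2}: {exc}") from exc
        out.setdefault(lesion.patient_id, []).append(lesion)
    return out


def write_landmarks_csv(
    landmarks_by_patient: dict[str, dict[str, np.ndarray]], path: str | Path
) -> None:
    rows = [
        {"patient_id": pid, "landmark": name, "x_cm": p[0], "y_cm": p[1], "z_cm": p[2]}
        for pid, lm in landmarks_by_patient.items()
        for name, p in lm.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    df = pd.read_csv(path)
    need = {"patient_id", "landmark", "x_cm", "y_cm", "z_cm"}
    if not need.issubset(df.columns):
        raise SchemaError(f"landmark table missing columns {sorted(need - set(df.columns))}")
    out: dict[str, dict[str, np.ndarray]] = {}
    for _i, row in df.iterrows():
        out.setdefault(str(row["patient_id"]), {})[str(row["landmark"])] = np.array(
            [row["x_cm"], row["y_cm"], row["z_cm"]], dtype=float
        )
    return out


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns {missing}")
    df["has_itm"] = df["has_itm"].astype(bool)
    return df
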