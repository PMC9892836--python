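"""Risk-factor statistics for in-transit metastasis (ITM).

Case-control comparison of melanoma patients of the lower extremity
with versus without ITM: Pearson chi-square for categorical covariates,
Mann-Whitney U for continuous ones, and univariate plus multivariate
logistic regression reporting odds ratios with 95% Wald confidence
intervals.

Covariate coding for the regression models follows the clinical
convention: age dichotomized at 55 years, histologic subtype with
superficial spreading melanoma (SSM) as reference (melanoma of unknown
primary excluded — no primary-tumor covariates exist for it), Breslow
thickness dichotomized at 1.0 mm, ulceration present vs absent
(absent = reference), site with foot as reference.  Records missing a
covariate are dropped from models containing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._stats import MannWhitneyResult, mann_whitney

SUBTYPES = ("SSM", "NM", "ALM", "NOS", "MUP")


class DegenerateTableError(ValueError):
    """Contingency table with a zero marginal."""


@dataclass
class CohortRecord:
    """Clinical covariates and ITM outcome of one patient."""

    patient_id: str
    gender: str  # "male" | "female"
    age: float  # years
    subtype: str  # SSM | NM | ALM | NOS | MUP
    thickness_mm: float | None  # Breslow depth; None if unknown / MUP
    ulceration: str  # "present" | "absent" | "missing"
    site: str  # "foot" | "lower_leg" | "thigh"
    has_itm: bool
    n_itm_category: str | None = None  # "1-5" | "6-10" | "11-20" | ">20"
    months_to_itm: float | None = None

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.thickness_mm is not None and self.thickness_mm <= 0:
            raise ValueError("thickness must be positive when present")
        if self.subtype == "MUP":
            # unknown primary: no primary-tumor attributes by definition
            self.thickness_mm = None
            self.ulceration = "missing"


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


@dataclass(frozen=True)
class EffectEstimate:
    """One odds-ratio row of a logistic model."""

    covariate: str
    level: str
    odds_ratio: float
    ci_low: float | None
    ci_high: float | None
    p: float | None
    analysis: str  # "univariate" | "multivariate"
    reference: bool = False
    converged: bool = True

    def as_row(self) -> dict:
        return {
            "covariate": self.covariate,
            "level": self.level,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "model": self.analysis,
        }


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (statistic, degrees of freedom, p).  Raises on tables with a
    zero row or column sum, where expected counts are undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateTableError("need at least a 2x2 table")
    if (t < 0).any():
        raise DegenerateTableError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero marginal in contingency table")
    chi2, p, dof, _exp = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


def mann_whitney_continuous(group_a, group_b) -> MannWhitneyResult:
    """Two-sided tie-corrected asymptotic Mann-Whitney U.

    Same engine as the ordinal site comparison of match categories.
    All-identical pooled values give the degenerate result z=0, p=1.
    """
    return mann_whitney(group_a, group_b, method="asymptotic")


# ---------------------------------------------------------------------------
# logistic models
# ---------------------------------------------------------------------------

#: model terms: name -> (builder returning a coded column or None for
#: missing, list of (column_label, covariate, level))
def _design_columns(df: pd.DataFrame) -> dict[str, tuple[pd.DataFrame, list]]:
    out: dict[str, tuple[pd.DataFrame, list]] = {}

    age = (df["age"] >= 55).astype(float)
    out["age"] = (age.to_frame("age_ge55"), [("age_ge55", "age", ">=55")])

    sub = df["subtype"].where(df["subtype"] != "MUP")
    cols = {}
    for lv in ("NM", "ALM", "NOS"):
        cols[f"subtype_{lv}"] = (sub == lv).astype(float)
    sub_df = pd.DataFrame(cols)
    sub_df[sub.isna()] = np.nan
    out["subtype"] = (
        sub_df,
        [(f"subtype_{lv}", "subtype", lv) for lv in ("NM", "ALM", "NOS")],
    )

    th = pd.to_numeric(df["thickness_mm"], errors="coerce")
    th_col = (th >= 1.0).astype(float)
    th_col[th.isna()] = np.nan
    out["thickness"] = (th_col.to_frame("thickness_ge1"), [("thickness_ge1", "thickness", ">=1.0 mm")])

    ulc = df["ulceration"].where(df["ulceration"].isin(["present", "absent"]))
    u_col = (ulc == "present").astype(float)
    u_col[ulc.isna()] = np.nan
    out["ulceration"] = (u_col.to_frame("ulceration_present"), [("ulceration_present", "ulceration", "present")])

    site_df = pd.DataFrame(
        {
            "site_lower_leg": (df["site"] == "lower_leg").astype(float),
            "site_thigh": (df["site"] == "thigh").astype(float),
        }
    )
    out["site"] = (
        site_df,
        [("site_lower_leg", "site", "lower_leg"), ("site_thigh", "site", "thigh")],
    )
    return out


_REFERENCE_LEVELS = {
    "age": "<55",
    "subtype": "SSM",
    "thickness": "<1.0 mm",
    "ulceration": "absent",
    "site": "foot",
}


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True)) and np.isfinite(
            res.bse.to_numpy()
        ).all()
        return res, converged
    except (np.linalg.LinAlgError, PerfectSeparationError):
        return None, False


def logistic_risk_model(
    cohort: pd.DataFrame | list[CohortRecord],
    mode: str = "multivariate",
    covariates: tuple[str, ...] = ("age", "subtype", "thickness", "ulceration", "site"),
) -> list[EffectEstimate]:
    """Odds ratios for ITM with 95% Wald confidence intervals.

    ``univariate``: one model per covariate, dropping records with that
    covariate missing.  ``multivariate``: one joint model on complete
    cases for all requested covariates.  Reference levels are reported
    with OR fixed at 1.0 and no interval.  Complete separation or
    non-convergence is reported per estimate via ``converged=False``
    (OR is then NaN), never silently.
    """
    df = cohort if isinstance(cohort, pd.DataFrame) else records_to_frame(cohort)
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    design = _design_columns(df)
    y_all = df["has_itm"].astype(float).to_numpy()

    groups = [covariates] if mode == "multivariate" else [(c,) for c in covariates]
    estimates: list[EffectEstimate] = []
    for grp in groups:
        X = pd.concat([design[c][0] for c in grp], axis=1)
        labels = [lab for c in grp for lab in design[c][1]]
        keep = ~X.isna().any(axis=1)
        Xk, yk = X[keep], y_all[keep.to_numpy()]
        dropped = [
            (col, cov, lv) for col, cov, lv in labels if Xk[col].nunique() < 2
        ]
        for col, cov, lv in dropped:  # empty level: drop with warning
            import warnings

            warnings.warn(f"level {cov}={lv} empty after exclusions; dropped")
            Xk = Xk.drop(columns=col)
        labels = [t for t in labels if t not in dropped]
        res, converged = _fit_logit(yk, Xk)
        seen_cov = set()
        for col, cov, lv in labels:
            if cov not in seen_cov:
                seen_cov.add(cov)
                estimates.append(
                    EffectEstimate(
                        covariate=cov,
                        level=_REFERENCE_LEVELS[cov],
                        odds_ratio=1.0,
                        ci_low=None,
                        ci_high=None,
                        p=None,
                        analysis=mode,
                        reference=True,
                    )
                )
            if res is None or not converged:
                estimates.append(
                    EffectEstimate(cov, lv, float("nan"), None, None, None, mode, converged=False)
                )
                continue
            beta = float(res.params[col])
            se = float(res.bse[col])
            estimates.append(
                EffectEstimate(
                    covariate=cov,
                    level=lv,
                    odds_ratio=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                    ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                    p=float(res.pvalues[col]),
                    analysis=mode,
                )
            )
    return estimates


def estimates_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy table (covariate, level, OR, CI, p, model)."""
    return pd.DataFrame([e.as_row() for e in estimates])
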