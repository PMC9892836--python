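"""Contingency tests, rank tests, and logistic odds-ratio models."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from itmap._stats import mann_whitney
from itmap.cohort_stats import (
    DegenerateTableError,
    chi_square_test,
    estimates_to_frame,
    logistic_risk_model,
    mann_whitney_continuous,
)

# published case-control ulceration counts: rows without/with ITM,
# columns present/absent
ULCERATION_TABLE = [[44, 244], [37, 44]]


def test_ulceration_association_is_strong():
    chi2, dof, p = chi_square_test(ULCERATION_TABLE)
    assert dof == 1
    assert p < 0.001


def test_chi_square_matches_direct_formula():
    # oracle: sum (O - E)^2 / E computed from scratch
    t = np.asarray(ULCERATION_TABLE, dtype=float)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    oracle = ((t - expected) ** 2 / expected).sum()
    chi2, _dof, _p = chi_square_test(ULCERATION_TABLE)
    assert chi2 == pytest.approx(oracle, rel=1e-12)
    assert chi2 == pytest.approx(34.104, abs=0.01)


def test_identical_row_proportions_give_zero_statistic():
    chi2, dof, p = chi_square_test([[10, 20], [30, 60]])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_2x2_equals_squared_two_proportion_score_z():
    # oracle: pooled two-proportion score test
    a, b, c, d = 20.0, 35.0, 14.0, 50.0
    chi2, _dof, _p = chi_square_test([[a, b], [c, d]])
    n1, n2 = a + b, c + d
    p1, p2 = a / n1, c / n2
    p_pool = (a + c) / (n1 + n2)
    z = (p1 - p2) / np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    assert chi2 == pytest.approx(z**2, abs=1e-9)


@pytest.mark.parametrize(
    "table", [[[0, 0], [1, 2]], [[1, 0], [2, 0]], [[1, 2]]]
)
def test_degenerate_tables_rejected(table):
    with pytest.raises(DegenerateTableError):
        chi_square_test(table)


# -- rank test ---------------------------------------------------------------


def test_identical_groups_degenerate():
    res = mann_whitney_continuous([1, 2, 3], [1, 2, 3])
    assert res.z == 0.0 and res.p == 1.0
    res2 = mann_whitney_continuous([5, 5, 5], [5, 5])
    assert res2.p == 1.0  # all tied: zero rank variance, flagged degenerate


def test_complete_separation_gives_zero_u():
    res = mann_whitney_continuous([1, 2], [10, 20])
    assert res.u == 0.0


def test_asymptotic_engine_matches_scipy():
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.normal(size=8).round(1)
        y = rng.normal(size=12).round(1)
        ours = mann_whitney_continuous(x, y)
        ref = stats.mannwhitneyu(x, y, use_continuity=False, method="asymptotic")
        assert ours.u == pytest.approx(float(ref.statistic), abs=1e-9)
        assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_exact_mode_matches_enumeration_5v5():
    rng = np.random.default_rng(17)
    for _ in range(10):
        x = rng.normal(size=5).round(1)
        y = rng.normal(size=5).round(1)
        res = mann_whitney(x, y, method="exact")
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        mu = 12.5
        obs = abs(ranks[:5].sum() - 15 - mu)
        hits = sum(
            1
            for idx in combinations(range(10), 5)
            if abs(ranks[list(idx)].sum() - 15 - mu) >= obs - 1e-9
        )
        assert res.p == pytest.approx(hits / comb(10, 5), abs=1e-12)


# -- logistic models ---------------------------------------------------------


def _two_by_two_cohort(a, b, c, d):
    """Exposed cases a, exposed controls b, unexposed cases c, controls d
    coded as ulceration present/absent."""
    rows = []
    spec = [
        ("present", True, a),
        ("present", False, b),
        ("absent", True, c),
        ("absent", False, d),
    ]
    i = 0
    for ulc, itm, count in spec:
        for _ in range(count):
            rows.append(
                {
                    "patient_id": f"P{i}",
                    "gender": "female",
                    "age": 50.0,
                    "subtype": "SSM",
                    "thickness_mm": 2.0,
                    "ulceration": ulc,
                    "site": "foot",
                    "has_itm": itm,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def test_univariate_or_equals_cross_product_ratio():
    df = _two_by_two_cohort(20, 10, 10, 20)
    est = logistic_risk_model(df, mode="univariate", covariates=("ulceration",))
    effect = [e for e in est if not e.reference][0]
    assert effect.odds_ratio == pytest.approx(4.0, rel=1e-6)  # ad/bc
    assert effect.ci_low < 4.0 < effect.ci_high


def test_reference_levels_fixed_at_one_without_ci():
    df = _two_by_two_cohort(20, 10, 10, 20)
    est = logistic_risk_model(df, mode="univariate", covariates=("ulceration",))
    ref = [e for e in est if e.reference][0]
    assert ref.odds_ratio == 1.0
    assert ref.ci_low is None and ref.ci_high is None
    assert ref.level == "absent"


def test_null_covariate_or_near_one_large_n():
    rng = np.random.default_rng(100)
    n = 10000
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "gender": "female",
            "age": rng.uniform(20, 90, n).round(1),
            "subtype": "SSM",
            "thickness_mm": 2.0,
            "ulceration": np.where(rng.random(n) < 0.5, "present", "absent"),
            "site": "foot",
            "has_itm": rng.random(n) < 0.3,
        }
    )
    est = logistic_risk_model(df, mode="univariate", covariates=("ulceration",))
    effect = [e for e in est if not e.reference][0]
    assert 0.9 <= effect.odds_ratio <= 1.1


def test_multivariate_model_reports_all_requested_levels(sim_config):
    from itmap.synthetic import simulate_cohort
    from dataclasses import replace

    df = simulate_cohort(replace(sim_config, n_patients=1500))
    est = logistic_risk_model(df, mode="multivariate")
    frame = estimates_to_frame(est)
    assert set(frame["covariate"]) == {"age", "subtype", "thickness", "ulceration", "site"}
    nm = frame[(frame["covariate"] == "subtype") & (frame["level"] == "NM")]
    assert len(nm) == 1 and np.isfinite(nm["odds_ratio"].iloc[0])
    # MUP records carry no subtype effect level
    assert "MUP" not in set(frame["level"])


def test_complete_separation_flagged_not_silent():
    df = _two_by_two_cohort(20, 0, 0, 20)
    est = logistic_risk_model(df, mode="univariate", covariates=("ulceration",))
    effect = [e for e in est if not e.reference][0]
    assert not effect.converged or not np.isfinite(effect.odds_ratio)
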