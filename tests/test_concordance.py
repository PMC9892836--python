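"""Concordance scoring, pattern tables, ordinal site comparison."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from itmap.concordance import (
    PatternTable,
    SiteComparisonError,
    UndefinedConcordanceError,
    compare_sites,
    round_half_up,
    score_concordance,
    tabulate_patterns,
)
from itmap.zones import ZoneId

AM, AL = ZoneId.ANTEROMEDIAL, ZoneId.ANTEROLATERAL


def _result(n_in, n_tot, site="lower_leg", pid="P"):
    zones = [AM] * n_in + [AL] * (n_tot - n_in)
    return score_concordance(AM, zones, patient_id=pid, site=site)


@pytest.mark.parametrize(
    "n_in,n_tot,pct,category",
    [
        (8, 8, 100, "full"),
        (8, 14, 57, "partial"),
        (2, 10, 20, "none"),
        (9, 10, 90, "full"),  # boundary: >= 90% is a full match
        (5, 10, 50, "partial"),  # boundary: >= 50% is at least partial
        (4, 10, 40, "none"),
    ],
)
def test_worked_examples_and_thresholds(n_in, n_tot, pct, category):
    r = _result(n_in, n_tot)
    assert r.percentage == pct
    assert r.category == category
    assert r.n_in_zone == n_in and r.n_itm == n_tot


def test_empty_itm_list_rejected():
    with pytest.raises(UndefinedConcordanceError):
        score_concordance(AM, [], patient_id="P0")


@given(st.integers(1, 40), st.data())
@settings(max_examples=60, deadline=None)
def test_category_monotone_in_fraction(n, data):
    k1 = data.draw(st.integers(0, n))
    k2 = data.draw(st.integers(0, n))
    lo, hi = sorted([k1, k2])
    order = {"none": 0, "partial": 1, "full": 2}
    assert order[_result(lo, n).category] <= order[_result(hi, n).category]


def test_half_up_rounding_matches_printed_cohort_percentages():
    # spot checks against published marginal percentages
    assert round_half_up(100 * 34 / 94) == 36
    assert round_half_up(100 * 7 / 31) == 23
    assert round_half_up(0.5) == 1
    assert round_half_up(56.5) == 57


def _cohort_results():
    results = []
    for i in range(22):
        results.append(_result(10, 10, "lower_leg", f"l{i}"))
    for i in range(2):
        results.append(_result(6, 10, "lower_leg", f"lp{i}"))
    for i in range(7):
        results.append(_result(1, 10, "lower_leg", f"ln{i}"))
    for i in range(3):
        results.append(_result(10, 10, "foot", f"f{i}"))
    for i in range(6):
        results.append(_result(6, 10, "foot", f"fp{i}"))
    for i in range(6):
        results.append(_result(1, 10, "foot", f"fn{i}"))
    return results


def test_pattern_table_reproduces_published_percentages():
    table = tabulate_patterns(_cohort_results())
    assert table.counts["lower_leg"].tolist() == [22, 2, 7]
    assert table.counts["foot"].tolist() == [3, 6, 6]
    assert table.percentages["lower_leg"].tolist() == [71, 6, 23]
    assert table.percentages["foot"].tolist() == [20, 40, 40]


def test_single_patient_table():
    table = tabulate_patterns([_result(5, 5, "foot")])
    assert table.percentages["foot"].tolist() == [100, 0, 0]


def test_tabulate_then_rederive_counts_is_identity():
    results = _cohort_results()
    table = tabulate_patterns(results)
    for site in ("foot", "lower_leg"):
        derived = {c: 0 for c in ("full", "partial", "none")}
        for r in results:
            if r.site == site:
                derived[r.category] += 1
        assert derived == table.site_counts(site)


def test_site_comparison_reproduces_published_p():
    res = compare_sites(tabulate_patterns(_cohort_results()))
    assert round(res.p, 3) == 0.007
    assert res.z == pytest.approx(-2.691, abs=0.005)


def test_identical_distributions_give_p_one():
    results = [_result(10, 10, s, f"{s}{i}") for s in ("foot", "lower_leg") for i in range(5)]
    res = compare_sites(tabulate_patterns(results))
    assert res.z == 0.0 and res.p == 1.0


def test_comparison_antisymmetric_under_site_swap():
    table = tabulate_patterns(_cohort_results())
    swapped = PatternTable(
        counts=table.counts[["lower_leg", "foot"]],
        percentages=table.percentages[["lower_leg", "foot"]],
    )
    a = compare_sites(table)
    b = compare_sites(swapped)
    assert a.z == pytest.approx(-b.z, abs=1e-12)
    assert a.p == pytest.approx(b.p, abs=1e-12)


def test_permutation_mode_matches_independent_enumeration_small_n():
    # independent oracle: enumerate all group assignments of the ordinal
    # codes and compute the two-sided permutation p for |U - mu|
    rng = np.random.default_rng(42)
    for _case in range(50):
        cats = rng.integers(0, 3, size=8)  # 4 foot + 4 leg patients
        foot, leg = cats[:4], cats[4:]
        results = []
        n_in = {0: 1, 1: 6, 2: 10}
        for i, c in enumerate(foot):
            results.append(_result(n_in[int(c)], 10, "foot", f"f{i}"))
        for i, c in enumerate(leg):
            results.append(_result(n_in[int(c)], 10, "lower_leg", f"l{i}"))
        res = compare_sites(tabulate_patterns(results), method="exact")

        pooled = np.concatenate([foot, leg]).astype(float)
        ranks = stats.rankdata(pooled)
        mu = 4 * 4 / 2
        obs = abs(ranks[:4].sum() - 10 - mu)
        hits = sum(
            1
            for idx in combinations(range(8), 4)
            if abs(ranks[list(idx)].sum() - 10 - mu) >= obs - 1e-9
        )
        p_exact = hits / comb(8, 4)
        assert res.p == pytest.approx(p_exact, abs=1e-12)


def test_exact_mode_matches_independent_enumeration():
    results = [
        _result(10, 10, "foot", "f0"),
        _result(6, 10, "foot", "f1"),
        _result(1, 10, "foot", "f2"),
        _result(1, 10, "foot", "f3"),
        _result(10, 10, "lower_leg", "l0"),
        _result(10, 10, "lower_leg", "l1"),
        _result(6, 10, "lower_leg", "l2"),
        _result(10, 10, "lower_leg", "l3"),
    ]
    res = compare_sites(tabulate_patterns(results), method="exact")
    pooled = np.array([2.0, 1, 0, 0, 2, 2, 1, 2])
    ranks = stats.rankdata(pooled)
    mu = 4 * 4 / 2
    obs = abs(ranks[:4].sum() - 10 - mu)
    hits = sum(
        1
        for idx in combinations(range(8), 4)
        if abs(ranks[list(idx)].sum() - 10 - mu) >= obs - 1e-9
    )
    assert res.p == pytest.approx(hits / comb(8, 4), abs=1e-12)


def test_empty_site_rejected():
    results = [_result(5, 5, "foot")]
    with pytest.raises(SiteComparisonError):
        compare_sites(tabulate_patterns(results))
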