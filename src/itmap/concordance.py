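"""Per-patient drainage concordance and cohort pattern tables.

The primary melanoma's drainage territory defines the expected location
of that patient's in-transit metastases.  The concordance fraction is
the share of ITM falling in that territory; patients are classified as
full match (fraction >= 90%), partial match (>= 50% and < 90%) or no
match (< 50%).  Percentages print with half-up rounding.

Site-level tables (foot vs lower leg) are compared with the ordinal
Mann-Whitney U test (none < partial < full), tie-corrected asymptotic
two-sided p by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from ._stats import mann_whitney
from .zones import ZoneId

CATEGORIES = ("none", "partial", "full")  # ordinal, ascending
FULL_THRESHOLD = 0.90
PARTIAL_THRESHOLD = 0.50


class UndefinedConcordanceError(ValueError):
    """Concordance is undefined without at least one ITM."""


class SiteComparisonError(ValueError):
    """Site comparison requires both sites to be populated."""


def round_half_up(x: float) -> int:
    """Integer percentage rounding used in the printed tables."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def categorize(fraction: float) -> str:
    if fraction >= FULL_THRESHOLD:
        return "full"
    if fraction >= PARTIAL_THRESHOLD:
        return "partial"
    return "none"


@dataclass(frozen=True)
class ConcordanceResult:
    """Concordance of one patient's ITM with the primary's territory."""

    patient_id: str
    primary_zone: ZoneId
    n_itm: int
    n_in_zone: int
    site: str  # "foot" | "lower_leg"

    @property
    def fraction(self) -> float:
        return self.n_in_zone / self.n_itm

    @property
    def percentage(self) -> int:
        return round_half_up(100.0 * self.fraction)

    @property
    def category(self) -> str:
        return categorize(self.fraction)


def score_concordance(
    primary_zone: ZoneId,
    itm_zones: list[ZoneId],
    patient_id: str = "",
    site: str = "lower_leg",
) -> ConcordanceResult:
    """Score one patient: fraction of ITM in the primary's territory."""
    if len(itm_zones) == 0:
        raise UndefinedConcordanceError(
            f"patient {patient_id!r}: no in-transit metastases to score"
        )
    n_in = sum(1 for z in itm_zones if z == primary_zone)
    return ConcordanceResult(
        patient_id=patient_id,
        primary_zone=primary_zone,
        n_itm=len(itm_zones),
        n_in_zone=n_in,
        site=site,
    )


@dataclass
class PatternTable:
    """3 x 2 classification table of match categories by primary site."""

    counts: pd.DataFrame  # index CATEGORIES (desc full..none), columns sites
    percentages: pd.DataFrame

    def site_counts(self, site: str) -> dict[str, int]:
        return {c: int(self.counts.loc[c, site]) for c in self.counts.index}

    def to_json_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(),
            "percentages": self.percentages.to_dict(),
        }


def tabulate_patterns(results: list[ConcordanceResult]) -> PatternTable:
    """Count and percentage table of match categories per site.

    Percentages are computed from counts within each site column by
    half-up rounding.  Sites appear in fixed order (foot, lower_leg)
    when present; rows run full, partial, none.
    """
    row_order = ["full", "partial", "none"]
    sites = [s for s in ("foot", "lower_leg") if any(r.site == s for r in results)]
    sites += sorted({r.site for r in results} - set(sites))
    counts = pd.DataFrame(0, index=row_order, columns=sites, dtype=int)
    for r in results:
        counts.loc[r.category, r.site] += 1
    pct = pd.DataFrame(0, index=row_order, columns=sites, dtype=int)
    for s in sites:
        tot = counts[s].sum()
        if tot:
            pct[s] = [round_half_up(100.0 * counts.loc[c, s] / tot) for c in row_order]
    return PatternTable(counts=counts, percentages=pct)


def compare_sites(table: PatternTable, method: str = "asymptotic"):
    """Ordinal Mann-Whitney comparison of the two site columns.

    Categories are coded none=0 < partial=1 < full=2 (the two-sided p is
    invariant to reversing the coding).  Returns the shared engine's
    result (U of the first site column, z, two-sided p).
    """
    sites = list(table.counts.columns)
    if len(sites) != 2:
        raise SiteComparisonError(f"need exactly two sites, have {sites}")
    code = {"none": 0, "partial": 1, "full": 2}
    samples = []
    for s in sites:
        vals = []
        for cat in table.counts.index:
            vals.extend([code[cat]] * int(table.counts.loc[cat, s]))
        if not vals:
            raise SiteComparisonError(f"site {s!r} has no patients")
        samples.append(np.array(vals, dtype=float))
    return mann_whitney(samples[0], samples[1], method=method)
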