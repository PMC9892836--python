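"""Shared two-sample rank-test engine.

One Mann-Whitney implementation serves both the ordinal site comparison
of concordance categories and the continuous clinical covariates: the
tie-corrected normal approximation without continuity correction (the
asymptotic default of common clinical statistics software).  An exact
enumeration mode is available for small samples and doubles as an
independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    z: float  # tie-corrected standard normal deviate (0 if degenerate)
    p: float  # two-sided p-value
    method: str


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney(x, y, method: str = "asymptotic") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``asymptotic``: tie-corrected normal approximation, no continuity
    correction.  If ties remove all rank variance (every pooled value
    identical) the test is degenerate: z = 0, p = 1.
    ``exact``: full enumeration of the permutation distribution of U
    (ties respected); total sample size capped at 22.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    if method == "asymptotic":
        if var <= 0:
            return MannWhitneyResult(u=u, z=0.0, p=1.0, method=method)
        z = (u - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        return MannWhitneyResult(u=u, z=float(z), p=p, method=method)

    if method == "exact":
        if n > 22:
            raise ValueError("exact enumeration limited to n1 + n2 <= 22")
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        dev = abs(u - mu)
        hits = 0
        for idx in combinations(range(n), n1):
            u_perm = ranks[list(idx)].sum() - offset
            if abs(u_perm - mu) >= dev - 1e-9:
                hits += 1
        p = hits / comb(n, n1)
        z = 0.0 if var <= 0 else float((u - mu) / np.sqrt(var))
        return MannWhitneyResult(u=u, z=z, p=float(p), method=method)

    raise ValueError(f"unknown method {method!r}")
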