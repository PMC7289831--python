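"""Nonparametric tests and the snout-deviation angle.

Two tests carry the comparisons in this pipeline: the two-sided
Mann–Whitney U test (interdomain-distance series of two trajectories) and
Fisher's exact test (phenotype-by-genotype penetrance counts).  Both are
implemented exactly:

* Mann–Whitney: U from rank sums with mid-ranks for ties.  The exact
  two-sided p doubles Pr(U <= min(U_x, U_y)) under the permutation null
  (capped at 1), computed from the classical count recurrence — no ties
  allowed in exact mode.  The normal approximation applies the tie
  correction and a continuity correction.  ``auto`` picks exact for
  tie-free samples with n_x + n_y <= 16, the approximation otherwise (so
  trajectory-scale inputs, n = 500 frames per arm, always use it).
* Fisher: two-sided p sums the hypergeometric probabilities of every table
  with the observed margins whose probability does not exceed the observed
  table's.

The snout-deviation angle α is the unsigned angle between the cranial
midline direction (posterior → anterior) and the posterior → snout-tip
vector on a 2-D landmark projection; α beyond a wild-type variability band
flags a deviant snout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "mann_whitney_u",
    "fisher_exact",
    "snout_deviation_angle",
    "classify_deviation",
    "exact_u_distribution",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d (e.g. affected/unaffected × genotype)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("table entries must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")


@lru_cache(maxsize=128)
def exact_u_distribution(m: int, n: int) -> np.ndarray:
    """Counts of labelings with U = u (u = 0..m·n) under the tie-free null.

    Classical recurrence w(u; m, n) = w(u − n; m − 1, n) + w(u; m, n − 1).
    Counts stay below 2**53 for the sample sizes exact mode is meant for,
    so float64 arithmetic is exact.
    """
    dp = np.zeros((m + 1, n + 1, m * n + 1))
    dp[0, :, 0] = 1.0
    dp[:, 0, 0] = 1.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            dp[i, j, :] = dp[i, j - 1, :]
            dp[i, j, j:] += dp[i - 1, j, : m * n + 1 - j]
    return dp[m, n]


def _rank_and_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    n_x, n_y = len(x), len(y)
    r_x = float(ranks[:n_x].sum())
    u_x = r_x - n_x * (n_x + 1) / 2.0
    u_y = n_x * n_y - u_x
    return u_x, u_y, combined


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test of two independent samples.

    ``mode``: ``"exact"`` (tie-free enumeration), ``"approx"`` (normal
    approximation with tie and continuity corrections) or ``"auto"``.
    The reported statistic is U of the first sample.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    n_x, n_y = len(x), len(y)
    u_x, u_y, combined = _rank_and_u(x, y)
    has_ties = len(np.unique(combined)) < len(combined)
    if mode == "auto":
        mode = "exact" if (not has_ties and n_x + n_y <= 16) else "approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free samples")
        dist = exact_u_distribution(n_x, n_y)
        total = dist.sum()
        u_min = min(u_x, u_y)
        p = 2.0 * dist[: int(round(u_min)) + 1].sum() / total
        return TestResult(statistic=u_x, p_value=min(p, 1.0), method="exact",
                          n_x=n_x, n_y=n_y)
    # normal approximation with tie correction and continuity correction
    n = n_x + n_y
    mean_u = n_x * n_y / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_u = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        # all observations identical: no evidence against the null
        return TestResult(statistic=u_x, p_value=1.0, method="normal_approx",
                          n_x=n_x, n_y=n_y)
    z = (abs(u_x - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return TestResult(statistic=u_x, p_value=p, method="normal_approx", n_x=n_x, n_y=n_y)


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test of a 2×2 table.

    p sums the hypergeometric probabilities (margins fixed) of all tables at
    most as probable as the observed one; the statistic is the sample odds
    ratio a·d / (b·c).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = sps.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    p = min(max(p, float(p_obs)), 1.0)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(statistic=odds, p_value=p, method="exact",
                      n_x=row1, n_y=c + d)


def snout_deviation_angle(tip, midline_anterior, midline_posterior) -> float:
    """Unsigned deviation angle α (degrees) of a snout tip from the midline.

    α is the angle between (posterior → anterior midline) and
    (posterior → tip) in a 2-D landmark projection; 0° means growth along
    the midline.
    """
    tip = np.asarray(tip, dtype=float)
    ant = np.asarray(midline_anterior, dtype=float)
    post = np.asarray(midline_posterior, dtype=float)
    v_mid = ant - post
    v_tip = tip - post
    n_mid = np.linalg.norm(v_mid)
    n_tip = np.linalg.norm(v_tip)
    if n_mid < 1e-12:
        raise ValueError("midline points coincide")
    if n_tip < 1e-12:
        raise ValueError("snout tip coincides with the posterior midline point")
    cosang = float(np.dot(v_mid, v_tip) / (n_mid * n_tip))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def classify_deviation(angle_deg: float, threshold_deg: float) -> bool:
    """True when α exceeds the wild-type variability band threshold."""
    return angle_deg > threshold_deg
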