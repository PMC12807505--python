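"""Small-sample group statistics: exact Fisher 2x2, exact Mann-Whitney U,
tie-corrected Kruskal-Wallis, and the ZT3 onset dichotomy.

The exact tests are implemented from first principles (hypergeometric
enumeration; dynamic-programming null distribution of U) because cohort
sizes here are 6-9 animals per group, where exactness is feasible and
removes approximation error. `scipy.stats` supplies only distribution
functions (hypergeom pmf, chi2/normal tails).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from scipy import stats as _st

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "MannWhitneyResult",
    "mann_whitney",
    "KruskalResult",
    "kruskal_wallis",
    "classify_onset",
]

# relative slack when comparing table probabilities in the two-sided
# probability-mass rule, so floating-point noise cannot flip inclusion
_PROB_RTOL = 1e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = outcome classes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value by the probability-mass rule.

    Conditional on both margins, the first cell is hypergeometric; the
    two-sided p sums the probabilities of all tables with the same margins
    whose probability does not exceed that of the observed table (within
    relative tolerance 1e-12). Degenerate margins (an all-zero row or
    column) give p = 1: only one table is compatible with the margins.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    n = table.total
    r1 = table.a + table.b
    c1 = table.a + table.c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = _st.hypergeom.pmf(support, n, r1, c1)
    p_obs = _st.hypergeom.pmf(table.a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + _PROB_RTOL)].sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


@lru_cache(maxsize=128)
def _u_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic (no ties).

    Let N(u; m, j) count the arrangements of m x's and j y's with exactly
    u pairs (x > y). Conditioning on whether the largest value is an x
    (it beats all j y's) or a y gives

        N(u; m, j) = N(u - j; m - 1, j) + N(u; m, j - 1)

    Returned as probabilities over u = 0..n1*n2.
    """
    max_u = n1 * n2
    # prev[m, u] = N(u; m, j-1); start at j = 0 where U is always 0
    prev = np.zeros((n1 + 1, max_u + 1), dtype=float)
    prev[:, 0] = 1.0
    for j in range(1, n2 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for m in range(1, n1 + 1):
            cur[m] = prev[m]
            cur[m, j:] += cur[m - 1, : max_u + 1 - j]
        prev = cur
    pmf = prev[n1]
    total = pmf.sum()
    assert abs(total - comb(n1 + n2, n1)) < 1e-6, "U-distribution recurrence failed"
    return pmf / total


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p_value: float
    method: str  # "exact" or "normal"


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact (full null distribution of U) when the combined sample size is
    <= 20 and there are no ties; otherwise the normal approximation with
    tie correction and continuity correction. Identical constant samples
    give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = _st.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if np.all(combined == combined[0]):
        return MannWhitneyResult(u=u1, p_value=1.0, method="degenerate")

    has_ties = len(np.unique(combined)) < n1 + n2
    if n1 + n2 <= 20 and not has_ties:
        pmf = _u_null_pmf(n1, n2)
        mu = n1 * n2 / 2.0
        dev = abs(u1 - mu)
        support = np.arange(n1 * n2 + 1)
        p = float(pmf[np.abs(support - mu) >= dev - 1e-9].sum())
        return MannWhitneyResult(u=u1, p_value=min(p, 1.0), method="exact")

    # Normal approximation with tie correction. No continuity correction:
    # this keeps the two-group test algebraically identical to the
    # tie-corrected Kruskal-Wallis chi-square test (H = z^2), so the two
    # reach the same accept/reject decision on the same data.
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return MannWhitneyResult(u=u1, p_value=1.0, method="degenerate")
    mu = n1 * n2 / 2.0
    z = (u1 - mu) / np.sqrt(sigma2)
    p = 2.0 * _st.norm.sf(abs(z))
    return MannWhitneyResult(u=u1, p_value=min(p, 1.0), method="normal")


@dataclass(frozen=True)
class KruskalResult:
    h: float
    p_value: float
    df: int


def kruskal_wallis(groups) -> KruskalResult:
    """Kruskal-Wallis H with tie correction, chi-square reference (k-1 df).

    All observations equal across groups gives H = 0 (the tie-corrected
    statistic's 0/0 limit), p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    combined = np.concatenate(groups)
    n = len(combined)
    ranks = _st.rankdata(combined)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(combined, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    if correction <= 0:  # every observation identical
        return KruskalResult(h=0.0, p_value=1.0, df=len(groups) - 1)
    h /= correction
    h = max(h, 0.0)
    df = len(groups) - 1
    return KruskalResult(h=float(h), p_value=float(_st.chi2.sf(h, df)), df=df)


def classify_onset(onset_zt: float | None, boundary: float = 3.0) -> bool | None:
    """Strictly-after-boundary labor-onset dichotomy (default ZT3).

    An onset exactly at the boundary counts as "before". Missing onsets
    return None.
    """
    if onset_zt is None or (isinstance(onset_zt, float) and np.isnan(onset_zt)):
        return None
    return bool(onset_zt > boundary)
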