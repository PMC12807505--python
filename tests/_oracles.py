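"""Independent brute-force oracles used only by the test suite.

Each oracle restates a definition directly (enumeration, O(n^2) scans,
numerical integration) and never shares code with the implementation it
checks.
"""

from __future__ import annotations

import itertools
from math import comb, lgamma, pi, sqrt

import numpy as np
from scipy.integrate import quad


def brute_force_peaks(x):
    """All strict local maxima (plateau midpoint, floor) with topographic
    prominence computed from the definition by direct scanning.

    Returns a list of (index, height, prominence).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    apexes = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                apexes.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    out = []
    for p in apexes:
        h = x[p]
        higher_left = [k for k in range(p) if x[k] > h]
        lo = (higher_left[-1] + 1) if higher_left else 0
        left_min = x[lo:p].min()
        higher_right = [k for k in range(p + 1, n) if x[k] > h]
        hi = higher_right[0] if higher_right else n
        right_min = x[p + 1 : hi].min()
        out.append((p, float(h), float(h - max(left_min, right_min))))
    return out


def fisher_two_sided_enum(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration with exact
    binomial coefficients."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: comb(r1, k) * comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)), 1.0)


def mann_whitney_enum(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled values to the two samples (no ties assumed)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)

    def u_of(sample, other):
        return sum(1 for a in sample for b in other if a > b)

    u_obs = u_of(x, y)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        first = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n1 + n2) if i not in set(idx)]
        u = u_of(first, rest)
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            count += 1
    return count / total


def t_cdf_numeric(t, df):
    """Lower-tail t probability by numerical integration of the density."""
    lognorm = lgamma((df + 1) / 2.0) - lgamma(df / 2.0) - 0.5 * np.log(df * pi)

    def pdf(u):
        return np.exp(lognorm - (df + 1) / 2.0 * np.log1p(u * u / df))

    val, _ = quad(pdf, -np.inf, t)
    return val


def gls_closed_form(X, y, omega):
    """beta = (X' Omega^-1 X)^-1 X' Omega^-1 y via explicit dense inverses."""
    Om_inv = np.linalg.inv(np.diag(omega))
    return np.linalg.inv(X.T @ Om_inv @ X) @ X.T @ Om_inv @ y
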