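"""Exact-test primitives shared across the package.

All 2x2 tests are parameterized through the hypergeometric distribution of
the top-left cell ``k`` given the margins: ``N`` items, ``K`` of which are
"successes", ``n`` drawn. Functions are vectorized over arrays of tables so
that thousands of tiles or promoter sets can be tested in one call.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import false_discovery_control, hypergeom

# relative tolerance used to decide which pmf terms count as "as extreme as
# observed" in the two-sided test (same convention as R's fisher.test)
_TWO_SIDED_REL_EPS = 1e-7


def _as_margins(a, b, c, d):
    """Map tables [[a, b], [c, d]] to hypergeometric (N, K, n, k) with k = a."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("2x2 table cells must be non-negative")
    N = a + b + c + d
    K = a + c
    n = a + b
    return N, K, n, a


def fisher_one_sided_p(a, b, c, d, alternative: str = "greater"):
    """One-sided Fisher exact p for tables [[a, b], [c, d]].

    ``greater``: probability of a top-left cell at least as large as observed
    (over-representation of row 1 in column 1); ``less``: at most as large.
    """
    N, K, n, k = _as_margins(a, b, c, d)
    if alternative == "greater":
        return hypergeom.sf(k - 1, N, K, n)
    if alternative == "less":
        return hypergeom.cdf(k, N, K, n)
    raise ValueError(f"unknown alternative: {alternative!r}")


def fisher_two_sided_p(a, b, c, d):
    """Two-sided Fisher exact p, vectorized.

    Sums every hypergeometric pmf term not exceeding the observed term (with
    a small relative tolerance for floating-point ties).
    """
    N, K, n, k = _as_margins(a, b, c, d)
    N, K, n, k = np.broadcast_arrays(N, K, n, k)
    shape = N.shape
    N, K, n, k = (x.ravel() for x in (N, K, n, k))

    p_obs = hypergeom.pmf(k, N, K, n)
    lo = np.maximum(0, n - (N - K))
    hi = np.minimum(n, K)
    total = np.zeros(N.shape, dtype=float)
    jmax = int(hi.max(initial=0))
    thresh = p_obs * (1.0 + _TWO_SIDED_REL_EPS)
    for j in range(0, jmax + 1):
        active = (j >= lo) & (j <= hi)
        if not active.any():
            continue
        pj = np.zeros_like(total)
        pj[active] = hypergeom.pmf(j, N[active], K[active], n[active])
        total += np.where(active & (pj <= thresh), pj, 0.0)
    return np.minimum(total, 1.0).reshape(shape)


def bh_adjust(pvalues):
    """Benjamini-Hochberg adjusted q-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = false_discovery_control(p[ok], method="bh")
    return q


def odds_ratio(a, b, c, d, haldane: bool = True):
    """Sample odds ratio (a*d)/(b*c); Haldane 0.5 correction when a cell is 0."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if haldane:
        zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        corr = np.where(zero, 0.5, 0.0)
        a, b, c, d = a + corr, b + corr, c + corr, d + corr
    return (a * d) / (b * c)
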