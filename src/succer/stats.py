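"""Statistical kernels: correlation, signed-rank test, enrichment tails.

The Wilcoxon signed-rank test is implemented here rather than delegated,
because the pipeline needs exact tie-handling semantics: zero differences are
dropped, tied absolute differences receive average ranks, the exact null
distribution (conditional on the observed ranks) is computed by dynamic
programming for small samples, and larger samples use a tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class PairedTestResult:
    W: float
    n_eff: int
    p: float


def pearson_fc_correlation(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


_EXACT_LIMIT = 25


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    W is the sum of ranks of positive differences. Exact p by enumeration of
    the 2^n sign assignments (rank-sum DP) for n_eff <= 25; otherwise the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction toward the mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no information: all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # == n(n+1)/2
    if n <= _EXACT_LIMIT:
        p = _exact_two_sided_p(ranks, w_pos)
    else:
        mu = total / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        sd = np.sqrt(var)
        z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / sd if w_pos != mu else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return PairedTestResult(w_pos, n, p)


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact conditional two-sided p given the observed (possibly tied) ranks.

    Ranks are doubled so average ranks (x.5) become integers; the DP counts
    sign assignments by achievable doubled rank-sum.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total2 = int(r2.sum())
    counts = np.zeros(total2 + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r if r else None]
    counts /= counts.sum()
    w2 = int(round(2 * w_obs))
    p_ge = counts[w2:].sum()
    p_le = counts[: w2 + 1].sum()
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn).

    p = sum_{i=k..min(K,n)} C(K,i) C(N-K, n-i) / C(N,n).
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"invalid hypergeometric bounds K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def binom_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must be a probability")
    if k == 0:
        return 1.0
    p = float(sps.binom.sf(k - 1, n, p0))
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q
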