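"""Statistical kernels shared by all pipeline stages.

Small-sample inference is the rule in morph-comparison qPCR studies (group
sizes of 2-13 birds), so the Mann-Whitney U test is computed from the exact
null distribution whenever feasible: the number of rank arrangements giving
each value of U is counted by dynamic programming, rather than relying on the
large-sample normal approximation. The remaining kernels -- one-sample t,
one-way ANOVA with Tukey HSD, Benjamini-Hochberg FDR and Bonferroni-Dunn
family-wise adjustment -- cover every test the downstream stages run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st


class InvalidParameterError(ValueError):
    """A parameter is outside its valid domain (e.g. df <= 0, p outside [0,1])."""


class DegenerateInputError(ValueError):
    """The data cannot support the test (too few values, zero variance)."""


#: largest n1*n2 for which the exact U null distribution is enumerated;
#: beyond this (or in the presence of ties) the tie-corrected normal
#: approximation is used.
EXACT_U_LIMIT = 400


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``df`` is the (possibly fractional) degrees of freedom for t/F style
    tests, or the pair of group sizes for rank tests. ``p_adjusted`` and
    ``n_tests`` are filled in only when a multiplicity correction was
    applied.
    """

    statistic: float
    df: float | tuple[int, int]
    p_two_sided: float
    p_adjusted: float | None = None
    n_tests: int | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise InvalidParameterError(f"p_two_sided={self.p_two_sided} outside [0,1]")
        if self.p_adjusted is not None:
            if not (0.0 <= self.p_adjusted <= 1.0):
                raise InvalidParameterError(f"p_adjusted={self.p_adjusted} outside [0,1]")
            if self.p_adjusted < self.p_two_sided - 1e-12:
                raise InvalidParameterError("p_adjusted below the raw p-value")


@dataclass(frozen=True)
class UNullDistribution:
    """Exact null distribution of the Mann-Whitney U statistic.

    ``pmf[u]`` is the probability of observing U = u under random ranking of
    ``n1`` + ``n2`` exchangeable observations, for u in [0, n1*n2].
    """

    n1: int
    n2: int
    pmf: np.ndarray

    def cdf(self, u: float) -> float:
        """P(U <= u)."""
        k = int(math.floor(u + 1e-9))
        if k < 0:
            return 0.0
        return float(self.pmf[: min(k, self.n1 * self.n2) + 1].sum())

    def sf(self, u: float) -> float:
        """P(U > u)."""
        return 1.0 - self.cdf(u)


def u_null_distribution(n1: int, n2: int) -> UNullDistribution:
    """Enumerate the exact Mann-Whitney U null distribution.

    Uses the classical recurrence on arrangement counts
    ``c(u; m, n) = c(u - n; m - 1, n) + c(u; m, n - 1)``,
    i.e. the coefficients of the Gaussian binomial, so the full pmf for
    group sizes ``n1``, ``n2`` costs O(n1 * n2 * n1*n2) additions.
    """
    if n1 < 1 or n2 < 1:
        raise InvalidParameterError("group sizes must be positive integers")
    umax = n1 * n2
    # counts[m, u] = number of arrangements of m X's among the current n Y's
    counts = np.zeros((n1 + 1, umax + 1))
    counts[0, 0] = 1.0
    prev = counts.copy()
    prev[:, 0] = 1.0  # n = 0: only u = 0 attainable for any m
    for n in range(1, n2 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for m in range(1, n1 + 1):
            cur[m] = prev[m]
            cur[m, n:] += cur[m - 1, : umax + 1 - n]
        prev = cur
    total = math.comb(n1 + n2, n1)
    pmf = prev[n1] / total
    return UNullDistribution(n1=n1, n2=n2, pmf=pmf)


def t_two_sided_p(t: float, df: float) -> float:
    """Two-sided tail probability 2*P(T_df >= |t|) of Student's t."""
    if not df > 0:
        raise InvalidParameterError(f"df must be positive, got {df}")
    return float(2.0 * _st.t.sf(abs(t), df))


def one_sample_t(values: Sequence[float], mu0: float) -> TestResult:
    """One-sample t-test of the mean against the hypothesized value ``mu0``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError(f"need >=2 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("zero variance: t statistic undefined")
    n = x.size
    stat = (x.mean() - mu0) / (sd / math.sqrt(n))
    df = n - 1
    return TestResult(statistic=float(stat), df=float(df),
                      p_two_sided=t_two_sided_p(stat, df), method="one-sample t")


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test with exact small-sample null.

    U is reported as min(U1, U2) and the two-sided p-value doubles the lower
    tail P(U_null <= U), capped at 1 (the null pmf is symmetric, so doubling
    equals summing both tails). Exact enumeration is used for
    n1*n2 <= ``EXACT_U_LIMIT`` and tie-free data; otherwise the tie-corrected
    normal approximation with continuity correction is used.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise InvalidParameterError("both groups must be nonempty")
    n1, n2 = xa.size, ya.size
    combined = np.concatenate([xa, ya])
    ranks = _st.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    has_ties = np.unique(combined).size < combined.size
    if n1 * n2 <= EXACT_U_LIMIT and not has_ties:
        dist = u_null_distribution(n1, n2)
        p = min(1.0, 2.0 * dist.cdf(u))
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            raise DegenerateInputError("all values tied: U variance is zero")
        z = (u - mu + 0.5) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * _st.norm.cdf(z))
        method = "normal-approx"
    return TestResult(statistic=float(u), df=(n1, n2), p_two_sided=float(p),
                      method=method)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted ascending, each p_(i) becomes p_(i)*m/i, then monotonicity is
    enforced from the largest rank down and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def bonferroni_dunn(p: float, m: int) -> float:
    """Bonferroni-Dunn family-wise adjustment: min(1, p*m)."""
    if not (0.0 <= p <= 1.0):
        raise InvalidParameterError(f"p={p} outside [0,1]")
    if m < 1:
        raise InvalidParameterError(f"m must be >= 1, got {m}")
    return min(1.0, p * m)


def anova_tukey(
    groups: Sequence[Sequence[float]],
) -> tuple[TestResult, dict[tuple[int, int], TestResult]]:
    """One-way ANOVA F-test plus Tukey HSD pairwise comparisons.

    Returns the omnibus result (df as the (k-1, N-k) pair) and a dict keyed
    by group-index pair with the Tukey-adjusted pairwise results (statistic
    is the mean difference group_i - group_j).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidParameterError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise DegenerateInputError("every group needs >= 2 values")
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0.0:
        raise DegenerateInputError("all values identical: F undefined")
    k = len(arrays)
    n_total = allv.size
    f, p = _st.f_oneway(*arrays)
    omnibus = TestResult(statistic=float(f), df=(k - 1, n_total - k),
                         p_two_sided=float(p), method="one-way ANOVA")
    hsd = _st.tukey_hsd(*arrays)
    pairwise: dict[tuple[int, int], TestResult] = {}
    for i in range(k):
        for j in range(i + 1, k):
            pairwise[(i, j)] = TestResult(
                statistic=float(hsd.statistic[i, j]),
                df=float(n_total - k),
                p_two_sided=float(min(1.0, hsd.pvalue[i, j])),
                method="Tukey HSD",
            )
    return omnibus, pairwise
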