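"""Hypothesis-testing battery for comparing volume-measurement methods.

The battery follows a fixed protocol: a Kolmogorov-Smirnov normality gate
(alpha = 0.05) decides between the paired t-test and the Wilcoxon
matched-pairs signed-rank test for location differences in VPE/VPD; an
F-test compares VPE variances (precision); Fisher's z-test compares Pearson
correlations (accuracy); and posterior or confidence intervals are compared
with a CI-overlap rule. Significance for the location/variance/correlation
tests is declared at p < 0.01.

The Wilcoxon test is implemented here with the exact null distribution for
small samples (n <= 25 after removing zero differences), computed by
counting sign assignments, so its p-values coincide bit-for-bit with full
2^n enumeration; larger samples use the normal approximation with tie and
continuity corrections. Zero differences are dropped (Wilcoxon convention);
the all-zero case returns p = 1, i.e. no evidence of a difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "ks_normality",
    "wilcoxon_signed_rank",
    "paired_location_test",
    "variance_f_test",
    "fisher_z_test",
    "ci_overlap_significant",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``significant`` is ``p_value < alpha`` for every p-based test.
    """

    test_name: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool

    def as_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def _result(name: str, statistic: float, p: float, alpha: float) -> TestResult:
    p = float(min(max(p, 0.0), 1.0))
    return TestResult(name, float(statistic), p, float(alpha), bool(p < alpha))


def ks_normality(values, alpha: float = 0.05) -> TestResult:
    """One-sample KS test against N(mean, sd) with parameters from the sample.

    ``significant`` means normality is rejected. Estimating the parameters
    from the same sample makes the nominal KS distribution conservative
    (true rejection rate below alpha); the protocol uses the naive test as
    stated, without a Lilliefors correction.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    res = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return _result("ks_normality", res.statistic, res.pvalue, alpha)


def _signed_rank_null_counts(ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments by W+ value, in half-rank units.

    ``ranks`` are midranks; doubling makes them integers (ties give .5
    midranks), so ``counts[w]`` is the number of the 2^n sign vectors whose
    positive-rank sum equals ``w / 2``. Counts are exact in float64 for
    n <= 25 (< 2^53).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    return counts


def wilcoxon_signed_rank(a, b, alpha: float = 0.01) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Reports W+ (sum of ranks of positive differences) as the statistic.
    Exact null distribution for n <= 25 after zero removal; otherwise the
    normal approximation with tie correction and a 0.5 continuity
    correction. Two-sided p is ``min(1, 2 * min(P(W+ <= w), P(W+ >= w)))``.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be 1-D with equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return _result("wilcoxon", 0.0, 1.0, alpha)

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_WILCOXON_MAX_N:
        counts = _signed_rank_null_counts(ranks)
        w2 = int(round(2 * w_plus))
        total = counts.size - 1
        n_le = counts[: w2 + 1].sum()
        n_ge = counts[w2:].sum()
        p = 2.0 * min(n_le, n_ge) / 2.0**n
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        dev = w_plus - mean
        # continuity correction shrinks the deviation toward the mean
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return _result("wilcoxon", w_plus, p, alpha)


def paired_location_test(a, b, alpha: float = 0.01, normality_alpha: float = 0.05) -> TestResult:
    """Normality-gated paired location test.

    Runs the KS normality gate on each of the two samples; if neither
    rejects, a paired t-test is used, otherwise the Wilcoxon matched-pairs
    signed-rank test. The chosen test is reported in ``test_name``
    (``"paired_t"`` or ``"wilcoxon"``). Identical samples return p = 1.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be 1-D with equal length")
    if a.size < 5:
        raise ValueError(f"need at least 5 pairs, got {a.size}")
    if np.all(a == b):
        return _result("paired_t", 0.0, 1.0, alpha)

    gaussian = not (
        ks_normality(a, normality_alpha).significant
        or ks_normality(b, normality_alpha).significant
    )
    if gaussian:
        res = stats.ttest_rel(a, b)
        return _result("paired_t", res.statistic, res.pvalue, alpha)
    return wilcoxon_signed_rank(a, b, alpha)


def variance_f_test(a, b, alpha: float = 0.01) -> TestResult:
    """Two-sided F-test for equality of two variances.

    ``F = s_a^2 / s_b^2`` on ``(n_a - 1, n_b - 1)`` degrees of freedom;
    two-sided p doubles the smaller tail.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per sample")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("F-test undefined for a constant sample")
    f = np.var(a, ddof=1) / np.var(b, ddof=1)
    dfn, dfd = a.size - 1, b.size - 1
    p = 2.0 * min(stats.f.cdf(f, dfn, dfd), stats.f.sf(f, dfn, dfd))
    return _result("f_test", f, p, alpha)


def fisher_z_test(r1: float, n1: int, r2: float, n2: int, alpha: float = 0.01) -> TestResult:
    """Fisher z-test comparing two independent Pearson correlations.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r!r}")
    for n in (n1, n2):
        if n < 4:
            raise ValueError(f"need n >= 4 per sample, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return _result("fisher_z", z, p, alpha)


def ci_overlap_significant(
    est_a: float,
    ci_a: tuple[float, float],
    est_b: float,
    ci_b: tuple[float, float],
    *,
    symmetric: bool = True,
) -> bool:
    """CI-overlap significance rule for interval-summarized estimates.

    Two estimates differ significantly when neither point estimate lies
    inside the other's interval (the symmetric, conservative reading of "no
    overlap between the CI of one score and the point estimate of the
    other"). With ``symmetric=False`` one exclusion suffices. Interval
    endpoints are inclusive.
    """
    for est, (lo, hi) in ((est_a, ci_a), (est_b, ci_b)):
        if lo > hi:
            raise ValueError(f"malformed interval ({lo}, {hi}): low > high")
        if not (lo <= est <= hi):
            raise ValueError(f"estimate {est} lies outside its own interval ({lo}, {hi})")
    a_out = not (ci_b[0] <= est_a <= ci_b[1])
    b_out = not (ci_a[0] <= est_b <= ci_a[1])
    return (a_out and b_out) if symmetric else (a_out or b_out)
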