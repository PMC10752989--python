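"""Accuracy and test-retest reliability metrics for volume measurements.

* VPE — signed volume percentage error of a prediction against manual ground
  truth; its mean measures systematic bias, its SD measures precision.
* VPD — symmetric volume percentage difference between test and retest
  sessions; lower means better short-interval reproducibility.
* Pearson CC with the interpretation bands conventional in the volumetry
  literature (> 0.9 very strong, 0.7-0.9 strong, 0.4-0.7 moderate,
  < 0.4 weak or negligible).
* Consistency ICC — single-rater, two-way mixed-effects intraclass
  correlation, insensitive to a constant session offset, with an F-based
  95% confidence interval and reliability bands (< 0.75 poor, 0.75-0.95
  good, > 0.95 excellent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SummaryStats",
    "ICCResult",
    "vpe",
    "vpe_summary",
    "vpd",
    "pearson_cc",
    "cc_band",
    "icc_band",
    "icc_consistency",
]


@dataclass(frozen=True)
class SummaryStats:
    """Distribution summary: median, mean, quartiles, sample SD."""

    median: float
    mean: float
    p25: float
    p75: float
    sd: float

    def as_dict(self) -> dict[str, float]:
        return {"median": self.median, "mean": self.mean, "p25": self.p25,
                "p75": self.p75, "sd": self.sd}


@dataclass(frozen=True)
class ICCResult:
    """Consistency ICC point estimate with its 95% CI and reliability band."""

    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_sessions: int
    band: str = field(init=False)
    model_label: str = field(init=False, default="two-way mixed, consistency, single rater")

    def __post_init__(self):
        object.__setattr__(self, "band", icc_band(self.estimate))

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_subjects": self.n_subjects,
            "k_sessions": self.k_sessions,
            "band": self.band,
            "model_label": self.model_label,
        }


def vpe(v_pred: float, v_gt: float) -> float:
    """Signed volume percentage error, ``100 * (v_pred - v_gt) / v_gt``.

    Underestimation is negative. Scale-invariant: common rescaling of both
    volumes leaves the VPE unchanged.
    """
    v_pred, v_gt = np.asarray(v_pred, dtype=float), np.asarray(v_gt, dtype=float)
    if np.any(v_gt <= 0):
        raise ValueError("ground-truth volume must be positive")
    out = 100.0 * (v_pred - v_gt) / v_gt
    return float(out) if out.ndim == 0 else out


def vpd(v_test: float, v_retest: float) -> float:
    """Volume percentage difference, ``100 * 2 * |v_test - v_retest| / (v_test + v_retest)``.

    Symmetric in its arguments, zero iff the volumes agree, bounded above by
    200 for positive volumes, and invariant to common rescaling.
    """
    v_test, v_retest = np.asarray(v_test, dtype=float), np.asarray(v_retest, dtype=float)
    if np.any(v_test <= 0) or np.any(v_retest <= 0):
        raise ValueError("both volumes must be positive")
    out = 100.0 * 2.0 * np.abs(v_test - v_retest) / (v_test + v_retest)
    return float(out) if out.ndim == 0 else out


def vpe_summary(values) -> SummaryStats:
    """Median, mean, 25th/75th percentile and sample SD of a VPE list.

    Percentiles use linear interpolation between order statistics; SD uses
    the n-1 denominator and needs at least two values.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    if x.size < 2:
        raise ValueError("sample SD needs at least two values")
    p25, med, p75 = np.percentile(x, [25, 50, 75])
    return SummaryStats(
        median=float(med),
        mean=float(np.mean(x)),
        p25=float(p25),
        p75=float(p75),
        sd=float(np.std(x, ddof=1)),
    )


def cc_band(r: float) -> str:
    """Interpretation band of a Pearson CC; boundary values take the lower band."""
    if r > 0.9:
        return "very strong"
    if r > 0.7:
        return "strong"
    if r > 0.4:
        return "moderate"
    return "weak or negligible"


def icc_band(icc: float) -> str:
    """Reliability band of an ICC: < 0.75 poor, 0.75-0.95 good, > 0.95 excellent."""
    if icc < 0.75:
        return "poor"
    if icc > 0.95:
        return "excellent"
    return "good"


def pearson_cc(x, y) -> tuple[float, str]:
    """Sample Pearson correlation with its interpretation band."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r = float(stats.pearsonr(x, y).statistic)
    return r, cc_band(r)


def icc_consistency(table, alpha: float = 0.05) -> ICCResult:
    """Consistency ICC (single rater, two-way mixed) of an n x k volume matrix.

    Two-way ANOVA without interaction: with between-subjects mean square
    ``MS_R`` and residual mean square ``MS_E`` (after removing the session
    effect),

        ICC = (MS_R - MS_E) / (MS_R + (k - 1) * MS_E)

    and the (1 - alpha) CI is the F-based interval: the observed
    ``F = MS_R / MS_E`` on ``(n-1, (n-1)(k-1))`` degrees of freedom is
    divided/multiplied by the critical F and mapped back through
    ``(F' - 1) / (F' + k - 1)``. The consistency form absorbs any constant
    session offset into the session effect, so a fixed test-retest bias does
    not lower the ICC.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be a 2-D n x k matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 sessions, got {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed; analyze complete pairs only")
    if np.ptp(x) == 0:
        raise ValueError("zero total variance: ICC undefined")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    df_e = (n - 1) * (k - 1)
    ms_e = np.sum(resid**2) / df_e

    if ms_e == 0.0:
        # Perfect consistency: the F interval degenerates to the point 1.
        return ICCResult(estimate=1.0, ci_low=1.0, ci_high=1.0, n_subjects=n, k_sessions=k)

    est = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    f_obs = ms_r / ms_e
    f_low = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df_e)
    f_up = f_obs * stats.f.ppf(1 - alpha / 2, df_e, n - 1)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_up - 1) / (f_up + k - 1)
    return ICCResult(
        estimate=float(est),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_subjects=n,
        k_sessions=k,
    )
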