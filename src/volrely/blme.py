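"""Bayesian linear mixed-effects (BLME) model for longitudinal volumes.

For volumes ``V_ij`` of subject ``i`` at time ``t_ij`` (months from the
subject's own baseline) the model is

    V_ij ~ N(alpha_i + beta_i * t_ij, sigma^2)
    alpha_i ~ N(alpha0, tau^2)         beta_i ~ N(beta0, rho^2)
    alpha0, beta0 ~ N(0, prior_loc_sd^2)
    sigma, tau, rho ~ HalfCauchy(prior_scale)

``tau`` is the between-subject variability, ``sigma`` the within-subject
variability, and the headline reliability statistic is the variance ratio
``r = tau / sigma``: a good longitudinal biomarker discriminates subjects
(large tau) while staying reproducible within subject (small sigma). ``r``
is invariant to linear rescaling of the volumes, so volumes are standardized
by the grand mean/SD before fitting by default — that is the scale on which
the default priors (SD 10, half-Cauchy scale 5) are weakly informative —
and location/scale summaries are reported on both the sampled and the raw
scale.

Sampling is Metropolis-within-Gibbs: subject effects and population
locations have conjugate Gaussian full conditionals; the three scales get
random-walk Metropolis updates on the log scale (with the half-Cauchy prior
and log-scale Jacobian), step sizes adapted during warmup only. Convergence
is enforced: the fit raises unless every parameter's split-rhat is at or
below the threshold (default 1.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .inference import ci_overlap_significant

__all__ = [
    "BLMESpec",
    "BLMEPosterior",
    "ConvergenceError",
    "normalize_time",
    "log_posterior",
    "fit_blme",
    "variance_ratio",
    "compare_blme",
]

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)

#: Metropolis scans of the (sigma, rho) pair per Gibbs iteration.
_SCALE_SCANS = 5


class ConvergenceError(RuntimeError):
    """The MCMC fit failed its convergence diagnostics."""


@dataclass(frozen=True)
class BLMESpec:
    """Priors, sampler settings and seed for one BLME fit.

    The defaults reproduce the model's stated priors on the standardized
    scale: N(0, 10^2) on the population intercept and slope, half-Cauchy
    with scale 5 on the three SDs.
    """

    prior_loc_sd: float = 10.0
    prior_scale: float = 5.0
    standardize: bool = True
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.01
    fix_tau: float | None = None
    fix_rho: float | None = None
    fix_sigma: float | None = None

    def __post_init__(self):
        if self.prior_loc_sd <= 0 or self.prior_scale <= 0:
            raise ValueError("prior_loc_sd and prior_scale must be positive")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.n_warmup < 1 or self.n_draws < 1:
            raise ValueError("n_warmup and n_draws must be positive")
        for name in ("fix_tau", "fix_sigma"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")
        if self.fix_rho is not None and self.fix_rho < 0:
            raise ValueError("fix_rho must be non-negative when given")


@dataclass
class BLMEPosterior:
    """MCMC draws and summaries of one BLME fit.

    ``draws`` maps parameter names to arrays of shape (chains, draws) for
    scalars and (chains, draws, n_subjects) for the subject effects, on the
    sampled (possibly standardized) scale. ``summaries`` holds posterior
    mean and central 95% credible interval per parameter on the sampled
    scale plus ``*_raw`` entries back-transformed to the input volume scale.
    ``r`` draws are tau / sigma elementwise.
    """

    draws: dict[str, np.ndarray]
    summaries: dict[str, dict[str, float]]
    r_mean: float
    r_ci: tuple[float, float]
    rhat: dict[str, float]
    scale_info: dict
    subjects: list[str]
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"parameter": k, **v} for k, v in self.summaries.items()]
        return pd.DataFrame(rows).set_index("parameter")

    def draws_frame(self) -> pd.DataFrame:
        """Flat rectangular draws table: chain, iteration, one column per scalar."""
        chains, ndraws = self.draws["tau"].shape
        cols = {
            "chain": np.repeat(np.arange(chains), ndraws),
            "iteration": np.tile(np.arange(ndraws), chains),
        }
        for name in ("alpha0", "beta0", "tau", "sigma", "rho", "r"):
            cols[name] = self.draws[name].ravel()
        return pd.DataFrame(cols)


def normalize_time(table: pd.DataFrame) -> pd.DataFrame:
    """Shift each subject's times so its earliest session is t = 0 months.

    The shift is computed per (subject, method, roi) series so methods with
    different session coverage stay internally consistent.
    """
    if "time_months" not in table.columns:
        raise ValueError("table lacks the 'time_months' column needed to normalize time")
    if table["time_months"].isna().any():
        raise ValueError("time_months contains missing values; baseline is undefined")
    out = table.copy()
    baseline = out.groupby(["subject_id", "method", "roi"])["time_months"].transform("min")
    out["time_months"] = out["time_months"] - baseline
    return out


def _norm_logpdf(x, mu, sd):
    return -_HALF_LOG_2PI - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def _half_cauchy_logpdf(x, scale):
    return np.log(2.0 / np.pi) - np.log(scale) - np.log1p((x / scale) ** 2)


def _design(table: pd.DataFrame):
    subjects = sorted(table["subject_id"].unique())
    idx = {s: i for i, s in enumerate(subjects)}
    si = table["subject_id"].map(idx).to_numpy()
    y = table["volume"].to_numpy(dtype=float)
    t = table["time_months"].to_numpy(dtype=float)
    return subjects, si, y, t


def log_posterior(params: dict, table: pd.DataFrame, spec: BLMESpec) -> float:
    """Exact log posterior density (up to nothing — all terms included).

    ``params`` must contain scalars ``alpha0, beta0, tau, sigma, rho`` and
    arrays ``alpha, beta`` of subject effects ordered by sorted subject id.
    Non-positive scales return ``-inf`` (rejected region) rather than
    raising; the value is finite everywhere else.
    """
    tau, sigma, rho = (float(params[k]) for k in ("tau", "sigma", "rho"))
    if tau <= 0 or sigma <= 0 or rho <= 0:
        return -np.inf
    alpha0, beta0 = float(params["alpha0"]), float(params["beta0"])
    a = np.asarray(params["alpha"], dtype=float)
    b = np.asarray(params["beta"], dtype=float)

    subjects, si, y, t = _design(table)
    if a.size != len(subjects) or b.size != len(subjects):
        raise ValueError(
            f"alpha/beta must have one entry per subject ({len(subjects)}), "
            f"got {a.size} and {b.size}"
        )

    lp = _norm_logpdf(y, a[si] + b[si] * t, sigma).sum()
    lp += _norm_logpdf(a, alpha0, tau).sum()
    lp += _norm_logpdf(b, beta0, rho).sum()
    lp += _norm_logpdf(alpha0, 0.0, spec.prior_loc_sd)
    lp += _norm_logpdf(beta0, 0.0, spec.prior_loc_sd)
    lp += _half_cauchy_logpdf(sigma, spec.prior_scale)
    lp += _half_cauchy_logpdf(tau, spec.prior_scale)
    lp += _half_cauchy_logpdf(rho, spec.prior_scale)
    return float(lp)


def _run_chain(rng, y, t, si, n_subj, spec, sd_y):
    """One MCMC chain of the fully collapsed Metropolis-within-Gibbs sampler.

    Per iteration: (1) the three scale SDs are updated by log-scale
    random-walk Metropolis against the likelihood with BOTH subject effects
    (a_i, b_i) integrated out analytically (rank-2 Woodbury identities, 2x2
    closed forms), several scans per iteration; (2) the population locations
    (alpha0, beta0) are drawn from their exact bivariate Gaussian conditional
    under the same effect-marginalized model; (3) the subject effects are
    refreshed jointly from their bivariate Gaussian full conditional.
    Collapsing the effects removes the funnel coupling that makes centered
    Gibbs mix slowly when a variance component is small relative to its
    sampling error, so mixing is limited only by three scalar Metropolis
    moves against their joint marginal.
    """
    n_i = np.bincount(si, minlength=n_subj).astype(float)
    sum_t = np.bincount(si, weights=t, minlength=n_subj)
    sum_t2 = np.bincount(si, weights=t * t, minlength=n_subj)
    sum_y = np.bincount(si, weights=y, minlength=n_subj)
    sum_ty = np.bincount(si, weights=t * y, minlength=n_subj)
    s0_prec = 1.0 / spec.prior_loc_sd**2

    # dispersed, data-informed inits
    ybar = sum_y / n_i
    alpha0 = float(np.mean(ybar)) + rng.normal(0, 0.25 * sd_y)
    beta0 = rng.normal(0, 0.02 * sd_y)
    tau = spec.fix_tau if spec.fix_tau is not None else max(np.std(ybar), 0.1 * sd_y) * np.exp(rng.uniform(-1, 1))
    rho = spec.fix_rho if spec.fix_rho is not None else 0.1 * sd_y * np.exp(rng.uniform(-1, 1))
    sigma = spec.fix_sigma if spec.fix_sigma is not None else 0.5 * sd_y * np.exp(rng.uniform(-1, 1))
    a = ybar.copy()
    b = np.full(n_subj, beta0)

    steps = {"sigma": 0.3, "tau": 0.3, "rho": 0.3}
    accepts = {"sigma": 0, "tau": 0, "rho": 0}
    sampled = [
        name
        for name, fix in (("sigma", spec.fix_sigma), ("tau", spec.fix_tau), ("rho", spec.fix_rho))
        if fix is None
    ]
    rho_zero = spec.fix_rho == 0.0

    total = spec.n_warmup + spec.n_draws
    out = {
        "alpha0": np.empty(spec.n_draws),
        "beta0": np.empty(spec.n_draws),
        "tau": np.empty(spec.n_draws),
        "sigma": np.empty(spec.n_draws),
        "rho": np.empty(spec.n_draws),
        "alpha": np.empty((spec.n_draws, n_subj)),
        "beta": np.empty((spec.n_draws, n_subj)),
    }

    def marginal_loglik(sig, ta, rh, sr, str_, total_rr):
        """log N(r_i; 0, sig^2 I + ta^2 11' + rh^2 tt') summed over subjects.

        r_i = y_i - alpha0 - beta0 t_i enters through its per-subject sums
        sr = sum(r), str_ = sum(t r) and the overall total_rr = sum(r^2).
        When rho is pinned at zero the slope term drops to rank 1.
        """
        s2 = sig * sig
        if rh == 0.0:
            denom = s2 + ta * ta * n_i
            quad = total_rr / s2 - float(np.sum((ta * ta / s2) * sr**2 / denom))
            logdet = float(np.sum((n_i - 1) * np.log(s2) + np.log(denom)))
            return -0.5 * (logdet + quad)
        a00 = 1.0 / (ta * ta) + n_i / s2
        a01 = sum_t / s2
        a11 = 1.0 / (rh * rh) + sum_t2 / s2
        det_a = a00 * a11 - a01 * a01
        logdet = float(
            np.sum(n_i * np.log(s2) + np.log(det_a))
        ) + n_subj * (np.log(ta * ta) + np.log(rh * rh))
        v_av = (a11 * sr**2 - 2.0 * a01 * sr * str_ + a00 * str_**2) / det_a
        quad = total_rr / s2 - float(np.sum(v_av)) / (s2 * s2)
        return -0.5 * (logdet + quad)

    for it in range(total):
        # (1) scales against the effect-marginalized likelihood
        r = y - alpha0 - beta0 * t
        sr = sum_y - alpha0 * n_i - beta0 * sum_t
        str_ = sum_ty - alpha0 * sum_t - beta0 * sum_t2
        total_rr = float(r @ r)
        cur = {"sigma": sigma, "tau": tau, "rho": rho}
        ll_cur = marginal_loglik(cur["sigma"], cur["tau"], cur["rho"], sr, str_, total_rr)
        for _ in range(_SCALE_SCANS):
            for name in sampled:
                prop = dict(cur)
                prop[name] = cur[name] * np.exp(steps[name] * rng.standard_normal())
                ll_prop = marginal_loglik(prop["sigma"], prop["tau"], prop["rho"], sr, str_, total_rr)
                logr = (
                    ll_prop
                    + _half_cauchy_logpdf(prop[name], spec.prior_scale)
                    + np.log(prop[name])
                ) - (
                    ll_cur
                    + _half_cauchy_logpdf(cur[name], spec.prior_scale)
                    + np.log(cur[name])
                )
                if np.log(rng.random()) < logr:
                    cur, ll_cur = prop, ll_prop
                    accepts[name] += 1
        sigma, tau, rho = cur["sigma"], cur["tau"], cur["rho"]

        # (2) (alpha0, beta0) from their exact Gaussian conditional under the
        # effect-marginalized model: precision sum_i U' Sigma_i^-1 U + I/s0^2
        s2 = sigma * sigma
        w00 = n_i / s2
        w01 = sum_t / s2
        w11 = sum_t2 / s2
        wy0 = sum_y / s2
        wy1 = sum_ty / s2
        if rho_zero:
            # rank-1: Sigma = s2 I + tau^2 11'
            denom = s2 + tau * tau * n_i
            shrink = tau * tau / (s2 * denom)
            p00 = w00 - shrink * n_i * n_i
            p01 = w01 - shrink * n_i * sum_t
            p11 = w11 - shrink * sum_t * sum_t
            m0 = wy0 - shrink * n_i * sum_y
            m1 = wy1 - shrink * sum_t * sum_y
        else:
            a00 = 1.0 / (tau * tau) + w00
            a01 = w01
            a11 = 1.0 / (rho * rho) + w11
            det_a = a00 * a11 - a01 * a01
            # C = A^-1 W,  B = A^-1 w
            c00 = (a11 * w00 - a01 * w01) / det_a
            c01 = (a11 * w01 - a01 * w11) / det_a
            c10 = (-a01 * w00 + a00 * w01) / det_a
            c11 = (-a01 * w01 + a00 * w11) / det_a
            b0 = (a11 * wy0 - a01 * wy1) / det_a
            b1 = (-a01 * wy0 + a00 * wy1) / det_a
            p00 = w00 - (w00 * c00 + w01 * c10)
            p01 = w01 - (w00 * c01 + w01 * c11)
            p11 = w11 - (w01 * c01 + w11 * c11)
            m0 = wy0 - (w00 * b0 + w01 * b1)
            m1 = wy1 - (w01 * b0 + w11 * b1)
        P00 = float(np.sum(p00)) + s0_prec
        P01 = float(np.sum(p01))
        P11 = float(np.sum(p11)) + s0_prec
        M0, M1 = float(np.sum(m0)), float(np.sum(m1))
        detP = P00 * P11 - P01 * P01
        mu_a = (P11 * M0 - P01 * M1) / detP
        mu_b = (-P01 * M0 + P00 * M1) / detP
        l00 = np.sqrt(P00)
        l10 = P01 / l00
        l11 = np.sqrt(P11 - l10 * l10)
        z0, z1 = rng.standard_normal(2)
        db = z1 / l11
        da = (z0 - l10 * db) / l00
        alpha0, beta0 = mu_a + da, mu_b + db

        # (3) joint refresh of the subject effects (a_i, b_i)
        if rho_zero:
            prec = n_i / s2 + 1.0 / (tau * tau)
            mean = ((sum_y - beta0 * sum_t) / s2 + alpha0 / (tau * tau)) / prec
            a = mean + rng.standard_normal(n_subj) / np.sqrt(prec)
            b = np.full(n_subj, beta0)
        else:
            a00 = 1.0 / (tau * tau) + w00
            a01 = w01
            a11 = 1.0 / (rho * rho) + w11
            det_a = a00 * a11 - a01 * a01
            c0 = wy0 + alpha0 / (tau * tau)
            c1 = wy1 + beta0 / (rho * rho)
            mean_a = (a11 * c0 - a01 * c1) / det_a
            mean_b = (-a01 * c0 + a00 * c1) / det_a
            l00 = np.sqrt(a00)
            l10 = a01 / l00
            l11 = np.sqrt(a11 - l10 * l10)
            z0 = rng.standard_normal(n_subj)
            z1 = rng.standard_normal(n_subj)
            db = z1 / l11
            da = (z0 - l10 * db) / l00
            a = mean_a + da
            b = mean_b + db

        # step-size adaptation, warmup only, batches of 50
        if it < spec.n_warmup and (it + 1) % 50 == 0:
            for k in sampled:
                rate = accepts[k] / (50.0 * _SCALE_SCANS)
                steps[k] = float(np.clip(steps[k] * np.exp(rate - 0.44), 1e-3, 5.0))
                accepts[k] = 0

        if it >= spec.n_warmup:
            j = it - spec.n_warmup
            out["alpha0"][j] = alpha0
            out["beta0"][j] = beta0
            out["tau"][j] = tau
            out["sigma"][j] = sigma
            out["rho"][j] = rho
            out["alpha"][j] = a
            out["beta"][j] = b
    return out


def fit_blme(table: pd.DataFrame, spec: BLMESpec) -> BLMEPosterior:
    """Fit the BLME model by Metropolis-within-Gibbs MCMC.

    Requires >= 3 subjects with per-subject baseline-normalized times
    (earliest session at t = 0; see :func:`normalize_time`). If no subject
    has two distinct timepoints the slope SD ``rho`` is unidentifiable and
    the fit is refused unless ``spec.fix_rho`` pins it. Raises
    :class:`ConvergenceError` listing the offending parameters if any
    split-rhat exceeds ``spec.rhat_threshold``.
    """
    subjects, si, y, t = _design(table)
    n_subj = len(subjects)
    if n_subj < 3:
        raise ValueError(f"need at least 3 subjects, got {n_subj}")
    tmin = pd.Series(t).groupby(si).min()
    if (tmin != 0).any():
        raise ValueError("times are not baseline-normalized; call normalize_time first")
    distinct = pd.Series(t).groupby(si).nunique()
    if distinct.max() < 2 and spec.fix_rho is None:
        raise ValueError(
            "all subjects have a single timepoint: slope SD rho is unidentifiable; "
            "pass BLMESpec(fix_rho=...) to pin it"
        )

    if spec.standardize:
        center, scale = float(np.mean(y)), float(np.std(y, ddof=1))
        if scale == 0:
            raise ValueError("zero variance in volumes; cannot standardize")
        y_fit = (y - center) / scale
    else:
        center, scale = 0.0, 1.0
        y_fit = y
    sd_y = float(np.std(y_fit, ddof=1))

    chain_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
    chains = [
        _run_chain(np.random.default_rng(s), y_fit, t, si, n_subj, spec, sd_y)
        for s in chain_seeds
    ]

    draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    draws["r"] = draws["tau"] / draws["sigma"]

    fixed = {
        name for name, v in (("tau", spec.fix_tau), ("rho", spec.fix_rho), ("sigma", spec.fix_sigma))
        if v is not None
    }
    if spec.fix_rho == 0.0:
        fixed.add("beta")  # beta_i degenerate to beta0 when rho is pinned at 0
    diag_vars = [k for k in ("alpha0", "beta0", "tau", "sigma", "rho", "alpha", "beta") if k not in fixed]
    rhat_ds = az.rhat(az.convert_to_dataset({k: draws[k] for k in diag_vars}))
    rhat: dict[str, float] = {}
    for k in diag_vars:
        vals = np.atleast_1d(rhat_ds[k].values)
        if vals.size == 1:
            rhat[k] = float(vals[0])
        else:
            for i, v in enumerate(vals):
                rhat[f"{k}[{i}]"] = float(v)
    bad = sorted(name for name, v in rhat.items() if not np.isfinite(v) or v > spec.rhat_threshold)
    if bad:
        worst = max(rhat[n] for n in bad)
        raise ConvergenceError(
            f"rhat > {spec.rhat_threshold} for parameter(s): {', '.join(bad)} "
            f"(worst {worst:.4f}); increase n_warmup/n_draws or inspect the data"
        )

    def _summ(x):
        lo, hi = np.percentile(x, [2.5, 97.5])
        return float(np.mean(x)), float(lo), float(hi)

    raw_xform = {
        "alpha0": lambda x: x * scale + center,
        "beta0": lambda x: x * scale,
        "tau": lambda x: x * scale,
        "sigma": lambda x: x * scale,
        "rho": lambda x: x * scale,
    }
    summaries = {}
    for name in ("alpha0", "beta0", "tau", "sigma", "rho"):
        flat = draws[name].ravel()
        m, lo, hi = _summ(flat)
        mr, lor, hir = _summ(raw_xform[name](flat))
        summaries[name] = {
            "mean": m, "ci_low": lo, "ci_high": hi,
            "mean_raw": mr, "ci_low_raw": lor, "ci_high_raw": hir,
        }
    r_mean, r_lo, r_hi = _summ(draws["r"].ravel())
    summaries["r"] = {
        "mean": r_mean, "ci_low": r_lo, "ci_high": r_hi,
        "mean_raw": r_mean, "ci_low_raw": r_lo, "ci_high_raw": r_hi,
    }

    return BLMEPosterior(
        draws=draws,
        summaries=summaries,
        r_mean=r_mean,
        r_ci=(r_lo, r_hi),
        rhat=rhat,
        scale_info={"standardize": spec.standardize, "center": center, "scale": scale},
        subjects=subjects,
        n_obs=y.size,
    )


def variance_ratio(post: BLMEPosterior) -> tuple[float, tuple[float, float]]:
    """Posterior mean and central 95% credible interval of r = tau / sigma.

    Computed per draw (the posterior of the derived ratio, not the ratio of
    posterior means); invariant to any linear rescaling of the volumes.
    """
    return post.r_mean, post.r_ci


def compare_blme(post_a: BLMEPosterior, post_b: BLMEPosterior, *, labels=("A", "B")) -> pd.DataFrame:
    """CI-overlap decisions between two fits for r, tau and sigma.

    tau and sigma are compared on the raw volume scale (the comparison is
    equivariant under common rescaling of both datasets); r is scale-free.
    Both posteriors must have been fit with the same standardization setting.
    """
    if post_a.scale_info["standardize"] != post_b.scale_info["standardize"]:
        raise ValueError("scale mismatch: one posterior standardized, the other raw")
    rows = []
    for q in ("r", "tau", "sigma"):
        sa, sb = post_a.summaries[q], post_b.summaries[q]
        sig = ci_overlap_significant(
            sa["mean_raw"], (sa["ci_low_raw"], sa["ci_high_raw"]),
            sb["mean_raw"], (sb["ci_low_raw"], sb["ci_high_raw"]),
        )
        rows.append(
            {
                "quantity": q,
                f"mean_{labels[0]}": sa["mean_raw"],
                f"ci_low_{labels[0]}": sa["ci_low_raw"],
                f"ci_high_{labels[0]}": sa["ci_high_raw"],
                f"mean_{labels[1]}": sb["mean_raw"],
                f"ci_low_{labels[1]}": sb["ci_low_raw"],
                f"ci_high_{labels[1]}": sb["ci_high_raw"],
                "significant": sig,
            }
        )
    return pd.DataFrame(rows)
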