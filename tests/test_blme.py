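"""BLME model: exact log posterior, sampler validation, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from volrely import (
    BLMESpec,
    ConvergenceError,
    SimulationConfig,
    compare_blme,
    fit_blme,
    log_posterior,
    normalize_time,
    simulate_longitudinal,
    variance_ratio,
)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "method", "roi", "session", "time_months", "volume"]
    )


def one_obs_table(volume=2.5, t=3.0):
    return _table([["S1", "m", "roi", "s1", t, volume]])


class TestLogPosterior:
    def test_matches_sum_of_closed_form_density_terms(self):
        # one subject, one observation: likelihood + two effect priors +
        # two location priors + three half-Cauchy terms, via scipy's logpdfs
        spec = BLMESpec(seed=0)
        params = dict(alpha0=1.0, beta0=-0.5, tau=2.0, sigma=0.7, rho=0.3,
                      alpha=np.array([1.4]), beta=np.array([-0.2]))
        tab = one_obs_table(volume=2.5, t=3.0)
        expected = (
            stats.norm.logpdf(2.5, 1.4 + (-0.2) * 3.0, 0.7)
            + stats.norm.logpdf(1.4, 1.0, 2.0)
            + stats.norm.logpdf(-0.2, -0.5, 0.3)
            + stats.norm.logpdf(1.0, 0.0, 10.0)
            + stats.norm.logpdf(-0.5, 0.0, 10.0)
            + stats.halfcauchy.logpdf(0.7, scale=5.0)
            + stats.halfcauchy.logpdf(2.0, scale=5.0)
            + stats.halfcauchy.logpdf(0.3, scale=5.0)
        )
        assert log_posterior(params, tab, spec) == pytest.approx(expected, abs=1e-12)

    def test_duplicate_observation_adds_exactly_one_likelihood_term(self):
        spec = BLMESpec(seed=0)
        params = dict(alpha0=1.0, beta0=-0.5, tau=2.0, sigma=0.7, rho=0.3,
                      alpha=np.array([1.4]), beta=np.array([-0.2]))
        tab1 = one_obs_table()
        tab2 = _table([
            ["S1", "m", "roi", "s1", 3.0, 2.5],
            ["S1", "m", "roi", "s2", 3.0, 2.5],
        ])
        lik_term = stats.norm.logpdf(2.5, 1.4 - 0.2 * 3.0, 0.7)
        assert log_posterior(params, tab2, spec) == pytest.approx(
            log_posterior(params, tab1, spec) + lik_term, abs=1e-12
        )

    def test_nonpositive_scales_give_minus_inf(self):
        spec = BLMESpec(seed=0)
        base = dict(alpha0=0.0, beta0=0.0, tau=1.0, sigma=1.0, rho=1.0,
                    alpha=np.array([0.0]), beta=np.array([0.0]))
        tab = one_obs_table()
        for name in ("tau", "sigma", "rho"):
            params = dict(base)
            params[name] = 0.0
            assert log_posterior(params, tab, spec) == -np.inf

    def test_sigma_to_zero_limit_with_residual(self):
        spec = BLMESpec(seed=0)
        params = dict(alpha0=0.0, beta0=0.0, tau=1.0, sigma=1e-12, rho=1.0,
                      alpha=np.array([0.0]), beta=np.array([0.0]))
        assert log_posterior(params, one_obs_table(volume=2.5, t=0.0), spec) < -1e10


class TestNormalizeTime:
    def test_shifts_to_subject_baseline(self):
        tab = _table([
            ["S1", "m", "roi", "a", 3.0, 10.0],
            ["S1", "m", "roi", "b", 9.0, 11.0],
            ["S1", "m", "roi", "c", 15.0, 12.0],
            ["S2", "m", "roi", "a", 5.0, 10.0],
        ])
        out = normalize_time(tab)
        assert out.loc[out["subject_id"] == "S1", "time_months"].tolist() == [0.0, 6.0, 12.0]
        assert out.loc[out["subject_id"] == "S2", "time_months"].tolist() == [0.0]

    def test_missing_times_rejected(self):
        tab = one_obs_table()
        tab.loc[0, "time_months"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            normalize_time(tab)


@pytest.fixture(scope="module")
def recovery_fit():
    cfg = SimulationConfig(
        n_subjects=40, timepoints_months=(0, 3, 6, 9, 12),
        alpha0=0.0, beta0=-0.02, tau=1.0, rho=0.02, sigma=0.2, seed=0,
    )
    tab = simulate_longitudinal(cfg)
    return fit_blme(tab, BLMESpec(seed=1))


class TestFitBLME:
    def test_parameter_recovery(self, recovery_fit):
        s = recovery_fit.summaries
        assert abs(s["tau"]["mean_raw"] - 1.0) / 1.0 < 0.20
        assert abs(s["sigma"]["mean_raw"] - 0.2) / 0.2 < 0.20
        assert s["tau"]["ci_low_raw"] <= 1.0 <= s["tau"]["ci_high_raw"]
        assert s["sigma"]["ci_low_raw"] <= 0.2 <= s["sigma"]["ci_high_raw"]
        assert max(recovery_fit.rhat.values()) <= 1.01

    def test_variance_ratio_recovery_and_per_draw_definition(self, recovery_fit):
        mean, (lo, hi) = variance_ratio(recovery_fit)
        assert 4.0 <= mean <= 6.0
        assert lo < mean < hi
        assert np.array_equal(
            recovery_fit.draws["r"], recovery_fit.draws["tau"] / recovery_fit.draws["sigma"]
        )
        assert (recovery_fit.draws["tau"] > 0).all()
        assert (recovery_fit.draws["sigma"] > 0).all()
        assert (recovery_fit.draws["rho"] > 0).all()

    def test_doubling_sigma_roughly_halves_r(self):
        spec = BLMESpec(seed=5, n_warmup=600, n_draws=800)
        r_means = []
        for sigma in (0.2, 0.4):
            cfg = SimulationConfig(
                n_subjects=40, timepoints_months=(0, 3, 6, 9, 12),
                alpha0=0.0, beta0=-0.02, tau=1.0, rho=0.02, sigma=sigma, seed=13,
            )
            r_means.append(fit_blme(simulate_longitudinal(cfg), spec).r_mean)
        assert 0.35 <= r_means[1] / r_means[0] <= 0.65

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_subjects=10, timepoints_months=(0, 6), seed=4)
        tab = simulate_longitudinal(cfg)
        spec = BLMESpec(seed=8, n_warmup=150, n_draws=150, rhat_threshold=2.0)
        p1, p2 = fit_blme(tab, spec), fit_blme(tab, spec)
        for k in p1.draws:
            assert np.array_equal(p1.draws[k], p2.draws[k])

    def test_r_invariant_under_power_of_two_rescale(self):
        # x4 rescale leaves standardized volumes bit-identical, so the MCMC
        # path and the scale-free ratio r are exactly reproduced
        cfg = SimulationConfig(n_subjects=15, timepoints_months=(0, 6, 12), seed=6)
        tab = simulate_longitudinal(cfg)
        scaled = tab.assign(volume=tab["volume"] * 4.0)
        spec = BLMESpec(seed=3, n_warmup=300, n_draws=300, rhat_threshold=1.2)
        p1, p2 = fit_blme(tab, spec), fit_blme(scaled, spec)
        assert np.array_equal(p1.draws["r"], p2.draws["r"])
        assert p2.summaries["tau"]["mean_raw"] == pytest.approx(
            4 * p1.summaries["tau"]["mean_raw"]
        )

    def test_conjugate_reduction_matches_closed_form(self):
        # tau, sigma fixed at truth, rho pinned at 0, all t = 0: the alpha0
        # posterior is Gaussian with a closed-form mean
        rng = np.random.default_rng(7)
        n, k, tau, sig, a0 = 12, 3, 2.0, 1.0, 5.0
        ai = rng.normal(a0, tau, n)
        rows = [
            [f"S{i:02d}", "m", "roi", f"s{j}", 0.0, ai[i] + rng.normal(0, sig)]
            for i in range(n)
            for j in range(k)
        ]
        tab = _table(rows)
        spec = BLMESpec(seed=3, standardize=False, fix_tau=tau, fix_sigma=sig,
                        fix_rho=0.0, n_warmup=500, n_draws=2000)
        post = fit_blme(tab, spec)
        ybar = tab.groupby("subject_id")["volume"].mean().to_numpy()
        prec = n / (tau**2 + sig**2 / k) + 1 / spec.prior_loc_sd**2
        closed_form = ybar.sum() / (tau**2 + sig**2 / k) / prec
        mcse = 3 * (1 / np.sqrt(prec)) / np.sqrt(200)  # generous effective n
        assert post.summaries["alpha0"]["mean"] == pytest.approx(closed_form, abs=mcse)

    def test_single_timepoint_design_refused_without_fixed_rho(self):
        tab = _table([[f"S{i}", "m", "roi", "s1", 0.0, 3000.0 + i] for i in range(5)])
        with pytest.raises(ValueError, match="rho"):
            fit_blme(tab, BLMESpec(seed=0))

    def test_unnormalized_time_refused(self):
        tab = _table([
            ["S1", "m", "roi", "a", 3.0, 10.0],
            ["S1", "m", "roi", "b", 9.0, 11.0],
            ["S2", "m", "roi", "a", 3.0, 10.0],
            ["S2", "m", "roi", "b", 9.0, 11.0],
            ["S3", "m", "roi", "a", 3.0, 10.0],
            ["S3", "m", "roi", "b", 9.0, 11.0],
        ])
        with pytest.raises(ValueError, match="normalize"):
            fit_blme(tab, BLMESpec(seed=0))

    def test_nonconvergence_raises_with_offenders(self):
        cfg = SimulationConfig(n_subjects=20, timepoints_months=(0, 3, 6), seed=2)
        tab = simulate_longitudinal(cfg)
        spec = BLMESpec(seed=1, n_warmup=1, n_draws=8)  # far too short to converge
        with pytest.raises(ConvergenceError, match="rhat"):
            fit_blme(tab, spec)


class TestCompareBLME:
    def test_identical_posteriors_not_significant(self, recovery_fit):
        table = compare_blme(recovery_fit, recovery_fit)
        assert not table["significant"].any()
        assert set(table["quantity"]) == {"r", "tau", "sigma"}

    def test_scale_mismatch_rejected(self, recovery_fit):
        other = fit_blme(
            simulate_longitudinal(
                SimulationConfig(n_subjects=10, timepoints_months=(0, 6), seed=4)
            ),
            BLMESpec(seed=8, n_warmup=150, n_draws=150, standardize=False, rhat_threshold=2.0),
        )
        with pytest.raises(ValueError, match="scale mismatch"):
            compare_blme(recovery_fit, other)
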