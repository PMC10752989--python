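"""Longitudinal reliability via the Bayesian linear mixed-effects model.

40 subjects, 5 visits (0-12 months). Volumes follow
V_ij ~ N(alpha_i + beta_i t, sigma^2) with between-subject intercept SD
tau = 1.0 and residual SD sigma = 0.2 (standardized units), so the true
variance ratio is r = tau/sigma = 5. The fit recovers tau, sigma and r with
95% credible intervals and convergence diagnostics.
"""

from volrely import BLMESpec, SimulationConfig, fit_blme, simulate_longitudinal, variance_ratio

cfg = SimulationConfig(
    n_subjects=40, timepoints_months=(0, 3, 6, 9, 12),
    alpha0=0.0, beta0=-0.02, tau=1.0, rho=0.02, sigma=0.2, seed=0,
)
post = fit_blme(simulate_longitudinal(cfg), BLMESpec(seed=1))

s = post.summaries
for name, truth in (("tau", 1.0), ("sigma", 0.2), ("rho", 0.02)):
    p = s[name]
    print(f"{name:>5}: posterior mean {p['mean_raw']:.3f} "
          f"(95% CrI [{p['ci_low_raw']:.3f}, {p['ci_high_raw']:.3f}]), truth {truth}")
r_mean, (r_lo, r_hi) = variance_ratio(post)
print(f"    r: posterior mean {r_mean:.2f} (95% CrI [{r_lo:.2f}, {r_hi:.2f}]), truth 5.0")
print(f"max split-rhat over all parameters: {max(post.rhat.values()):.4f}")
print("\nThe variance ratio r = tau/sigma summarizes longitudinal reliability:")
print("the measurement separates subjects (tau) while repeat measurements of the")
print("same subject stay tight (sigma). Higher r = a more trustworthy biomarker.")
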