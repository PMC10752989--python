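"""Generate the three kinds of synthetic volume tables and save one to CSV.

Each generator emits the canonical long-format table
(subject_id, method, roi, session, time_months, volume) with a known
statistical structure, so every downstream metric has a ground truth.
"""

from volrely import (
    SimulationConfig,
    simulate_accuracy,
    simulate_longitudinal,
    simulate_testretest,
    write_volume_table,
)

# longitudinal trajectories: intercepts ~ N(3000, 300^2) mm^3, slopes
# ~ N(-2, 1) mm^3/month, residual SD 50 mm^3
cfg = SimulationConfig(
    n_subjects=5, timepoints_months=(0, 6, 12), alpha0=3000, beta0=-2,
    tau=300, rho=1.0, sigma=50, seed=7,
)
longitudinal = simulate_longitudinal(cfg)
print("longitudinal table (first subject):")
print(longitudinal.head(3).to_string(index=False))

# paired test/retest volumes: the generative consistency ICC is
# 300^2 / (300^2 + 30^2) = 0.990
testretest = simulate_testretest(45, mu=3000, between_sd=300, within_sd=30, seed=7)
print("\ntest-retest table (first subject):")
print(testretest.head(2).to_string(index=False))

# manual/predicted pairs: VPE has mean 1.5% (bias) and SD 5.2% (noise)
accuracy = simulate_accuracy(45, gt_mean=3000, gt_sd=300, bias_pct=1.5, noise_pct=5.2, seed=7)
print("\naccuracy table (first subject):")
print(accuracy.head(2).to_string(index=False))

write_volume_table(longitudinal, "longitudinal_volumes.csv")
print("\nwrote longitudinal_volumes.csv "
      f"({len(longitudinal)} records = 5 subjects x 3 timepoints)")
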