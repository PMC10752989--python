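"""Test-retest reliability: consistency ICC and volume percentage difference.

45 subjects are scanned twice. The generator's between-subject SD (300 mm^3)
and within-subject SD (30 mm^3) imply a population ICC of
300^2/(300^2 + 30^2) = 0.990 — the estimate and its 95% CI should sit near
that value, in the "excellent" band (> 0.95).
"""

from volrely import PipelineConfig, run_testretest, simulate_testretest

table = simulate_testretest(45, mu=3000, between_sd=300, within_sd=30, seed=5)
report = run_testretest(table, PipelineConfig(seed=0))

pm = report["per_method"]["simulated/hippocampus_L"]
icc = pm["icc"]
print(f"ICC = {icc['estimate']:.3f} (95% CI [{icc['ci_low']:.3f}, {icc['ci_high']:.3f}]) "
      f"- {icc['band']} ({icc['model_label']})")
print(f"VPD median {pm['vpd_median']:.2f}% "
      f"(IQR [{pm['vpd_iqr'][0]:.2f}, {pm['vpd_iqr'][1]:.2f}]%)")
print(f"{pm['vpd_pct_below_2']:.1f}% of subjects differ by less than 2% between sessions")
print("\nThe ICC near 0.990 matches the generative variance components; a VPD")
print("median near 1% means repeat scans agree to about the size of the annual")
print("age-related atrophy signal such measurements are meant to detect.")
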