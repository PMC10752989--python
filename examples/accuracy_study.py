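"""Accuracy study: compare two volume-measurement methods against manual truth.

Method A has a 1.5% systematic bias with 5.2% noise; method B is much worse
(20% bias, 13% noise). The pipeline computes per-method VPE summaries and
Pearson correlations, then runs the full comparison battery: a
normality-gated paired test on |VPE| (location / accuracy), an F-test on the
VPE variances (precision), and Fisher's z-test on the correlations.
"""

import pandas as pd

from volrely import PipelineConfig, run_accuracy, simulate_accuracy

# the same seed reuses the same manual (ground-truth) volumes for both methods
ta = simulate_accuracy(500, 3000, 300, bias_pct=1.5, noise_pct=5.2, seed=77, method="methodA")
tb = simulate_accuracy(500, 3000, 300, bias_pct=20.0, noise_pct=13.0, seed=77, method="methodB")
table = pd.concat([ta, tb[tb["method"] == "methodB"]], ignore_index=True)

report = run_accuracy(table, PipelineConfig(seed=0))

for key, pm in report["per_method"].items():
    v = pm["vpe"]
    print(f"{key}: VPE mean {v['mean']:+.2f}%  sd {v['sd']:.2f}%  "
          f"median {v['median']:+.2f}%  CC {pm['cc']:.3f} ({pm['cc_band']})")

comp = report["comparisons"][0]
print(f"\n{comp['method_a']} vs {comp['method_b']}:")
print(f"  |VPE| location: {comp['location']['test_name']}, "
      f"p = {comp['location']['p_value']:.2e}, significant = {comp['location']['significant']}")
print(f"  VPE variance:   F = {comp['variance']['statistic']:.3f}, "
      f"p = {comp['variance']['p_value']:.2e}, significant = {comp['variance']['significant']}")
print(f"  CC difference:  z = {comp['cc']['statistic']:.2f}, "
      f"p = {comp['cc']['p_value']:.2e}, significant = {comp['cc']['significant']}")
print("\nA mean VPE near +1.5% with sd near 5.2% reproduces the generator; all three")
print("comparisons flag method A as significantly more accurate and precise at p < 0.01.")
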