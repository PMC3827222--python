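"""Power of the SS-T statistic as its truncation threshold varies.

SS-T sums the squared univariate statistics whose square exceeds a threshold
t; t=0 is the plain sum of squares (V-SS).  This sweep shares the simulated
cohorts across thresholds, so differences between columns are paired.
"""
from blocktest import SimSetting, threshold_sweep

setting = SimSetting(m=10, rho=0.8, raf=0.1, causal_raf=0.1, k=1,
                     mode="recessive", r1=1.0, r2=3.14, n=1000,
                     replicates=150, B=500, seed=9)
report = threshold_sweep(setting, t_values=(1, 3, 6, 9))

print("empirical power of SS-t at alpha=0.05 "
      f"({setting.replicates} replicates, recessive causal SNP):")
print(f"{'t':>6s} {'plain':>8s} {'ADR':>8s}")
for t in (0, 1, 3, 6, 9):
    plain = report.rate(f"ss_{t}", False)
    adr = report.rate(f"ss_{t}", True)
    print(f"{t:6d} {plain:8.3f} {adr:8.3f}")

print(
    "\nss_0 is the untruncated sum of squares (the V-SS statistic).\n"
    "With a recessive signal, a high within-block correlation and a small\n"
    "block, truncation tends to help the ADR version: weak statistics that\n"
    "only add noise are excluded from the sum."
)
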