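"""ADR power gain under a recessive mode of inheritance (small-scale).

Runs one calibrated recessive single-causal setting at reduced replicate
count and prints each method's power with and without the ADR extension.
"""
from dataclasses import replace

from blocktest import evaluate_size_power
from blocktest.experiments import RECESSIVE_K1_SETTINGS, adr_power_gain

setting = replace(RECESSIVE_K1_SETTINGS[0], replicates=200)
report = evaluate_size_power(setting)
gain = adr_power_gain(report)

print(f"recessive causal SNP, m={setting.m}, rho={setting.rho}, "
      f"CAF={setting.causal_raf}, R2={setting.r2}, "
      f"{setting.replicates} replicates\n")
print(f"{'method':12s} {'plain':>8s} {'ADR':>8s} {'gain (pts)':>11s}")
for method in gain.index:
    print(f"{method:12s} {report.rate(method, False):8.3f} "
          f"{report.rate(method, True):8.3f} {gain[method]:11.1f}")
print(f"\nmean ADR gain: {gain.mean():.1f} percentage points")
print(
    "\nAn additive-only test dilutes a recessive signal (heterozygotes\n"
    "carry no extra risk); adding the recessive coding recovers it, at the\n"
    "price of a conservative 3m multiple-testing correction."
)
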