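"""Run every block test on one simulated case-control cohort.

Simulates a 10-SNP LD block (exchangeable polychoric correlation 0.8, allele
frequency 0.1) with one recessive causal SNP, samples 1,000 cases and 1,000
controls, and prints the block p-value of each method with and without the
ADR (additive+dominant+recessive) extension.
"""
import numpy as np

from blocktest import SimSetting, analyze_block
from blocktest.harness import simulate_cohort

setting = SimSetting(m=10, rho=0.8, raf=0.1, k=1, mode="recessive",
                     r1=1.0, r2=3.14, n=1000, seed=42)
rng = np.random.default_rng(setting.seed)
block, y, causal_idx = simulate_cohort(setting, rng)

print(f"causal SNP: snp{causal_idx[0]+1} (recessive, R2={setting.r2})")
print(f"{'method':12s} {'plain p':>10s} {'ADR p':>10s}")
results = analyze_block(block, y, B=1000, seed=7)
by_key = {(r.method, r.adr): r.p_value for r in results}
for method in sorted({r.method for r in results}):
    print(f"{method:12s} {by_key[(method, False)]:10.4g} {by_key[(method, True)]:10.4g}")

print(
    "\nEach row is one block-level test of association between the 10-SNP\n"
    "block and the trait.  Under this recessive causal model the ADR\n"
    "column (which also tests dominant and recessive codings, 3m tests)\n"
    "is usually far smaller than the additive-only column."
)
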