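"""Canned simulation-study settings and ADR gain summaries.

The power settings below follow the study design of the latent-normal
(polychoric) simulation experiment: a single causal SNP (or two
non-interacting causal SNPs) inside an exchangeably correlated LD block,
1,000 cases and 1,000 controls, trait prevalence 5%, and effect sizes
calibrated once so that the *average* empirical power over all tested
methods (ADR and non-ADR alike) is close to the 50% target.  Within that
design, ADR gains are largest for a recessive mode of inheritance, high
within-block correlation, small blocks and low causal allele frequency.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .harness import EvaluationReport
from .simulate import SimSetting

__all__ = [
    "NULL_SIZE_SETTING",
    "RECESSIVE_K1_SETTINGS",
    "NONRECESSIVE_K1_SETTINGS",
    "RECESSIVE_K2_SETTINGS",
    "adr_power_gain",
    "mean_adr_gain",
]

#: null (size-of-test) setting: 20 SNPs, exchangeable polychoric correlation
#: 0.64, counted-allele frequency 0.3, 1,000 cases / 1,000 controls.
NULL_SIZE_SETTING = SimSetting(
    m=20, rho=0.64, raf=0.3, k=0, n=1000, replicates=500, B=1000, seed=20540,
)

#: single-causal recessive settings (effect sizes calibrated to the 50%
#: average power target; heterozygote relative risk 1).
RECESSIVE_K1_SETTINGS = (
    SimSetting(m=10, rho=0.80, raf=0.10, causal_raf=0.10, k=1, mode="recessive",
               r1=1.0, r2=3.14, n=1000, B=500, seed=211),
    SimSetting(m=20, rho=0.64, raf=0.10, causal_raf=0.10, k=1, mode="recessive",
               r1=1.0, r2=3.40, n=1000, B=500, seed=212),
    SimSetting(m=10, rho=0.80, raf=0.05, causal_raf=0.05, k=1, mode="recessive",
               r1=1.0, r2=6.91, n=1000, B=500, seed=213),
)

#: single-causal additive and dominant settings (same calibration target;
#: additive uses R2 = 2 R1 - 1, dominant uses R1 = R2).
NONRECESSIVE_K1_SETTINGS = (
    SimSetting(m=10, rho=0.80, raf=0.10, causal_raf=0.10, k=1, mode="additive",
               r1=1.29, r2=1.58, n=1000, B=500, seed=221),
    SimSetting(m=20, rho=0.64, raf=0.10, causal_raf=0.10, k=1, mode="dominant",
               r1=1.34, r2=1.34, n=1000, B=500, seed=222),
)

#: dual non-interacting causal recessive settings (probability-scale effect
#: size per recessive carrier, calibrated to the same target).
RECESSIVE_K2_SETTINGS = (
    SimSetting(m=10, rho=0.80, raf=0.10, causal_raf=0.10, k=2, mode="recessive",
               delta=0.054, n=1000, B=500, seed=231),
    SimSetting(m=20, rho=0.64, raf=0.10, causal_raf=0.10, k=2, mode="recessive",
               delta=0.064, n=1000, B=500, seed=232),
)


def adr_power_gain(report: EvaluationReport) -> pd.Series:
    """Per-method ADR power gain in percentage points (ADR minus non-ADR)."""
    df = report.df
    plain = df[~df.adr].set_index("method").rate
    adr = df[df.adr].set_index("method").rate
    common = plain.index.intersection(adr.index)
    return ((adr[common] - plain[common]) * 100.0).rename("gain_points")


def mean_adr_gain(reports: list[EvaluationReport]) -> pd.Series:
    """Per-method ADR gain averaged over settings, plus the cross-method mean
    under the index ``'mean'``."""
    gains = pd.concat([adr_power_gain(r) for r in reports], axis=1).mean(axis=1)
    gains.loc["mean"] = gains.mean()
    return gains
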