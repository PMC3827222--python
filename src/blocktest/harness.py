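"""Size/power evaluation harness and single-block analysis driver.

Each replicate simulates one case-control cohort and feeds the *same*
univariate statistics and the same Monte-Carlo null draws to every requested
block method, so method comparisons (including ADR vs non-ADR and SS-T
threshold sweeps) are paired.  A master seed spawns one substream per
replicate, making the whole run reproducible and any single replicate
reproducible in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import combine
from .combine import BlockResult
from .genotypes import GenotypeBlock, code_genotypes, filter_by_maf, DEFAULT_MAF_MIN
from .mvnnull import NullModel, null_correlation, simulation_block_p
from .phenotype import (
    PenetranceModel,
    multi_variant_penetrance,
    sample_case_control,
    single_variant_penetrance,
)
from .simulate import SimSetting, draw_genotype_matrix
from .univariate import UnivariateResults, adr_statistics

__all__ = [
    "EvaluationReport",
    "DEFAULT_METHODS",
    "evaluate_size_power",
    "threshold_sweep",
    "analyze_block",
    "block_pvalues",
    "simulate_cohort",
]

#: canonical method labels; ``ss_<t>`` denotes SS-T at threshold t.
DEFAULT_METHODS = (
    "bonferroni", "simes", "gates", "v_ss", "ss_6", "v_minp", "pc", "s_pc",
)

_CALIBRATION_SAMPLE = 50_000


@dataclass
class EvaluationReport:
    """Rejection rates with Wilson 95% confidence intervals per method."""

    df: pd.DataFrame
    metadata: dict

    def rate(self, method: str, adr: bool) -> float:
        row = self.df[(self.df.method == method) & (self.df.adr == adr)]
        if row.empty:
            raise KeyError(f"no entry for method={method!r}, adr={adr}")
        return float(row.rate.iloc[0])


def _parse_method(label: str) -> tuple[str, float | None]:
    if label.startswith("ss_"):
        return "ss_t", float(label[3:])
    return label, None


def block_pvalues(
    univ: UnivariateResults,
    coded,
    methods: Sequence[str],
    adr_flags: Iterable[bool],
    B: int,
    rng: np.random.Generator,
    k_pc: int = combine.DEFAULT_K_PC,
) -> dict[tuple[str, bool], BlockResult]:
    """All requested block-level results for one cohort's statistics.

    Null draws are taken once per correlation structure and shared across the
    simulation-based methods and SS-T thresholds.
    """
    parsed = [_parse_method(lab) for lab in methods]
    needs_mc = any(base in ("ss_t", "v_ss", "v_minp") for base, _ in parsed)
    out: dict[tuple[str, bool], BlockResult] = {}
    for adr in adr_flags:
        z = univ.z_adr if adr else univ.z_add
        p = univ.p_adr if adr else univ.p_add
        corr = null_correlation(coded, adr=adr)
        model = NullModel(corr)
        draws = model.sample(B, rng) if needs_mc else None
        dim = z.size
        for label, (base, t) in zip(methods, parsed):
            if base == "bonferroni":
                res = BlockResult("bonferroni", combine.bonferroni_p(p),
                                  n_tests_used=dim, adr=adr)
            elif base == "simes":
                res = BlockResult("simes", combine.simes_p(p),
                                  n_tests_used=dim, adr=adr)
            elif base == "gates":
                res = BlockResult("gates", combine.gates_p(p, corr),
                                  n_tests_used=dim, adr=adr)
            elif base == "pc":
                q, pv = combine.pc_test(z, corr, k=k_pc, clamp_k=True)
                res = BlockResult("pc", pv, statistic=q, n_tests_used=dim, adr=adr)
            elif base == "s_pc":
                pv = combine.spc_test(p, z, corr, k=k_pc, clamp_k=True)
                res = BlockResult("s_pc", pv, n_tests_used=dim, adr=adr)
            elif base in ("ss_t", "v_ss", "v_minp"):
                res = simulation_block_p(
                    base, univ, model, t=t if t is not None else 0.0,
                    B=B, adr=adr, null_draws=draws,
                )
            else:
                raise ValueError(f"unknown method {label!r}")
            out[(label, adr)] = res
    return out


def _penetrance_for(setting: SimSetting, causal_idx: np.ndarray | None,
                    baseline: float | None) -> PenetranceModel:
    if setting.k == 0 or causal_idx is None:
        return PenetranceModel.null(setting.prevalence)
    causal_raf = setting.causal_raf if setting.causal_raf is not None else (
        float(setting.raf) if np.isscalar(setting.raf) else float(np.asarray(setting.raf)[causal_idx[0]])
    )
    if setting.k == 1:
        f = single_variant_penetrance(setting.r1, setting.r2,
                                      setting.prevalence, causal_raf)
        return PenetranceModel(mode=setting.mode, causal_idx=causal_idx[:1], f=f)
    return PenetranceModel(mode=setting.mode, causal_idx=causal_idx,
                           baseline=baseline, delta=setting.delta)


def _calibrate_baseline(setting: SimSetting, rng: np.random.Generator) -> float | None:
    """One-off baseline calibration for the multi-causal model; the generating
    distribution of the causal genotype counts depends only on (k, rho, CAF)."""
    if setting.k < 2:
        return None
    causal_raf = setting.causal_raf if setting.causal_raf is not None else float(setting.raf)
    sample = draw_genotype_matrix(
        _CALIBRATION_SAMPLE, np.full(setting.k, causal_raf), setting.rho, rng
    )
    return multi_variant_penetrance(
        setting.delta, setting.mode, setting.prevalence, sample
    )


def simulate_cohort(
    setting: SimSetting,
    rng: np.random.Generator,
    baseline: float | None = None,
) -> tuple[GenotypeBlock, np.ndarray, np.ndarray | None]:
    """One case-control cohort under ``setting``.

    Chooses the causal SNP(s) uniformly at random, builds the penetrance
    model, and rejection-samples genotype vectors until the cohort holds
    exactly ``n`` cases and ``n`` controls.  Returns
    ``(block, phenotype, causal_idx)``; ``baseline`` may carry a precomputed
    multi-causal baseline (otherwise it is calibrated on the fly).
    """
    causal_idx = (
        rng.choice(setting.m, size=setting.k, replace=False)
        if setting.k > 0 else None
    )
    if setting.k >= 2 and baseline is None:
        baseline = _calibrate_baseline(setting, rng)
    rafs = setting.raf_vector(causal_idx)
    pen = _penetrance_for(setting, causal_idx, baseline)

    def source(nn: int, rr: np.random.Generator) -> np.ndarray:
        return draw_genotype_matrix(nn, rafs, setting.rho, rr)

    g, y = sample_case_control(source, pen, setting.n, rng)
    block = GenotypeBlock(g, [f"snp{j+1}" for j in range(setting.m)])
    return block, y, causal_idx


def _run_replicates(
    setting: SimSetting,
    methods: Sequence[str],
    adr_flags: Sequence[bool],
) -> pd.DataFrame:
    """p-values per replicate: rows = replicates, columns = (method, adr)."""
    ss = np.random.SeedSequence(setting.seed)
    calib_rng = np.random.default_rng(ss.spawn(1)[0])
    baseline = _calibrate_baseline(setting, calib_rng)
    rep_seeds = ss.spawn(setting.replicates)
    rows = []
    for r in range(setting.replicates):
        rng = np.random.default_rng(rep_seeds[r])
        block, y, _ = simulate_cohort(setting, rng, baseline)
        coded = code_genotypes(block)
        univ = adr_statistics(y, coded)
        res = block_pvalues(univ, coded, methods, adr_flags, setting.B, rng)
        rows.append({key: br.p_value for key, br in res.items()})
    return pd.DataFrame(rows)


def _summarise(pvals: pd.DataFrame, alpha: float, setting: SimSetting) -> EvaluationReport:
    records = []
    for (method, adr) in pvals.columns:
        rejected = int((pvals[(method, adr)] <= alpha).sum())
        n = len(pvals)
        lo, hi = proportion_confint(rejected, n, alpha=0.05, method="wilson")
        records.append({
            "method": method, "adr": adr, "n_reps": n, "n_reject": rejected,
            "rate": rejected / n, "ci_low": float(lo), "ci_high": float(hi),
        })
    df = pd.DataFrame(records).sort_values(["method", "adr"]).reset_index(drop=True)
    meta = {k: (v if np.isscalar(v) else repr(v)) for k, v in asdict(setting).items()}
    meta["alpha"] = alpha
    return EvaluationReport(df=df, metadata=meta)


def evaluate_size_power(
    setting: SimSetting,
    methods: Sequence[str] = DEFAULT_METHODS,
    alpha: float = 0.05,
    adr_flags: Sequence[bool] = (False, True),
) -> EvaluationReport:
    """Empirical size (k=0) or power (k>0) of each method at level ``alpha``.

    All methods within a replicate share the cohort, the univariate
    statistics and the null draws.
    """
    if setting.replicates < 1:
        raise ValueError("need at least one replicate")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    pvals = _run_replicates(setting, methods, adr_flags)
    return _summarise(pvals, alpha, setting)


def threshold_sweep(
    setting: SimSetting,
    t_values: Sequence[float] = tuple(range(1, 10)),
    alpha: float = 0.05,
    adr_flags: Sequence[bool] = (False, True),
) -> EvaluationReport:
    """SS-T power across thresholds, sharing cohorts across ``t`` (paired).

    ``ss_0`` is included as the V-SS reference point.
    """
    methods = ["ss_0"] + [f"ss_{t:g}" for t in t_values]
    pvals = _run_replicates(setting, methods, adr_flags)
    return _summarise(pvals, alpha, setting)


def analyze_block(
    block: GenotypeBlock,
    phenotype: np.ndarray,
    methods: Sequence[str] = DEFAULT_METHODS,
    adr_flags: Sequence[bool] = (False, True),
    B: int = 1000,
    seed: int = 0,
    maf_min: float = DEFAULT_MAF_MIN,
    k_pc: int = combine.DEFAULT_K_PC,
) -> list[BlockResult]:
    """Real-data mode: run the requested block tests on one genotype block."""
    y = np.asarray(phenotype)
    if y.shape[0] != block.n_subjects:
        raise ValueError("phenotype length must match the number of subjects")
    block = filter_by_maf(block, maf_min)
    coded = code_genotypes(block)
    univ = adr_statistics(y, coded)
    rng = np.random.default_rng(seed)
    res = block_pvalues(univ, coded, methods, adr_flags, B, rng, k_pc=k_pc)
    return [res[key] for key in sorted(res, key=lambda k: (k[1], k[0]))]
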