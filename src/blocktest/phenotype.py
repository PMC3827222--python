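"""Case-control phenotype generation under penetrance models.

Single-causal cohorts use genotype relative risks: with risk-allele frequency
``p`` (so ``q = 1 - p``), prevalence ``K`` and relative risks ``R1`` (het) and
``R2`` (hom), the genotype penetrances are

    f0 = K / (q^2 + 2 p q R1 + p^2 R2),   f1 = R1 f0,   f2 = R2 f0.

Multi-causal cohorts use an additive model on the probability scale:
``P(case | g) = clamp(b + delta * sum_j c_mode(g_j), 0, 1)`` over the causal
SNPs, with the baseline ``b`` solved numerically so the population case rate
equals ``K``.  Cohorts of exactly ``n`` cases and ``n`` controls are obtained
by rejection sampling: genotype vectors are drawn fresh from the population
generator, a case/control status is drawn from the penetrance, and subjects
are accepted until both classes are full.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize

__all__ = [
    "InfeasiblePenetranceError",
    "AcceptanceStallError",
    "PenetranceModel",
    "single_variant_penetrance",
    "multi_variant_penetrance",
    "sample_case_control",
    "mode_coding",
]

MAX_DRAWS = 10_000_000


class InfeasiblePenetranceError(ValueError):
    """Raised when no penetrance setting can satisfy the requested prevalence."""


class AcceptanceStallError(RuntimeError):
    """Raised when rejection sampling fails to fill a cohort within MAX_DRAWS."""


def mode_coding(counts: np.ndarray, mode: str) -> np.ndarray:
    """Code genotype counts per mode of inheritance: additive = count,
    dominant = [count >= 1], recessive = [count == 2]."""
    if mode == "additive":
        return counts.astype(np.float64)
    if mode == "dominant":
        return (counts >= 1).astype(np.float64)
    if mode == "recessive":
        return (counts == 2).astype(np.float64)
    raise ValueError(f"unknown mode {mode!r}")


def single_variant_penetrance(
    r1: float, r2: float, prevalence: float, causal_raf: float
) -> tuple[float, float, float]:
    """Genotype penetrances ``(f0, f1, f2)`` for a single causal SNP."""
    if r1 < 0 or r2 < 0:
        raise ValueError("relative risks must be nonnegative")
    if not 0 < prevalence < 1 or not 0 < causal_raf < 1:
        raise ValueError("prevalence and causal_raf must lie in (0, 1)")
    p, q = causal_raf, 1.0 - causal_raf
    f0 = prevalence / (q * q + 2 * p * q * r1 + p * p * r2)
    f1, f2 = r1 * f0, r2 * f0
    if max(f0, f1, f2) > 1.0:
        raise InfeasiblePenetranceError(
            f"penetrances ({f0:.4g}, {f1:.4g}, {f2:.4g}) exceed 1 for "
            f"R1={r1}, R2={r2}, K={prevalence}, p={causal_raf}"
        )
    return f0, f1, f2


def multi_variant_penetrance(
    delta: float,
    mode: str,
    prevalence: float,
    causal_counts_sample: np.ndarray,
    tol: float = 1e-4,
) -> float:
    """Baseline ``b`` of the linear-probability multi-causal model.

    ``causal_counts_sample`` is a large generating sample of genotype counts
    at the causal SNPs (subjects x k); ``b`` is solved by root finding so that
    the mean of ``clamp(b + delta * sum_j c_mode(g_j), 0, 1)`` over the sample
    equals ``prevalence``.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if causal_counts_sample.ndim != 2 or causal_counts_sample.shape[1] < 1:
        raise ValueError("causal_counts_sample must be subjects x k")
    s = mode_coding(np.asarray(causal_counts_sample), mode).sum(axis=1)

    def gap(b: float) -> float:
        return float(np.clip(b + delta * s, 0.0, 1.0).mean() - prevalence)

    lo, hi = -delta * float(s.max() if s.size else 0.0) - 1.0, 1.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise InfeasiblePenetranceError(
            f"no baseline achieves prevalence {prevalence} with delta={delta}"
        )
    b = optimize.brentq(gap, lo, hi, xtol=tol * 1e-2)
    raw = b + delta * s
    if (raw < -1e-9).any() or (raw > 1 + 1e-9).any():
        raise InfeasiblePenetranceError(
            f"delta={delta} forces case probabilities outside [0, 1] at the "
            f"baseline matching prevalence {prevalence}; the linear model "
            "does not hold for this setting"
        )
    return float(b)


@dataclass(frozen=True)
class PenetranceModel:
    """Per-subject case probability as a function of causal genotype counts.

    Exactly one of two parameterisations is active: genotype penetrances
    ``f = (f0, f1, f2)`` for a single causal SNP, or ``(baseline, delta)``
    for the additive multi-causal model.
    """

    mode: str
    causal_idx: np.ndarray
    f: tuple[float, float, float] | None = None
    baseline: float | None = None
    delta: float | None = None

    def case_probability(self, genotypes: np.ndarray) -> np.ndarray:
        """Vector of case probabilities for a subjects x m genotype matrix."""
        counts = np.asarray(genotypes)[:, self.causal_idx]
        if self.f is not None:
            return np.asarray(self.f, dtype=np.float64)[counts[:, 0]]
        s = mode_coding(counts, self.mode).sum(axis=1)
        return np.clip(self.baseline + self.delta * s, 0.0, 1.0)

    @classmethod
    def null(cls, prevalence: float) -> "PenetranceModel":
        """No-effect model: every subject is a case with probability K."""
        return cls(
            mode="additive",
            causal_idx=np.array([0]),
            f=(prevalence, prevalence, prevalence),
        )


def sample_case_control(
    genotype_source: Callable[[int, np.random.Generator], np.ndarray],
    penetrance: PenetranceModel,
    n: int,
    rng: np.random.Generator,
    max_draws: int = MAX_DRAWS,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample a cohort of exactly ``n`` cases then ``n`` controls.

    ``genotype_source(n_draw, rng)`` returns fresh population genotype
    matrices.  Returns ``(genotypes, phenotype)`` with cases first; surplus
    subjects of a filled class are discarded.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_cases = n_controls = 0
    drawn = 0
    case_rate = 0.5  # refined from observed yield after the first batch
    while n_cases < n or n_controls < n:
        need_cases, need_controls = n - n_cases, n - n_controls
        batch = int(np.clip(max(need_cases / max(case_rate, 1e-4) * 1.1,
                                need_controls / max(1 - case_rate, 1e-4) * 1.1),
                            256, 500_000))
        g = genotype_source(batch, rng)
        drawn += batch
        pr = penetrance.case_probability(g)
        y = rng.random(batch) < pr
        case_rate = float(np.clip((y.mean() * batch + 1) / (batch + 2), 1e-4, 1 - 1e-4))
        if n_cases < n:
            take = g[y][: n - n_cases]
            cases.append(take)
            n_cases += take.shape[0]
        if n_controls < n:
            take = g[~y][: n - n_controls]
            controls.append(take)
            n_controls += take.shape[0]
        if drawn > max_draws:
            raise AcceptanceStallError(
                f"drew {drawn} subjects but collected only {n_cases}/{n} cases "
                f"and {n_controls}/{n} controls; penetrance likely degenerate"
            )
    genotypes = np.vstack(cases + controls)
    phenotype = np.concatenate([np.ones(n, dtype=np.int8), np.zeros(n, dtype=np.int8)])
    return genotypes, phenotype
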