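"""Simulation-based block tests: SS-T, V-SS and V-minP.

The observed statistic is computed from the (possibly ADR-stacked) vector of
univariate score statistics; its significance comes from Monte-Carlo draws of
a zero-mean multivariate normal whose correlation matrix reflects the LD
pattern in the block.  For score tests the null correlation of the statistics
equals the sample correlation of the coded genotype columns, so that matrix
is used directly.  Sampling is eigendecomposition-based with negative
eigenvalues clipped to zero, which handles the rank-deficient stacked ADR
matrix without jitter.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .combine import BlockResult
from .genotypes import CodedGenotypes
from .univariate import UnivariateResults

__all__ = [
    "NullModel",
    "null_correlation",
    "draw_null_statistics",
    "ss_threshold_stat",
    "max_chisq_stat",
    "mc_pvalue",
    "simulation_block_p",
]

#: default SS-T threshold: z^2 >= 6 (|z| >= 2.449, two-sided p <= 0.0143).
DEFAULT_SS_THRESHOLD = 6.0

#: default Monte-Carlo draw count for the null distribution.
DEFAULT_B = 1000

SIMULATION_METHODS = ("ss_t", "v_ss", "v_minp")


def null_correlation(coded: CodedGenotypes, adr: bool = False) -> np.ndarray:
    """Null correlation matrix of the block's score statistics.

    Plain mode: Pearson correlation of the additive coding columns (m x m).
    ADR mode: correlation of the stacked ``[additive|dominant|recessive]``
    columns (3m x 3m).  Degenerate (constant) columns get zero off-diagonals
    and a unit diagonal, so they behave as independent standard-normal
    coordinates that the observed statistic (fixed at 0 there) never exceeds.
    """
    X = coded.stacked() if adr else coded.additive
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects to estimate correlations")
    sd = X.std(axis=0)
    ok = sd > 1e-12
    corr = np.eye(X.shape[1])
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class NullModel:
    """A PSD-repaired correlation matrix with a seeded MVN sampler."""

    corr: np.ndarray
    _factor: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.corr, dtype=np.float64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("correlation matrix must be square")
        lam, vec = np.linalg.eigh(c)
        if lam.min() < -1e-6:
            raise ValueError("matrix is far from positive semidefinite")
        lam = np.clip(lam, 0.0, None)
        self._factor = vec * np.sqrt(lam)

    @property
    def dim(self) -> int:
        return self.corr.shape[0]

    def sample(self, B: int, rng: np.random.Generator) -> np.ndarray:
        """``B`` independent zero-mean draws with covariance ``corr``."""
        if B < 1:
            raise ValueError("B must be at least 1")
        return rng.standard_normal((B, self.dim)) @ self._factor.T


def draw_null_statistics(
    model: NullModel, B: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Reproducible ``B x dim`` matrix of null statistic vectors."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return model.sample(B, rng)


def ss_threshold_stat(z_vec: np.ndarray, t: float = DEFAULT_SS_THRESHOLD) -> float:
    """SS-T statistic: sum of squared statistics whose square is >= ``t``.

    ``t = 0`` recovers the plain sum of squares (the V-SS statistic).
    """
    if t < 0:
        raise ValueError("threshold t must be nonnegative")
    z2 = np.asarray(z_vec, dtype=np.float64) ** 2
    return float(np.sum(z2 * (z2 >= t), axis=-1))


def max_chisq_stat(z_vec: np.ndarray) -> float:
    """max_j z_j^2 — the statistic equivalent to the minimum p-value."""
    z = np.asarray(z_vec, dtype=np.float64)
    if z.size == 0:
        raise ValueError("empty statistic vector")
    return float(np.max(z * z, axis=-1))


def mc_pvalue(observed: float, null_stats: np.ndarray) -> float:
    """Add-one Monte-Carlo p-value ``(1 + #{null >= observed}) / (B + 1)``."""
    ns = np.asarray(null_stats, dtype=np.float64).ravel()
    if ns.size == 0:
        raise ValueError("empty null sample")
    return float((1 + np.count_nonzero(ns >= observed)) / (ns.size + 1))


def _null_stat_matrix(null_draws: np.ndarray, method: str, t: float) -> np.ndarray:
    z2 = null_draws**2
    if method == "ss_t":
        return (z2 * (z2 >= t)).sum(axis=1)
    if method == "v_ss":
        return z2.sum(axis=1)
    if method == "v_minp":
        return z2.max(axis=1)
    raise ValueError(f"unknown simulation method {method!r}")


def _observed_stat(z: np.ndarray, method: str, t: float) -> float:
    if method == "ss_t":
        return ss_threshold_stat(z, t)
    if method == "v_ss":
        return ss_threshold_stat(z, 0.0)
    if method == "v_minp":
        return max_chisq_stat(z)
    raise ValueError(f"unknown simulation method {method!r}")


def simulation_block_p(
    method: str,
    results: UnivariateResults,
    model: NullModel,
    t: float = DEFAULT_SS_THRESHOLD,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
    adr: bool = False,
    null_draws: np.ndarray | None = None,
) -> BlockResult:
    """Monte-Carlo block p-value for one simulation method.

    ``null_draws`` may be supplied to share one draw set across methods and
    SS-T thresholds (paired comparisons); otherwise ``B`` fresh draws are
    taken from ``model`` with ``seed``.
    """
    z = results.z_adr if adr else results.z_add
    if model.dim != z.size:
        raise ValueError(
            f"null model dimension {model.dim} does not match statistic vector "
            f"length {z.size}"
        )
    if null_draws is None:
        null_draws = draw_null_statistics(model, B, seed)
    obs = _observed_stat(z, method, t)
    null_stats = _null_stat_matrix(null_draws, method, t)
    p = mc_pvalue(obs, null_stats)
    name = f"ss_{t:g}" if method == "ss_t" else method
    return BlockResult(
        method=name, p_value=p, statistic=obs, n_tests_used=z.size, adr=adr
    )
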