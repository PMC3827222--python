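"""Latent-normal genotype simulator with polychoric LD.

Correlated hard-call genotypes are produced by (i) drawing latent vectors
from an m-variate normal with the requested polychoric correlation structure
and (ii) discretising each coordinate at the probit thresholds implied by the
SNP's counted-allele frequency under Hardy-Weinberg equilibrium.  The latent
correlation (the polychoric correlation, PCC) is the LD measure: it is
directly applicable regardless of the allele frequencies of the SNPs
involved, and the marginal genotype distribution is invariant to it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypes import GenotypeBlock, hwe_genotype_freqs

__all__ = ["SimSetting", "latent_thresholds", "simulate_block_genotypes", "draw_genotype_matrix"]


def latent_thresholds(raf: float) -> tuple[float, float]:
    """Probit cutpoints ``(tau1, tau2)`` discretising a standard-normal latent
    variable into genotypes 0/1/2 with HWE frequencies at counted-allele
    frequency ``raf``: latent < tau1 -> 0, < tau2 -> 1, else 2."""
    f0, f1, _ = hwe_genotype_freqs(raf)
    return float(stats.norm.ppf(f0)), float(stats.norm.ppf(f0 + f1))


def draw_genotype_matrix(
    n_subjects: int,
    rafs: np.ndarray,
    rho: float | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an ``(n_subjects, m)`` hard-call genotype matrix.

    ``rho`` is either a single exchangeable latent correlation in ``[0, 1)``
    or a full ``m x m`` latent correlation matrix.
    """
    rafs = np.atleast_1d(np.asarray(rafs, dtype=np.float64))
    m = rafs.size
    if np.isscalar(rho) or np.ndim(rho) == 0:
        r = float(rho)
        if not 0 <= r < 1:
            raise ValueError("exchangeable rho must lie in [0, 1)")
        shared = rng.standard_normal((n_subjects, 1))
        latent = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.standard_normal((n_subjects, m))
    else:
        c = np.asarray(rho, dtype=np.float64)
        if c.shape != (m, m):
            raise ValueError("latent correlation matrix shape must match rafs")
        lam, vec = np.linalg.eigh(c)
        if lam.min() < -1e-8:
            raise ValueError("latent correlation matrix must be PSD")
        factor = vec * np.sqrt(np.clip(lam, 0, None))
        latent = rng.standard_normal((n_subjects, m)) @ factor.T
    tau = np.array([latent_thresholds(p) for p in rafs])  # (m, 2)
    g = (latent >= tau[:, 0]).astype(np.int8)
    g += latent >= tau[:, 1]
    return g


@dataclass
class SimSetting:
    """One simulation configuration for the size/power experiments.

    Parameters
    ----------
    m : SNP count of the block.
    rho : exchangeable latent polychoric correlation between block SNPs.
    raf : counted-allele frequency shared by non-causal block SNPs
        (or a per-SNP array of length ``m``).
    k : number of causal SNPs (0 = null hypothesis).
    mode : underlying mode of inheritance, ``additive``/``dominant``/``recessive``.
    causal_raf : counted (risk) allele frequency of each causal SNP; defaults
        to ``raf``.
    r1, r2 : heterozygote and homozygote relative risks (single-causal model).
    delta : per-"coded unit" effect size on the probability scale
        (multi-causal model, ``k >= 2``).
    prevalence : population case probability K.
    n : cases (= controls) per cohort.
    replicates : cohorts per setting.
    B : Monte-Carlo null draws for the simulation-based tests.
    seed : master seed for the whole setting.
    """

    m: int = 20
    rho: float = 0.64
    raf: float | np.ndarray = 0.3
    k: int = 0
    mode: str = "additive"
    causal_raf: float | None = None
    r1: float = 1.0
    r2: float = 1.0
    delta: float = 0.0
    prevalence: float = 0.05
    n: int = 1000
    replicates: int = 500
    B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.k < 0 or self.k > self.m:
            raise ValueError("need 0 <= k <= m and m >= 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.mode not in ("additive", "dominant", "recessive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.r1 < 0 or self.r2 < 0 or self.delta < 0:
            raise ValueError("effect parameters must be nonnegative")

    def raf_vector(self, causal_idx: np.ndarray | None = None) -> np.ndarray:
        rafs = np.full(self.m, self.raf, dtype=np.float64) if np.isscalar(self.raf) \
            else np.asarray(self.raf, dtype=np.float64).copy()
        if causal_idx is not None and self.causal_raf is not None:
            rafs[causal_idx] = self.causal_raf
        return rafs


def simulate_block_genotypes(
    setting: SimSetting,
    n_subjects: int,
    seed: int | np.random.Generator,
    causal_idx: np.ndarray | None = None,
) -> GenotypeBlock:
    """Simulate a genotype block under ``setting`` for ``n_subjects``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rafs = setting.raf_vector(causal_idx)
    g = draw_genotype_matrix(n_subjects, rafs, setting.rho, rng)
    return GenotypeBlock(
        genotypes=g,
        snp_ids=[f"snp{j+1}" for j in range(setting.m)],
    )
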