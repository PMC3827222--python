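"""Per-SNP association statistics for each mode of inheritance.

The univariate statistic is the logistic-regression *score* statistic for a
single coded predictor with an intercept: ``z = U / sqrt(V)`` with
``U = sum_i x_i (y_i - ybar)`` and ``V = ybar (1 - ybar) * sum_i (x_i - xbar)^2``.
For the additive coding this is exactly the Cochran-Armitage trend statistic.
The score form is used (rather than Wald or LRT) because it stays finite under
separation and because its null correlation across predictors equals the
predictor correlation, which the multivariate-normal null machinery exploits.

A coded column with zero variance (e.g. a recessive coding with no
counted-allele homozygotes) is *degenerate*: its statistic is set to 0 and its
p-value to 1, and it is retained so the test multiplicities stay exactly
``m`` and ``3m``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypes import CodedGenotypes

__all__ = ["UnivariateResults", "score_test", "score_tests", "adr_statistics"]

_VAR_TOL = 1e-12


@dataclass(frozen=True)
class UnivariateResults:
    """Signed statistics and two-sided p-values per SNP and mode."""

    z_add: np.ndarray
    z_dom: np.ndarray
    z_rec: np.ndarray
    p_add: np.ndarray
    p_dom: np.ndarray
    p_rec: np.ndarray
    defined_add: np.ndarray
    defined_dom: np.ndarray
    defined_rec: np.ndarray

    @property
    def m(self) -> int:
        return self.z_add.shape[0]

    @property
    def z_adr(self) -> np.ndarray:
        """Stacked statistics, length ``3m``: all additive, then dominant, then
        recessive, SNP order preserved within each segment."""
        return np.concatenate([self.z_add, self.z_dom, self.z_rec])

    @property
    def p_adr(self) -> np.ndarray:
        return np.concatenate([self.p_add, self.p_dom, self.p_rec])

    @property
    def defined_adr(self) -> np.ndarray:
        return np.concatenate([self.defined_add, self.defined_dom, self.defined_rec])


def score_tests(phenotype: np.ndarray, coded: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised score tests of a 0/1 phenotype against each column of ``coded``.

    Returns ``(z, p, defined)``; degenerate (constant) columns get
    ``z = 0, p = 1, defined = False``.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    X = np.atleast_2d(np.asarray(coded, dtype=np.float64))
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("phenotype and coded matrix must have matching length")
    n = y.shape[0]
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("phenotype must contain both cases and controls")
    resid = y - ybar
    u = resid @ X
    ssx = (X * X).sum(axis=0) - X.sum(axis=0) ** 2 / n
    v = ybar * (1.0 - ybar) * ssx
    defined = v > _VAR_TOL
    z = np.zeros_like(u)
    np.divide(u, np.sqrt(v, where=defined, out=np.ones_like(v)), out=z, where=defined)
    p = np.ones_like(z)
    p[defined] = 2.0 * stats.norm.sf(np.abs(z[defined]))
    # guard against exact-zero p from extreme statistics
    np.clip(p, np.finfo(float).tiny, 1.0, out=p)
    return z, p, defined


def score_test(phenotype: np.ndarray, coded_column: np.ndarray) -> tuple[float, float]:
    """Score test for a single coded genotype column; returns ``(z, p)``."""
    z, p, _ = score_tests(phenotype, np.asarray(coded_column).reshape(-1, 1))
    return float(z[0]), float(p[0])


def adr_statistics(phenotype: np.ndarray, coded: CodedGenotypes) -> UnivariateResults:
    """Score statistics for all three codings of every SNP in a block."""
    za, pa, da = score_tests(phenotype, coded.additive)
    zd, pd_, dd = score_tests(phenotype, coded.dominant)
    zr, pr, dr = score_tests(phenotype, coded.recessive)
    return UnivariateResults(
        z_add=za, z_dom=zd, z_rec=zr,
        p_add=pa, p_dom=pd_, p_rec=pr,
        defined_add=da, defined_dom=dd, defined_rec=dr,
    )
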