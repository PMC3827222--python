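"""Closed-form LD-block p-value combiners.

Bonferroni and Simes act on the p-value vector alone; GATES additionally uses
an effective number of tests derived from the statistic correlation matrix;
the PC test reduces the block to the first ``k`` principal-component
statistics of the genotype correlation matrix; S-PC is a Simes combination of
the Simes and PC p-values.

ADR variants are the same operations fed the stacked length-``3m`` p-value /
statistic vectors and the ``3m x 3m`` stacked correlation matrix.  The stacked
matrix is rank deficient (additive = dominant + recessive), so PC construction
discards eigenvalues below a tolerance and ``k`` counts only retained
components.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "BlockResult",
    "bonferroni_p",
    "simes_p",
    "effective_tests",
    "gates_p",
    "pvalue_correlation",
    "pc_test",
    "spc_test",
]

#: eigenvalues below this are treated as null directions of a rank-deficient
#: correlation matrix (the stacked ADR matrix always has some).
EIG_TOL = 1e-8

#: number of principal-component statistics used by the PC test.
DEFAULT_K_PC = 3


@dataclass(frozen=True)
class BlockResult:
    """One block-level test outcome."""

    method: str
    p_value: float
    statistic: float | None = None
    n_tests_used: int | None = None
    adr: bool = False


def _check_pvec(pvec: np.ndarray) -> np.ndarray:
    p = np.asarray(pvec, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def bonferroni_p(pvec: np.ndarray) -> float:
    """Block p-value ``min(m * min_j p_j, 1)``."""
    p = _check_pvec(pvec)
    return float(min(p.size * p.min(), 1.0))


def _ordered(pvec: np.ndarray) -> np.ndarray:
    """Ascending p-values with ties broken by SNP index (deterministic)."""
    p = _check_pvec(pvec)
    order = np.lexsort((np.arange(p.size), p))
    return p[order], order


def simes_p(pvec: np.ndarray) -> float:
    """Simes block p-value ``min_j (m * p_(j) / j)``, capped at 1."""
    ps, _ = _ordered(pvec)
    m = ps.size
    ranks = np.arange(1, m + 1)
    return float(min((m * ps / ranks).min(), 1.0))


def _check_corr(corr: np.ndarray) -> np.ndarray:
    c = np.asarray(corr, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    return c


def effective_tests(stat_corr: np.ndarray) -> float:
    """Effective number of tests ``m_eff = m - sum_{lambda_i > 1}(lambda_i - 1)``.

    Derived from the eigenvalues of the statistic correlation matrix; equals
    ``m`` for independent tests and 1 for perfectly correlated ones.
    """
    c = _check_corr(stat_corr)
    lam = np.linalg.eigvalsh(c)
    excess = lam[lam > 1.0] - 1.0
    return float(c.shape[0] - excess.sum())


@lru_cache(maxsize=1)
def _pvalue_corr_grid() -> tuple[np.ndarray, np.ndarray]:
    """Tabulate corr(p_i, p_j) as a function of the statistic correlation r.

    With (Z_i, Z_j) standard bivariate normal at correlation r and
    p = 2 Phi(-|Z|), the p-value correlation (E[p_i p_j] - 1/4) / (1/12) is a
    smooth even function of r, evaluated here by two-dimensional quadrature
    on a fine grid for later interpolation.
    """
    # E[p1 p2] = 8 [I(r) + I(-r)] with I(r) the positive-quadrant integral of
    # Phi(-z1) Phi(-z2) phi2(z1, z2; r), where the integrand is smooth; the
    # quadrant is handled by 48-point Gauss-Legendre on [0, 8]^2.
    x, w = np.polynomial.legendre.leggauss(48)
    t = 4.0 * (x + 1.0)
    wt = 4.0 * w
    f = stats.norm.sf(t)
    r_grid = np.linspace(-1.0, 1.0, 1001)
    r_in = np.clip(r_grid, -0.9999, 0.9999)
    om = 1.0 - r_in**2
    z1 = t[:, None]
    z2 = t[None, :]
    quad = z1**2 + z2**2
    cross = z1 * z2
    expo = -(quad[None, :, :] - 2.0 * r_in[:, None, None] * cross[None, :, :]) / (
        2.0 * om[:, None, None]
    )
    dens = np.exp(expo) / (2.0 * np.pi * np.sqrt(om)[:, None, None])
    i_r = np.einsum("rij,i,j->r", dens, wt * f, wt * f)
    e_pp = 8.0 * (i_r + i_r[::-1])  # r -> -r is a grid reversal
    corr = np.clip((e_pp - 0.25) / (1.0 / 12.0), -1.0, 1.0)
    corr[0] = corr[-1] = 1.0  # |r| = 1 means identical |Z|, hence identical p
    return r_grid, corr


def pvalue_correlation(stat_corr: np.ndarray) -> np.ndarray:
    """Map a statistic correlation matrix to the implied correlation matrix
    of the two-sided p-values (elementwise, unit diagonal preserved)."""
    c = _check_corr(stat_corr)
    r_grid, corr = _pvalue_corr_grid()
    out = np.interp(c.ravel(), r_grid, corr).reshape(c.shape)
    np.fill_diagonal(out, 1.0)
    return out


def gates_p(
    pvec: np.ndarray, stat_corr: np.ndarray, transform: str = "pvalue"
) -> float:
    """GATES block p-value ``min_j (m_eff * p_(j) / m_eff(j))``.

    ``m_eff`` is the effective number of tests of the whole block and
    ``m_eff(j)`` is recomputed on the correlation submatrix of the SNPs
    carrying the ``j`` smallest p-values.  By default the statistic
    correlation matrix is first mapped to the implied p-value correlation
    (``transform="pvalue"``); ``transform="direct"`` uses it as is, which is
    noticeably anti-conservative in correlated blocks.
    """
    if transform == "pvalue":
        c = pvalue_correlation(stat_corr)
    elif transform == "direct":
        c = _check_corr(stat_corr)
    else:
        raise ValueError(f"unknown correlation transform {transform!r}")
    ps, order = _ordered(pvec)
    if ps.size != c.shape[0]:
        raise ValueError("p-value vector and correlation matrix sizes differ")
    m_eff = effective_tests(c)
    best = np.inf
    for j in range(1, ps.size + 1):
        idx = order[:j]
        m_eff_j = effective_tests(c[np.ix_(idx, idx)])
        best = min(best, m_eff * ps[j - 1] / m_eff_j)
    return float(min(best, 1.0))


def pc_test(
    z_vec: np.ndarray,
    geno_corr: np.ndarray,
    k: int = DEFAULT_K_PC,
    clamp_k: bool = False,
) -> tuple[float, float]:
    """Principal-component block test.

    The j-th PC statistic is ``U_j = v_j . z / sqrt(lambda_j)`` with
    ``(lambda_j, v_j)`` the descending eigenpairs of the genotype correlation
    matrix.  ``Q_k = sum_{j<=k} U_j^2`` is chi-square with ``k`` df under the
    null.  Eigenvalues below :data:`EIG_TOL` are discarded (rank-deficient ADR
    matrices); ``k`` counts retained components only.

    Returns ``(Q_k, p)``.
    """
    z = np.asarray(z_vec, dtype=np.float64).ravel()
    c = _check_corr(geno_corr)
    if z.size != c.shape[0]:
        raise ValueError("statistic vector and correlation matrix sizes differ")
    lam, vec = np.linalg.eigh(c)
    lam, vec = lam[::-1], vec[:, ::-1]
    keep = lam > EIG_TOL
    lam, vec = lam[keep], vec[:, keep]
    if clamp_k:
        k = min(k, lam.size)
    if k < 1 or k > lam.size:
        raise ValueError(
            f"k={k} exceeds the {lam.size} retained eigenvalues of the block"
        )
    u = (vec[:, :k].T @ z) / np.sqrt(lam[:k])
    q = float(u @ u)
    return q, float(stats.chi2.sf(q, df=k))


def spc_test(
    pvec: np.ndarray,
    z_vec: np.ndarray,
    geno_corr: np.ndarray,
    k: int = DEFAULT_K_PC,
    clamp_k: bool = False,
) -> float:
    """Simes combination of the Simes p-value and the PC-test p-value."""
    p_simes = simes_p(pvec)
    _, p_pc = pc_test(z_vec, geno_corr, k=k, clamp_k=clamp_k)
    return simes_p(np.array([p_simes, p_pc]))
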