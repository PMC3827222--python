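"""Genotype containers, mode-of-inheritance codings and allele-frequency utilities.

Genotypes are hard calls in {0, 1, 2}, counting copies of the *counted*
(reference/risk) allele per SNP.  A :class:`GenotypeBlock` holds the
subjects-by-SNPs matrix for one LD block; :func:`code_genotypes` derives the
additive, dominant and recessive recodings used by every downstream test.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenotypeBlock",
    "CodedGenotypes",
    "EmptyBlockError",
    "code_genotypes",
    "filter_by_maf",
    "hwe_genotype_freqs",
]

#: default minor-allele-frequency cutoff separating "not-very-rare" variants
#: (0.5%); configurable in every entry point that filters.
DEFAULT_MAF_MIN = 0.005


class EmptyBlockError(ValueError):
    """Raised when a filtering step would leave an LD block with no SNPs."""


@dataclass
class GenotypeBlock:
    """Hard-call genotypes for the SNPs of one LD block.

    Parameters
    ----------
    genotypes
        Integer matrix, shape ``(n_subjects, m)``, entries in ``{0, 1, 2}``
        counting copies of the counted allele.  No missing values: apply the
        ingestion missingness policy (mean imputation, rounded) upstream.
    snp_ids
        Unique identifier per SNP column.
    counted_allele
        Optional per-SNP label of which allele is counted (e.g. the VCF ALT).
    sample_ids, positions, chrom
        Optional metadata carried through I/O round trips.
    """

    genotypes: np.ndarray
    snp_ids: list[str]
    counted_allele: list[str] | None = None
    sample_ids: list[str] | None = None
    positions: np.ndarray | None = None
    chrom: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D subjects x SNPs matrix")
        if g.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length must match the number of columns")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("SNP ids must be unique")
        if g.shape[1] < 1:
            raise EmptyBlockError("a block must contain at least one SNP")
        if not np.issubdtype(g.dtype, np.integer):
            if not np.array_equal(g, np.round(g)):
                raise ValueError("genotypes must be integral hard calls")
            g = g.astype(np.int8)
        if g.size and (g.min() < 0 or g.max() > 2):
            raise ValueError("genotype entries must lie in {0, 1, 2}")
        self.genotypes = g

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def counted_allele_freq(self) -> np.ndarray:
        """Sample frequency of the counted allele per SNP."""
        return self.genotypes.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Sample minor-allele frequency per SNP."""
        f = self.counted_allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, idx: np.ndarray) -> "GenotypeBlock":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            counted_allele=(
                [self.counted_allele[i] for i in idx] if self.counted_allele else None
            ),
            positions=self.positions[idx] if self.positions is not None else None,
            chrom=[self.chrom[i] for i in idx] if self.chrom else None,
        )


@dataclass(frozen=True)
class CodedGenotypes:
    """Additive / dominant / recessive recodings of a genotype block.

    ``additive`` is the allele count itself; ``dominant`` indicates carrying
    at least one counted allele; ``recessive`` indicates the counted-allele
    homozygote.  By construction ``additive = dominant + recessive``.
    """

    additive: np.ndarray
    dominant: np.ndarray
    recessive: np.ndarray

    @property
    def n_snps(self) -> int:
        return self.additive.shape[1]

    def stacked(self) -> np.ndarray:
        """All three codings side by side: ``[additive | dominant | recessive]``."""
        return np.hstack([self.additive, self.dominant, self.recessive])


def code_genotypes(block: GenotypeBlock) -> CodedGenotypes:
    """Derive the additive, dominant and recessive codings of a block."""
    g = block.genotypes
    return CodedGenotypes(
        additive=g.astype(np.float64),
        dominant=(g >= 1).astype(np.float64),
        recessive=(g == 2).astype(np.float64),
    )


def filter_by_maf(block: GenotypeBlock, maf_min: float = DEFAULT_MAF_MIN) -> GenotypeBlock:
    """Drop SNPs with sample MAF below ``maf_min``; monomorphic SNPs always go.

    SNP order is preserved.  Raises :class:`EmptyBlockError` if nothing
    survives rather than returning a silently empty block.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    maf = block.maf()
    keep = np.flatnonzero((maf >= maf_min) & (maf > 0))
    if keep.size == 0:
        raise EmptyBlockError(
            f"all {block.n_snps} SNPs removed by the MAF >= {maf_min} filter"
        )
    if keep.size == block.n_snps:
        return block
    return block.subset_snps(keep)


def hwe_genotype_freqs(raf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies ``(f0, f1, f2)`` for counted-allele
    frequency ``raf``."""
    if not 0 < raf < 1:
        raise ValueError("raf must lie strictly inside (0, 1)")
    q = 1.0 - raf
    return (q * q, 2.0 * raf * q, raf * raf)
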