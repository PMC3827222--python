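"""File I/O: genotype matrices (VCF or plain TSV), phenotype tables,
block-definition tables and result/report serialisation.

The plain genotype format is a TSV whose first column is the sample id and
whose remaining columns are SNP ids, entries 0/1/2 counting copies of the
counted allele.  VCF ingestion takes hard calls from GT; the counted allele
defaults to ALT ("dosage of ALT") and can be flipped to REF.  Missing hard
calls are mean-imputed per SNP and rounded to the nearest hard call;
multi-allelic sites are dropped.
"""
from __future__ import annotations

import logging
import sys

import numpy as np
import pandas as pd

from .combine import BlockResult
from .genotypes import GenotypeBlock
from .harness import EvaluationReport

__all__ = [
    "read_genotypes",
    "read_phenotype",
    "read_blocks_table",
    "write_genotypes_tsv",
    "write_block_results",
    "write_report",
    "setup_logging",
]

log = logging.getLogger("blocktest")


def setup_logging(level: str = "INFO") -> None:
    """Timestamped logging to standard error."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def _impute_column(col: np.ndarray) -> np.ndarray:
    """Mean-impute missing entries (coded -1), rounded to the nearest hard call."""
    missing = col < 0
    if missing.any():
        observed = col[~missing]
        fill = int(np.clip(np.rint(observed.mean() if observed.size else 0), 0, 2))
        col = col.copy()
        col[missing] = fill
    return col


def read_genotypes(path: str, fmt: str = "tsv", counted: str = "alt") -> GenotypeBlock:
    """Read a genotype block from ``path`` in ``tsv`` or ``vcf`` format."""
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "vcf":
        return _read_vcf(path, counted=counted)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_tsv(path: str) -> GenotypeBlock:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("genotype TSV needs a sample-id column plus >= 1 SNP")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    g = df.iloc[:, 1:].to_numpy()
    try:
        g = g.astype(np.int8)
    except ValueError as exc:
        raise ValueError(f"malformed genotype entries in {path}") from exc
    return GenotypeBlock(
        genotypes=g, snp_ids=list(df.columns[1:]), sample_ids=sample_ids
    )


def _read_vcf(path: str, counted: str = "alt") -> GenotypeBlock:
    from cyvcf2 import VCF

    if counted not in ("alt", "ref"):
        raise ValueError("counted must be 'alt' or 'ref'")
    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    cols, ids, alleles, positions, chroms = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning("dropping multi-allelic site %s:%s", var.CHROM, var.POS)
            continue
        for gt in var.genotypes:
            if len(gt) != 3:  # [allele_a, allele_b, phased_flag] for diploids
                raise ValueError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS}"
                )
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        dose = var.gt_types.astype(np.int16)
        dose[dose == 3] = -1
        if (dose < 0).any():
            log.info("imputing %d missing calls at %s:%s",
                     int((dose < 0).sum()), var.CHROM, var.POS)
        dose = _impute_column(dose)
        if counted == "ref":
            dose = 2 - dose
        cols.append(dose.astype(np.int8))
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        alleles.append(var.ALT[0] if counted == "alt" else var.REF)
        positions.append(var.POS)
        chroms.append(var.CHROM)
    if not cols:
        raise ValueError(f"no usable biallelic records in {path}")
    return GenotypeBlock(
        genotypes=np.column_stack(cols),
        snp_ids=ids,
        counted_allele=alleles,
        sample_ids=sample_ids,
        positions=np.asarray(positions),
        chrom=chroms,
    )


def read_phenotype(path: str, block: GenotypeBlock | None = None) -> np.ndarray:
    """Read a two-column TSV ``sample_id<TAB>status`` (1 = case).

    If ``block`` carries sample ids, the phenotype is matched and reordered
    by id; a mismatch is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] != 2:
        raise ValueError("phenotype file must have exactly two columns")
    status = df.iloc[:, 1].to_numpy()
    if not np.isin(status, [0, 1]).all():
        raise ValueError("phenotype status must be 0 (control) or 1 (case)")
    if block is not None and block.sample_ids is not None:
        lookup = dict(zip(df.iloc[:, 0], status))
        missing = [s for s in block.sample_ids if s not in lookup]
        if missing:
            raise ValueError(f"samples missing from phenotype file: {missing[:5]}")
        return np.array([lookup[s] for s in block.sample_ids], dtype=np.int8)
    return status.astype(np.int8)


def read_blocks_table(path: str) -> dict[str, list[str]]:
    """Read a block-definition TSV ``snp_id<TAB>block_id`` into block -> SNPs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("block table must have exactly two columns")
    out: dict[str, list[str]] = {}
    for snp, blk in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(blk, []).append(snp)
    return out


def write_genotypes_tsv(block: GenotypeBlock, path: str) -> None:
    """Write the plain genotype TSV (first column sample id)."""
    samples = block.sample_ids or [f"s{i+1}" for i in range(block.n_subjects)]
    df = pd.DataFrame(block.genotypes, columns=block.snp_ids)
    df.insert(0, "sample_id", samples)
    df.to_csv(path, sep="\t", index=False)


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.6g}"


def write_block_results(results: list[BlockResult], path: str,
                        block_id: str = "block1") -> None:
    """Serialise block results as TSV with deterministic row/column order."""
    if not results:
        raise ValueError("no results to write")
    rows = [
        {
            "block_id": block_id,
            "method": r.method,
            "adr": int(r.adr),
            "statistic": _fmt(r.statistic),
            "p": _fmt(r.p_value),
        }
        for r in results
    ]
    df = pd.DataFrame(rows).sort_values(["block_id", "method", "adr"])
    df.to_csv(path, sep="\t", index=False)


def write_report(report: EvaluationReport, path: str) -> None:
    """Serialise an evaluation report (rates + Wilson CIs) as TSV."""
    if report.df.empty:
        raise ValueError("no report rows to write")
    df = report.df.copy().sort_values(["method", "adr"])
    for col in ("rate", "ci_low", "ci_high"):
        df[col] = df[col].map(lambda v: float(f"{v:.6g}"))
    df.to_csv(path, sep="\t", index=False)
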