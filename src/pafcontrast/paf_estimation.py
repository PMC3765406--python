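"""Per-SNP population allele frequency (PAF) estimation with Wald intervals.

The PAF of a SNP is the proportion of its counted allele among all called
alleles in the cohort. The 95% interval is the Wald normal approximation

    paf +/- z * sqrt(paf * (1 - paf) / n_alleles),   z = 1.96 by default,

clipped to [0, 1]. The normal approximation degenerates at monomorphic SNPs
(it collapses to a zero-width interval), so boundary estimates get a fixed
1% margin: paf = 0 -> CI (0, 0.01); paf = 1 -> CI (0.99, 1). The margin
applies only at exactly 0 and 1.

All frequencies are proportions in [0, 1] internally; percent appears only
at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING_CODE, GenotypeTable

BOUNDARY_MARGIN = 0.01  #: CI half-width assigned at monomorphic estimates


@dataclass(frozen=True)
class FreqEstimate:
    """PAF of one SNP with its confidence interval.

    ``n_alleles`` is twice the number of called samples (diploid cohort).
    """

    snp_id: str
    counted_allele: str
    paf: float
    n_alleles: int
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.paf <= self.ci_high <= 1.0):
            raise ValueError(
                f"{self.snp_id}: bounds must satisfy 0 <= ci_low <= paf <= ci_high <= 1"
            )
        if self.n_alleles < 2 or self.n_alleles % 2:
            raise ValueError(f"{self.snp_id}: n_alleles must be even and >= 2")

    def mirrored(self) -> "FreqEstimate":
        """The estimate for the other allele of the pair."""
        return FreqEstimate(
            self.snp_id,
            self.counted_allele,
            1.0 - self.paf,
            self.n_alleles,
            1.0 - self.ci_high,
            1.0 - self.ci_low,
        )


def count_alleles(column: np.ndarray) -> tuple:
    """Counted-allele copies and total called alleles for one genotype column.

    Codes are 0/1/2 copies of the counted allele, or missing. Raises
    ``ValueError`` when no sample is called.
    """
    column = np.asarray(column)
    called = column != MISSING_CODE
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("no called genotypes for SNP")
    return int(column[called].sum()), 2 * n_called


def wald_bounds(paf: np.ndarray, n_alleles: np.ndarray, z_quantile: float = 1.96):
    """Vectorized Wald bounds with clipping and the boundary-margin override."""
    paf = np.asarray(paf, dtype=float)
    n_alleles = np.asarray(n_alleles, dtype=float)
    half = z_quantile * np.sqrt(paf * (1.0 - paf) / n_alleles)
    low = np.clip(paf - half, 0.0, 1.0)
    high = np.clip(paf + half, 0.0, 1.0)
    low = np.where(paf == 1.0, 1.0 - BOUNDARY_MARGIN, low)
    high = np.where(paf == 0.0, BOUNDARY_MARGIN, high)
    return low, high


def estimate_paf(
    snp_id: str,
    counted_allele: str,
    count: int,
    n_alleles: int,
    z_quantile: float = 1.96,
) -> FreqEstimate:
    """Wald estimate from a counted-allele count and an allele total."""
    if n_alleles < 2:
        raise ValueError(f"{snp_id}: need at least 2 alleles, got {n_alleles}")
    if not 0 <= count <= n_alleles:
        raise ValueError(f"{snp_id}: count {count} outside [0, {n_alleles}]")
    paf = count / n_alleles
    low, high = wald_bounds(paf, n_alleles, z_quantile)
    return FreqEstimate(snp_id, counted_allele, paf, int(n_alleles), float(low), float(high))


def estimate_cohort(
    genotypes: GenotypeTable,
    counted_alleles: dict | None = None,
    z_quantile: float = 1.96,
) -> dict:
    """FreqEstimate per SNP over a genotype table (vectorized).

    ``counted_alleles`` maps snp_id -> counted allele letter for labelling;
    SNPs with zero called samples raise.
    """
    called = genotypes.codes != MISSING_CODE
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        snp = genotypes.snp_ids[int(np.argmax(n_called == 0))]
        raise ValueError(f"{snp}: no called genotypes")
    counts = np.where(called, genotypes.codes, 0).sum(axis=0)
    n_alleles = 2 * n_called
    paf = counts / n_alleles
    low, high = wald_bounds(paf, n_alleles, z_quantile)
    out = {}
    for j, snp_id in enumerate(genotypes.snp_ids):
        allele = counted_alleles.get(snp_id, "?") if counted_alleles else "?"
        out[snp_id] = FreqEstimate(
            snp_id, allele, float(paf[j]), int(n_alleles[j]), float(low[j]), float(high[j])
        )
    return out


def estimates_from_reference(frame: pd.DataFrame, z_quantile: float = 1.96) -> dict:
    """FreqEstimate per SNP from a reference-frequency table.

    Reference tables report the PAF and the number of alleles sampled; the
    interval is reconstructed with the same Wald formula used for the study
    cohort.
    """
    paf = frame["paf"].to_numpy(dtype=float)
    n_alleles = frame["n_alleles"].to_numpy(dtype=int)
    low, high = wald_bounds(paf, n_alleles, z_quantile)
    return {
        row.snp_id: FreqEstimate(
            row.snp_id, row.counted_allele, float(paf[j]), int(n_alleles[j]), float(low[j]), float(high[j])
        )
        for j, row in enumerate(frame.itertuples(index=False))
    }


def estimates_to_frame(estimates: dict) -> pd.DataFrame:
    rows = [
        (e.snp_id, e.counted_allele, e.paf, e.n_alleles, e.ci_low, e.ci_high)
        for e in estimates.values()
    ]
    return pd.DataFrame(rows, columns=["snp_id", "allele", "paf", "n_alleles", "ci_low", "ci_high"])
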