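"""SNP- and sample-level quality control.

Four filters, applied in a fixed order: sample call rate, strand-ambiguity
elimination, SNP call rate, minor allele frequency, and an exact
Hardy-Weinberg equilibrium test. Strand-ambiguous SNPs are A/T and C/G
pairs: both alleles are their own reverse complements, so strand
orientation cannot be resolved from the alleles alone and cross-cohort
frequency comparisons at such loci are unreliable.

The HWE test is the exact conditional test: given the allele counts, the
heterozygote count follows a known discrete distribution under random
mating, and the two-sided p-value sums the probabilities of all heterozygote
configurations no more probable than the observed one (ties included).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from math import comb

import numpy as np

from .genio import MISSING_CODE, GenotypeTable, SnpRecord

AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the QC filters; all proportions in [0, 1]."""

    snp_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.95
    maf_min: float = 0.1
    hwe_p_min: float = 1e-6
    drop_strand_ambiguous: bool = True
    #: the sample call-rate stage reports low-call samples; dropping them is
    #: opt-in, the default keeps every sample
    drop_low_call_samples: bool = False

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "sample_call_rate_min", "maf_min", "hwe_p_min"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")


@dataclass
class QcReport:
    """Per-stage removal tallies plus the surviving SNP ids."""

    n_snps_in: int = 0
    n_samples_in: int = 0
    samples_low_call: int = 0
    samples_removed: int = 0
    snps_strand_ambiguous: int = 0
    snps_low_call: int = 0
    snps_low_maf: int = 0
    snps_hwe_fail: int = 0
    surviving_snps: list = field(default_factory=list)
    surviving_samples: list = field(default_factory=list)

    @property
    def n_snps_removed(self) -> int:
        return self.snps_strand_ambiguous + self.snps_low_call + self.snps_low_maf + self.snps_hwe_fail

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def is_strand_ambiguous(record: SnpRecord) -> bool:
    """True iff the allele pair is {A,T} or {C,G}."""
    return record.alleles in AMBIGUOUS_PAIRS


def hwe_exact_test(n_hom_counted: int, n_het: int, n_hom_other: int) -> float:
    """Exact conditional two-sided Hardy-Weinberg p-value from genotype counts.

    Conditions on the observed allele counts; the p-value is the total
    probability of heterozygote counts whose conditional probability does not
    exceed that of the observed count. Returns a value in (0, 1].
    """
    if min(n_hom_counted, n_het, n_hom_other) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_counted + n_het + n_hom_other
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom_counted + n_het  # counted-allele copies
    rare = min(n_a, 2 * n - n_a)
    # exact integer weights: w(het) proportional to P(het | allele counts);
    # integer arithmetic makes the tie comparison (<=) unambiguous
    weights = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_a = (n_a - het) // 2
        weights[het] = comb(n, hom_a) * comb(n - hom_a, het) * 2**het
    total = sum(weights.values())
    observed = weights[n_het]
    selected = sum(w for w in weights.values() if w <= observed)
    return float(Fraction(selected, total))


def _column_genotype_counts(codes: np.ndarray):
    called = codes != MISSING_CODE
    n_hom_counted = ((codes == 2) & called).sum(axis=0)
    n_het = ((codes == 1) & called).sum(axis=0)
    n_hom_other = ((codes == 0) & called).sum(axis=0)
    return n_hom_counted, n_het, n_hom_other


def apply_qc(
    genotypes: GenotypeTable,
    snp_table: list,
    config: QcConfig | None = None,
) -> tuple:
    """Run the QC stages in order and tally removals per stage.

    Stage order: sample call rate, strand ambiguity, SNP call rate, MAF
    (computed on called alleles only), exact HWE. The report accounts for
    every input SNP exactly once.
    """
    config = config or QcConfig()
    by_id = {r.snp_id: r for r in snp_table}
    missing = [s for s in genotypes.snp_ids if s not in by_id]
    if missing:
        raise ValueError(f"SNP ids absent from snp table: {missing[:5]}")

    report = QcReport(n_snps_in=genotypes.n_snps, n_samples_in=genotypes.n_samples)

    # -- sample call rate
    called = genotypes.codes != MISSING_CODE
    sample_rate = called.mean(axis=1)
    low = sample_rate < config.sample_call_rate_min
    report.samples_low_call = int(low.sum())
    if config.drop_low_call_samples and low.any():
        keep = [s for s, is_low in zip(genotypes.sample_ids, low) if not is_low]
        genotypes = genotypes.subset_samples(keep)
        report.samples_removed = report.samples_low_call
    report.surviving_samples = list(genotypes.sample_ids)

    snp_ids = np.array(genotypes.snp_ids)
    codes = genotypes.codes
    keep_mask = np.ones(len(snp_ids), dtype=bool)

    # -- strand ambiguity
    if config.drop_strand_ambiguous:
        ambiguous = np.array([is_strand_ambiguous(by_id[s]) for s in snp_ids])
        report.snps_strand_ambiguous = int((keep_mask & ambiguous).sum())
        keep_mask &= ~ambiguous

    # -- SNP call rate
    call_rate = (codes != MISSING_CODE).mean(axis=0)
    low_call = call_rate < config.snp_call_rate_min
    report.snps_low_call = int((keep_mask & low_call).sum())
    keep_mask &= ~low_call

    # -- MAF on called alleles
    called = codes != MISSING_CODE
    n_alleles = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        paf = np.where(called, codes, 0).sum(axis=0) / np.where(n_alleles > 0, n_alleles, 1)
    maf = np.minimum(paf, 1.0 - paf)
    low_maf = maf < config.maf_min
    report.snps_low_maf = int((keep_mask & low_maf).sum())
    keep_mask &= ~low_maf

    # -- exact HWE
    if config.hwe_p_min > 0.0:
        n2, n1, n0 = _column_genotype_counts(codes)
        hwe_fail = np.zeros(len(snp_ids), dtype=bool)
        for j in np.flatnonzero(keep_mask):
            p = hwe_exact_test(int(n2[j]), int(n1[j]), int(n0[j]))
            hwe_fail[j] = p < config.hwe_p_min
        report.snps_hwe_fail = int((keep_mask & hwe_fail).sum())
        keep_mask &= ~hwe_fail

    survivors = [s for s, k in zip(snp_ids, keep_mask) if k]
    report.surviving_snps = survivors
    return genotypes.subset_snps(survivors), report
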