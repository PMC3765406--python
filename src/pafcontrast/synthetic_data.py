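"""Two-population SNP-array simulator with known ground truth.

Emulates the statistical structure of a candidate-gene array study: a study
cohort genotyped directly (diploid calls under Hardy-Weinberg proportions,
with missingness) and a reference cohort published only as an
allele-frequency table. A configurable fraction of SNPs is truly diverged
between the populations; strand-ambiguous A/T and C/G loci and
opposite-strand reference encodings are planted so the harmonization and QC
stages have real work to do; genes and functional groups are assigned
randomly, with optional groups enriched for diverged SNPs.

Every random draw flows from one seeded generator, so a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genio import (
    COMPLEMENT,
    MISSING_CODE,
    GenotypeTable,
    GroupMapping,
    SnpRecord,
)

NON_AMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
AMBIGUOUS_PAIR_CHOICES = [("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class FreqSpectrum:
    """Shared true-frequency spectrum: Beta body plus point masses at 0 and 1.

    The Beta(0.8, 0.8) default gives the U-shaped spectrum typical of array
    content; the point masses produce monomorphic loci.
    """

    beta_a: float = 0.8
    beta_b: float = 0.8
    mass_at_0: float = 0.05
    mass_at_1: float = 0.05

    def __post_init__(self) -> None:
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("freq_spectrum: beta parameters must be positive")
        if not 0 <= self.mass_at_0 <= 1 or not 0 <= self.mass_at_1 <= 1:
            raise ValueError("freq_spectrum: point masses must be in [0,1]")
        if self.mass_at_0 + self.mass_at_1 > 1:
            raise ValueError("freq_spectrum: point masses exceed 1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the motivating study design: 216 diploid study samples
    (432 alleles when fully called), a reference cohort of 224 alleles
    published as a frequency table, 13.1% strand-ambiguous loci, 53
    functional groups over 705 genes.
    """

    n_snps: int = 34240
    n_samples_study: int = 216
    n_alleles_reference: int = 224
    freq_spectrum: FreqSpectrum = field(default_factory=FreqSpectrum)
    prop_diverged: float = 0.4
    divergence_magnitude: tuple = (0.05, 0.30)
    missing_rate: float = 0.02
    prop_at_cg: float = 0.131
    prop_opposite_strand: float = 0.2
    n_genes: int = 705
    n_groups: int = 53
    enriched_groups: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_snps", "n_samples_study", "n_genes", "n_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_alleles_reference < 2 or self.n_alleles_reference % 2:
            raise ValueError("n_alleles_reference must be even and >= 2")
        for name in ("prop_diverged", "missing_rate", "prop_at_cg", "prop_opposite_strand"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        lo, hi = self.divergence_magnitude
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("divergence_magnitude must satisfy 0 < low <= high <= 1")
        if self.n_genes < self.n_groups:
            raise ValueError("n_genes must be >= n_groups so every group has a gene")
        for group, multiplier in self.enriched_groups:
            if multiplier < 0:
                raise ValueError(f"enriched group {group!r}: multiplier must be >= 0")


def _draw_shared_frequencies(rng: np.random.Generator, n: int, spectrum: FreqSpectrum):
    u = rng.random(n)
    body = rng.beta(spectrum.beta_a, spectrum.beta_b, size=n)
    p = np.where(u < spectrum.mass_at_0, 0.0, body)
    p = np.where(
        (u >= spectrum.mass_at_0) & (u < spectrum.mass_at_0 + spectrum.mass_at_1), 1.0, p
    )
    return p


def _assign_groups(rng: np.random.Generator, config: SimConfig, snp_ids):
    """Every SNP belongs to exactly one gene; every gene to exactly one group.

    The first n_groups genes (in a random permutation) seed the groups so no
    group is empty.
    """
    genes = [f"gene{g + 1:05d}" for g in range(config.n_genes)]
    groups = [f"group{k + 1:02d}" for k in range(config.n_groups)]
    permuted = rng.permutation(config.n_genes)
    gene_group = np.empty(config.n_genes, dtype=int)
    gene_group[permuted[: config.n_groups]] = np.arange(config.n_groups)
    if config.n_genes > config.n_groups:
        gene_group[permuted[config.n_groups :]] = rng.integers(
            0, config.n_groups, config.n_genes - config.n_groups
        )
    snp_gene = rng.integers(0, config.n_genes, len(snp_ids))
    group_to_genes = {g: [] for g in groups}
    for gi, gene in enumerate(genes):
        group_to_genes[groups[gene_group[gi]]].append(gene)
    gene_to_snps = {gene: [] for gene in genes}
    for snp, gi in zip(snp_ids, snp_gene):
        gene_to_snps[genes[gi]].append(snp)
    mapping = GroupMapping(group_to_genes, gene_to_snps)
    snp_group = np.array([gene_group[gi] for gi in snp_gene])
    return mapping, snp_gene, snp_group, genes, groups


def generate_dataset(config: SimConfig):
    """Simulate one study: genotypes, reference frequencies, SNP table, groups, truth.

    Returns ``(genotypes, reference_frame, snp_records, mapping, truth)``
    where ``truth`` is a DataFrame holding each SNP's true frequency in both
    populations (for the study record's counted allele), its diverged flag,
    and its gene/group assignment.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    snp_ids = [f"rs{i + 1:07d}" for i in range(n)]

    shared = _draw_shared_frequencies(rng, n, config.freq_spectrum)
    mapping, snp_gene, snp_group, genes, groups = _assign_groups(rng, config, snp_ids)

    # per-SNP divergence probability, boosted inside enriched groups
    prob = np.full(n, config.prop_diverged)
    multipliers = {g: m for g, m in config.enriched_groups}
    for k, group in enumerate(groups):
        if group in multipliers:
            prob[snp_group == k] = np.clip(config.prop_diverged * multipliers[group], 0.0, 1.0)
    diverged = rng.random(n) < prob

    lo, hi = config.divergence_magnitude
    magnitude = rng.uniform(lo, hi, size=n)
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    study_freq = shared.copy()
    shifted = np.clip(shared + direction * magnitude, 0.0, 1.0)
    stuck = diverged & (shifted == shared)  # shift truncated away at a boundary
    shifted = np.where(stuck, np.clip(shared - direction * magnitude, 0.0, 1.0), shifted)
    study_freq[diverged] = shifted[diverged]
    reference_freq = shared

    # SNP identities
    ambiguous = rng.random(n) < config.prop_at_cg
    pair_choice = rng.integers(0, 4, n)
    ambiguous_choice = rng.integers(0, 2, n)
    count_second = rng.random(n) < 0.5
    chromosome = rng.integers(1, 23, n)
    position = rng.integers(1, 100_000_000, n)
    records = []
    for j in range(n):
        a, b = (
            AMBIGUOUS_PAIR_CHOICES[ambiguous_choice[j]]
            if ambiguous[j]
            else NON_AMBIGUOUS_PAIRS[pair_choice[j]]
        )
        counted = b if count_second[j] else a
        records.append(
            SnpRecord(snp_ids[j], str(chromosome[j]), int(position[j]), a, b, "+", counted)
        )

    # study genotypes: HWE binomial draws of counted-allele copies
    codes = rng.binomial(2, study_freq, size=(config.n_samples_study, n)).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        codes[miss] = MISSING_CODE
    genotypes = GenotypeTable(
        [f"sample{i + 1:04d}" for i in range(config.n_samples_study)], list(snp_ids), codes
    )

    # reference cohort, as a frequency table with its own allele encoding
    ref_swap = rng.random(n) < 0.5
    ref_complement = rng.random(n) < config.prop_opposite_strand
    ref_counted_freq = np.where(ref_swap, 1.0 - reference_freq, reference_freq)
    ref_counts = rng.binomial(config.n_alleles_reference, ref_counted_freq)
    ref_rows = []
    for j, rec in enumerate(records):
        ref_rec = rec if not ref_swap[j] else replace(rec, counted_allele=rec.other_allele)
        if ref_complement[j]:
            ref_rec = ref_rec.complemented()
        ref_rows.append(
            (
                ref_rec.snp_id, ref_rec.chromosome, ref_rec.position,
                ref_rec.allele_a, ref_rec.allele_b, ref_rec.strand, ref_rec.counted_allele,
                ref_counts[j] / config.n_alleles_reference, config.n_alleles_reference,
            )
        )
    reference_frame = pd.DataFrame(
        ref_rows,
        columns=[
            "snp_id", "chromosome", "position", "allele_a", "allele_b",
            "strand", "counted_allele", "paf", "n_alleles",
        ],
    )

    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "true_freq_study": study_freq,
            "true_freq_reference": reference_freq,
            "diverged": diverged,
            "gene": [genes[g] for g in snp_gene],
            "group": [groups[g] for g in snp_group],
            "strand_ambiguous": ambiguous,
            "reference_opposite_strand": ref_complement,
        }
    )
    return genotypes, reference_frame, records, mapping, truth


def generate_group_mapping(
    n_genes: int,
    n_groups: int,
    mean_snps_per_gene: float = 12.7,
    seed: int = 0,
    allow_gene_overlap: bool = False,
    overlap_rate: float = 0.1,
) -> GroupMapping:
    """Random functional-group mapping with its own SNP ids.

    Per-gene SNP counts are Poisson with the given mean; every group gets at
    least one gene, and every SNP belongs to exactly one gene. With
    ``allow_gene_overlap`` a fraction of genes is additionally listed under
    a second group.
    """
    if n_genes < 1 or n_groups < 1:
        raise ValueError("n_genes and n_groups must be positive")
    if n_genes < n_groups:
        raise ValueError("n_genes must be >= n_groups")
    rng = np.random.default_rng(seed)
    genes = [f"gene{g + 1:05d}" for g in range(n_genes)]
    groups = [f"group{k + 1:02d}" for k in range(n_groups)]
    permuted = rng.permutation(n_genes)
    gene_group = np.empty(n_genes, dtype=int)
    gene_group[permuted[:n_groups]] = np.arange(n_groups)
    if n_genes > n_groups:
        gene_group[permuted[n_groups:]] = rng.integers(0, n_groups, n_genes - n_groups)
    group_to_genes = {g: [] for g in groups}
    for gi, gene in enumerate(genes):
        group_to_genes[groups[gene_group[gi]]].append(gene)
    if allow_gene_overlap:
        extra = rng.random(n_genes) < overlap_rate
        for gi in np.flatnonzero(extra):
            other = int(rng.integers(0, n_groups))
            if genes[gi] not in group_to_genes[groups[other]]:
                group_to_genes[groups[other]].append(genes[gi])
    counts = rng.poisson(mean_snps_per_gene, n_genes)
    gene_to_snps = {}
    serial = 0
    for gene, count in zip(genes, counts):
        snps = [f"rs{serial + i + 1:07d}" for i in range(int(count))]
        serial += int(count)
        gene_to_snps[gene] = snps
    return GroupMapping(group_to_genes, gene_to_snps)


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
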