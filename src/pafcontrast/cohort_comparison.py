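"""Cross-cohort allele-frequency comparison by confidence-interval overlap.

Two cohorts' frequencies for a SNP are declared significantly different when
their 95% confidence intervals are disjoint; touching bounds count as
overlap. Before comparison the reference record is harmonized onto the
study's counted allele, resolving allele swaps and opposite-strand
encodings (strand-ambiguous A/T and C/G SNPs must already be removed —
for them the two resolutions are indistinguishable).

Per-SNP calls are summarized as the proportions greater / less / either,
tabulated over seven frequency bins (exact 0%, five 20-point interior
ranges, exact 100%), and screened for large absolute differences within the
mid-frequency window where both cohorts have power.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genio import COMPLEMENT, SnpRecord, reference_records
from .paf_estimation import FreqEstimate, estimates_from_reference

BIN_LABELS = ["0%", ">0-20%", ">20-40%", ">40-60%", ">60-80%", ">80-<100%", "100%"]


class Orientation(enum.Enum):
    SAME = "same"
    SWAP = "swap"
    COMPLEMENT = "complement"
    COMPLEMENT_SWAP = "complement+swap"
    INCOMPARABLE = "incomparable"

    @property
    def flips_frequency(self) -> bool:
        return self in (Orientation.SWAP, Orientation.COMPLEMENT_SWAP)


class DiffStatus(enum.Enum):
    GREATER = "GREATER"
    LESS = "LESS"
    NOT_DIFFERENT = "NOT_DIFFERENT"
    INCOMPARABLE = "INCOMPARABLE"


@dataclass(frozen=True)
class ComparisonConfig:
    """Bin scheme and difference thresholds (percent scale)."""

    z_quantile: float = 1.96
    abs_diff_thresholds: tuple = (10.0, 20.0)
    mid_range: tuple = (20.0, 80.0)


@dataclass(frozen=True)
class DiffCall:
    """Classification of one SNP's study-vs-reference frequency difference."""

    snp_id: str
    status: DiffStatus
    study: FreqEstimate | None = None
    reference: FreqEstimate | None = None  # harmonized onto the study counted allele

    @property
    def comparable(self) -> bool:
        return self.status is not DiffStatus.INCOMPARABLE

    @property
    def differing(self) -> bool:
        return self.status in (DiffStatus.GREATER, DiffStatus.LESS)


def harmonize(study_record: SnpRecord, ref_record: SnpRecord) -> Orientation:
    """Orientation mapping the reference counted allele onto the study's.

    Tries the identity and the base-complement map; within each, the
    reference may count either allele of the pair (swap). Returns
    ``INCOMPARABLE`` when neither map matches the allele pairs.
    """
    if ref_record.alleles == study_record.alleles:
        if ref_record.counted_allele == study_record.counted_allele:
            return Orientation.SAME
        return Orientation.SWAP
    complemented = frozenset(COMPLEMENT[a] for a in ref_record.alleles)
    if complemented == study_record.alleles:
        if COMPLEMENT[ref_record.counted_allele] == study_record.counted_allele:
            return Orientation.COMPLEMENT
        return Orientation.COMPLEMENT_SWAP
    return Orientation.INCOMPARABLE


def classify_difference(study: FreqEstimate, reference: FreqEstimate) -> DiffCall:
    """CI-overlap call for a harmonized estimate pair.

    GREATER/LESS require strictly disjoint intervals; a shared endpoint is
    overlap, hence NOT_DIFFERENT.
    """
    if study.ci_low > reference.ci_high:
        status = DiffStatus.GREATER
    elif study.ci_high < reference.ci_low:
        status = DiffStatus.LESS
    else:
        status = DiffStatus.NOT_DIFFERENT
    return DiffCall(study.snp_id, status, study, reference)


def compare_cohorts(
    study_estimates: Mapping[str, FreqEstimate],
    study_records: Mapping[str, SnpRecord],
    reference_frame: pd.DataFrame,
    config: ComparisonConfig | None = None,
) -> list:
    """Per-SNP DiffCalls of a study cohort against a reference table.

    SNPs missing from the reference, or whose allele pairs cannot be
    harmonized, yield INCOMPARABLE calls.
    """
    config = config or ComparisonConfig()
    ref_recs = reference_records(reference_frame)
    ref_est = estimates_from_reference(reference_frame, config.z_quantile)
    calls = []
    for snp_id, study in study_estimates.items():
        if snp_id not in ref_est:
            calls.append(DiffCall(snp_id, DiffStatus.INCOMPARABLE, study, None))
            continue
        orientation = harmonize(study_records[snp_id], ref_recs[snp_id])
        if orientation is Orientation.INCOMPARABLE:
            calls.append(DiffCall(snp_id, DiffStatus.INCOMPARABLE, study, None))
            continue
        reference = ref_est[snp_id]
        if orientation.flips_frequency:
            reference = reference.mirrored()
        calls.append(classify_difference(study, reference))
    return calls


def summarize_differences(calls: Sequence[DiffCall]) -> tuple:
    """(greater, less, either) proportions over comparable SNPs."""
    comparable = [c for c in calls if c.comparable]
    if not comparable:
        raise ValueError("no comparable SNPs to summarize")
    n = len(comparable)
    greater = sum(c.status is DiffStatus.GREATER for c in comparable) / n
    less = sum(c.status is DiffStatus.LESS for c in comparable) / n
    return greater, less, greater + less


def bin_by_paf(paf: float) -> int:
    """Index of the seven-bin scheme a PAF (proportion) falls in.

    Exact 0 and exact 1 have singleton bins; interior bins are upper-closed
    20-point ranges on the percent scale.
    """
    if not 0.0 <= paf <= 1.0:
        raise ValueError(f"PAF outside [0,1]: {paf}")
    if paf == 0.0:
        return 0
    if paf == 1.0:
        return 6
    pct = 100.0 * paf
    for k, upper in enumerate((20.0, 40.0, 60.0, 80.0), start=1):
        if pct <= upper:
            return k
    return 5


def tabulate_by_bin(calls: Sequence[DiffCall]) -> pd.DataFrame:
    """Per-bin totals, differing counts and percentages, binned by study PAF.

    Mirrors the layout of a literature-comparison table: one column per
    frequency range plus a Total column.
    """
    totals = np.zeros(7, dtype=int)
    differing = np.zeros(7, dtype=int)
    for call in calls:
        if not call.comparable:
            continue
        k = bin_by_paf(call.study.paf)
        totals[k] += 1
        differing[k] += call.differing
    with np.errstate(invalid="ignore"):
        pct = np.where(totals > 0, 100.0 * differing / np.maximum(totals, 1), 0.0)
    frame = pd.DataFrame(
        [
            np.append(totals, totals.sum()),
            np.append(differing, differing.sum()),
            np.append(pct, 100.0 * differing.sum() / totals.sum() if totals.sum() else 0.0),
        ],
        index=["total_snps", "differing", "percent_of_total"],
        columns=BIN_LABELS + ["Total"],
    )
    return frame


def absolute_difference_summary(
    calls: Sequence[DiffCall],
    config: ComparisonConfig | None = None,
) -> dict:
    """Fraction of mid-range SNPs exceeding each absolute-difference threshold.

    Restricted to comparable SNPs with study PAF inside the mid-range window
    (inclusive); the threshold comparison is ``>=`` on the percent scale.
    """
    config = config or ComparisonConfig()
    lo, hi = (x / 100.0 for x in config.mid_range)
    window = [
        c for c in calls if c.comparable and lo <= c.study.paf <= hi
    ]
    out = {}
    for threshold in config.abs_diff_thresholds:
        if not window:
            out[threshold] = 0.0
            continue
        hits = sum(
            100.0 * abs(c.study.paf - c.reference.paf) >= threshold - 1e-9 for c in window
        )
        out[threshold] = hits / len(window)
    return out


def multi_cohort_comparison(
    frames: Mapping[str, pd.DataFrame],
    config: ComparisonConfig | None = None,
    pairs: Sequence[tuple] | None = None,
) -> dict:
    """All pairwise CI-overlap tabulations across k cohort frequency tables.

    Each cohort is given as a reference-frequency frame; for a pair (a, b)
    cohort ``a`` plays the study role. Returns per-pair calls and bin tables
    plus the aggregate percent differing (pooled counts over the pairs).
    """
    config = config or ComparisonConfig()
    names = list(frames)
    if len(names) < 2:
        raise ValueError("need at least two cohorts")
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    results = {}
    total = differing = 0
    for a, b in pairs:
        est_a = estimates_from_reference(frames[a], config.z_quantile)
        rec_a = reference_records(frames[a])
        calls = compare_cohorts(est_a, rec_a, frames[b], config)
        comparable = [c for c in calls if c.comparable]
        n_diff = sum(c.differing for c in comparable)
        results[(a, b)] = {
            "calls": calls,
            "table": tabulate_by_bin(calls),
            "n_comparable": len(comparable),
            "n_differing": n_diff,
        }
        total += len(comparable)
        differing += n_diff
    aggregate = 100.0 * differing / total if total else 0.0
    return {"pairs": results, "aggregate_percent_differing": aggregate,
            "aggregate_total": total, "aggregate_differing": differing}


def calls_to_frame(calls: Sequence[DiffCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            (
                c.snp_id,
                c.status.value,
                c.study.paf if c.study else np.nan,
                c.study.ci_low if c.study else np.nan,
                c.study.ci_high if c.study else np.nan,
                c.reference.paf if c.reference else np.nan,
                c.reference.ci_low if c.reference else np.nan,
                c.reference.ci_high if c.reference else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "status", "study_paf", "study_ci_low", "study_ci_high",
            "ref_paf", "ref_ci_low", "ref_ci_high",
        ],
    )
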