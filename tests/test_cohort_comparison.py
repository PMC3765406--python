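import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pafcontrast import (
    ComparisonConfig,
    DiffStatus,
    Orientation,
    SnpRecord,
    classify_difference,
    compare_cohorts,
    harmonize,
    summarize_differences,
)
from pafcontrast.cohort_comparison import (
    absolute_difference_summary,
    bin_by_paf,
    multi_cohort_comparison,
    tabulate_by_bin,
)
from pafcontrast.genio import COMPLEMENT
from pafcontrast.paf_estimation import FreqEstimate, estimate_paf


def _rec(snp="rs1", a="A", b="G", counted="A", strand="+"):
    return SnpRecord(snp, "1", 100, a, b, strand, counted)


def _est(snp="rs1", paf=0.5, low=None, high=None, n=432, allele="A"):
    if low is None:
        low, high = max(paf - 0.05, 0), min(paf + 0.05, 1)
    return FreqEstimate(snp, allele, paf, n, low, high)


class TestHarmonize:
    def test_identity(self):
        assert harmonize(_rec(), _rec()) is Orientation.SAME

    def test_swap(self):
        assert harmonize(_rec(counted="A"), _rec(counted="G")) is Orientation.SWAP

    def test_complement(self):
        study = _rec(a="A", b="G", counted="A")
        ref = _rec(a="T", b="C", counted="T", strand="-")
        assert harmonize(study, ref) is Orientation.COMPLEMENT

    def test_complement_swap(self):
        study = _rec(a="A", b="G", counted="A")
        ref = _rec(a="T", b="C", counted="C", strand="-")
        assert harmonize(study, ref) is Orientation.COMPLEMENT_SWAP

    def test_disjoint_pairs_incomparable(self):
        assert harmonize(_rec(a="A", b="G"), _rec(a="A", b="C", counted="A")) \
            is Orientation.INCOMPARABLE


class TestClassifyDifference:
    def test_identical_estimates_not_different(self):
        call = classify_difference(_est(), _est())
        assert call.status is DiffStatus.NOT_DIFFERENT

    def test_disjoint_intervals_greater(self):
        study = _est(paf=0.60, low=0.55, high=0.65)
        ref = _est(paf=0.40, low=0.34, high=0.46)
        assert classify_difference(study, ref).status is DiffStatus.GREATER

    def test_disjoint_intervals_less(self):
        study = _est(paf=0.40, low=0.34, high=0.46)
        ref = _est(paf=0.60, low=0.55, high=0.65)
        assert classify_difference(study, ref).status is DiffStatus.LESS

    def test_touching_bounds_count_as_overlap(self):
        study = _est(paf=0.50, low=0.45, high=0.55)
        ref = _est(paf=0.60, low=0.55, high=0.65)
        assert classify_difference(study, ref).status is DiffStatus.NOT_DIFFERENT

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.integers(0, 432), st.integers(0, 224)
    )
    def test_antisymmetry(self, count_a, count_b):
        a = estimate_paf("rs1", "A", count_a, 432)
        b = estimate_paf("rs1", "A", count_b, 224)
        forward = classify_difference(a, b).status
        backward = classify_difference(b, a).status
        mapping = {DiffStatus.GREATER: DiffStatus.LESS,
                   DiffStatus.LESS: DiffStatus.GREATER}
        assert backward is mapping.get(forward, forward)


class TestSummarize:
    def test_all_not_different(self):
        calls = [classify_difference(_est(), _est()) for _ in range(4)]
        assert summarize_differences(calls) == (0.0, 0.0, 0.0)

    def test_mixed_counts(self):
        greater = classify_difference(_est(paf=0.6, low=0.55, high=0.65),
                                      _est(paf=0.4, low=0.34, high=0.46))
        less = classify_difference(_est(paf=0.4, low=0.34, high=0.46),
                                   _est(paf=0.6, low=0.55, high=0.65))
        same = classify_difference(_est(), _est())
        summary = summarize_differences([greater, less, same, same])
        assert summary == (0.25, 0.25, 0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_differences([])


class TestBinning:
    @pytest.mark.parametrize(
        "paf, expected",
        [(0.0, 0), (1e-9, 1), (0.2, 1), (0.2000001, 2), (0.4, 2), (0.6, 3),
         (0.8, 4), (0.80001, 5), (0.999999, 5), (1.0, 6)],
    )
    def test_bin_edges(self, paf, expected):
        assert bin_by_paf(paf) == expected

    def test_tabulate_matches_direct_counting(self, small_dataset):
        _, (genotypes, reference, records, _, _) = small_dataset
        from pafcontrast import estimate_cohort

        by_id = {r.snp_id: r for r in records}
        keep = [r.snp_id for r in records if r.alleles not in
                (frozenset("AT"), frozenset("CG"))]
        counted = {r.snp_id: r.counted_allele for r in records}
        estimates = estimate_cohort(genotypes.subset_snps(keep), counted)
        calls = compare_cohorts(estimates, by_id, reference)
        table = tabulate_by_bin(calls)
        # brute-force binning oracle
        totals = [0] * 7
        differing = [0] * 7
        for c in calls:
            if not c.comparable:
                continue
            p = c.study.paf
            if p == 0:
                k = 0
            elif p == 1:
                k = 6
            else:
                k = min(int(np.ceil(p * 5)), 5)
            totals[k] += 1
            differing[k] += c.status in (DiffStatus.GREATER, DiffStatus.LESS)
        assert table.loc["total_snps"].tolist()[:-1] == totals
        assert table.loc["differing"].tolist()[:-1] == differing
        assert table.loc["total_snps", "Total"] == sum(totals)


class TestAbsoluteDifference:
    def test_identical_cohorts_zero(self):
        calls = [classify_difference(_est(paf=0.5), _est(paf=0.5))]
        summary = absolute_difference_summary(calls)
        assert summary == {10.0: 0.0, 20.0: 0.0}

    def test_threshold_rule_is_inclusive_on_percent(self):
        call = classify_difference(_est(paf=0.50), _est(paf=0.35, low=0.30, high=0.40))
        summary = absolute_difference_summary([call])
        assert summary[10.0] == 1.0
        assert summary[20.0] == 0.0

    def test_window_excludes_extreme_pafs(self):
        inside = classify_difference(_est(paf=0.5), _est(paf=0.2, low=0.15, high=0.25))
        outside = classify_difference(_est(paf=0.1, low=0.05, high=0.15),
                                      _est(paf=0.9, low=0.85, high=0.95))
        summary = absolute_difference_summary([inside, outside])
        assert summary[10.0] == 1.0  # only the in-window SNP counts

    def test_matches_brute_force_on_synthetic(self, small_dataset):
        _, (genotypes, reference, records, _, _) = small_dataset
        from pafcontrast import estimate_cohort

        by_id = {r.snp_id: r for r in records}
        counted = {r.snp_id: r.counted_allele for r in records}
        estimates = estimate_cohort(genotypes, counted)
        calls = compare_cohorts(estimates, by_id, reference)
        summary = absolute_difference_summary(calls)
        window = [c for c in calls if c.comparable and 0.2 <= c.study.paf <= 0.8]
        for threshold in (10.0, 20.0):
            expected = np.mean(
                [abs(c.study.paf - c.reference.paf) * 100 >= threshold - 1e-9
                 for c in window]
            )
            assert summary[threshold] == pytest.approx(expected)


class TestHarmonizationInvariance:
    def test_complement_encoded_reference_gives_identical_calls(self, small_dataset):
        """Re-encoding the whole reference table on the opposite strand must
        not change a single difference call."""
        _, (genotypes, reference, records, _, _) = small_dataset
        from pafcontrast import estimate_cohort

        by_id = {r.snp_id: r for r in records}
        keep = [r.snp_id for r in records if r.alleles not in
                (frozenset("AT"), frozenset("CG"))]
        counted = {r.snp_id: r.counted_allele for r in records}
        estimates = estimate_cohort(genotypes.subset_snps(keep), counted)
        calls = compare_cohorts(estimates, by_id, reference)

        flipped = reference.copy()
        flipped["allele_a"] = reference["allele_a"].map(COMPLEMENT)
        flipped["allele_b"] = reference["allele_b"].map(COMPLEMENT)
        flipped["counted_allele"] = reference["counted_allele"].map(COMPLEMENT)
        flipped["strand"] = reference["strand"].map({"+": "-", "-": "+"})
        calls_flipped = compare_cohorts(estimates, by_id, flipped)

        ambiguous = {r.snp_id for r in records if r.alleles in
                     (frozenset("AT"), frozenset("CG"))}
        for a, b in zip(calls, calls_flipped):
            if a.snp_id in ambiguous:
                continue  # ambiguous pairs are unresolvable by construction
            assert a.status == b.status, a.snp_id


class TestMultiCohort:
    def _cohort_frame(self, rng, snps, n_alleles, freqs):
        rows = []
        for (snp, freq) in zip(snps, freqs):
            count = rng.binomial(n_alleles, freq)
            rows.append((snp, "1", 100, "A", "G", "+", "A",
                         count / n_alleles, n_alleles))
        return pd.DataFrame(rows, columns=[
            "snp_id", "chromosome", "position", "allele_a", "allele_b",
            "strand", "counted_allele", "paf", "n_alleles"])

    def test_self_comparison_zero_differing(self):
        rng = np.random.default_rng(0)
        snps = [f"rs{i}" for i in range(50)]
        frame = self._cohort_frame(rng, snps, 224, rng.uniform(0.1, 0.9, 50))
        result = multi_cohort_comparison({"a": frame, "b": frame.copy()})
        assert result["aggregate_percent_differing"] == 0.0

    def test_pairwise_counts_match_brute_force(self):
        rng = np.random.default_rng(1)
        snps = [f"rs{i}" for i in range(120)]
        frames = {
            name: self._cohort_frame(rng, snps, 224, rng.uniform(0.05, 0.95, len(snps)))
            for name in ("a", "b", "c")
        }
        result = multi_cohort_comparison(frames)
        assert set(result["pairs"]) == {("a", "b"), ("a", "c"), ("b", "c")}
        total = differing = 0
        for (x, y), res in result["pairs"].items():
            from pafcontrast.paf_estimation import estimates_from_reference

            ex = estimates_from_reference(frames[x])
            ey = estimates_from_reference(frames[y])
            expected_diff = sum(
                ex[s].ci_low > ey[s].ci_high or ex[s].ci_high < ey[s].ci_low
                for s in snps
            )
            assert res["n_differing"] == expected_diff
            assert res["n_comparable"] == len(snps)
            total += len(snps)
            differing += expected_diff
        assert result["aggregate_percent_differing"] == pytest.approx(
            100 * differing / total
        )

    def test_requires_two_cohorts(self):
        with pytest.raises(ValueError):
            multi_cohort_comparison({"a": pd.DataFrame()})
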