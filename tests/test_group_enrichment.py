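import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pafcontrast import (
    DiffStatus,
    binom_cdf,
    bonferroni_threshold,
    direction_sign_test,
    group_binomial_test,
    meta_count_probability,
    run_enrichment,
)
from pafcontrast.cohort_comparison import DiffCall
from pafcontrast.genio import GroupMapping
from pafcontrast.group_enrichment import (
    Direction,
    EnrichmentConfig,
    Tail,
    compute_base_rate,
    meta_group_count_test,
)


def binom_cdf_oracle(k: int, n: int, p: float) -> float:
    """Direct-summation oracle with exact binomial coefficients."""
    return float(sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k + 1)))


def _call(snp, status):
    return DiffCall(snp, status)


class TestBinomCdf:
    def test_full_support_is_one(self):
        assert binom_cdf(10, 10, 0.3) == 1.0

    def test_small_enumeration(self):
        assert binom_cdf(1, 2, 0.5) == pytest.approx(0.75, abs=1e-15)

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60),
           st.sampled_from([0.05, 0.25, 0.471, 0.5, 0.9]))
    def test_matches_direct_summation(self, k, n, p):
        if k > n:
            return
        assert binom_cdf(k, n, p) == pytest.approx(binom_cdf_oracle(k, n, p), abs=1e-12)

    def test_non_decreasing_in_k(self):
        values = [binom_cdf(k, 40, 0.471) for k in range(41)]
        assert all(a <= b + 1e-15 for a, b in zip(values, values[1:]))

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            binom_cdf(5, 4, 0.5)
        with pytest.raises(ValueError):
            binom_cdf(1, 4, 1.5)


class TestComputeBaseRate:
    def test_all_not_different_is_zero(self):
        calls = [_call(f"rs{i}", DiffStatus.NOT_DIFFERENT) for i in range(5)]
        assert compute_base_rate(calls) == 0.0

    def test_fraction(self):
        calls = [_call(f"rs{i}", DiffStatus.GREATER) for i in range(47)]
        calls += [_call(f"rs{i + 47}", DiffStatus.NOT_DIFFERENT) for i in range(53)]
        assert compute_base_rate(calls) == pytest.approx(0.47)

    def test_incomparable_excluded(self):
        calls = [_call("rs1", DiffStatus.LESS), _call("rs2", DiffStatus.INCOMPARABLE)]
        assert compute_base_rate(calls) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compute_base_rate([])


class TestGroupBinomialTest:
    @pytest.mark.parametrize(
        "n, k, expected, direction",
        [
            (18, 14, 0.0018, Direction.MORE),
            (130, 67, 0.1353, Direction.MORE),
            (834, 378, 0.1604, Direction.LESS),
            (144, 49, 0.0010, Direction.LESS),
        ],
    )
    def test_published_anchor_rows(self, n, k, expected, direction):
        """Group tallies reproduce the published probabilities at base rate
        0.471 under the default tail conventions."""
        result = group_binomial_test("g", n, k, 0.471)
        assert result.direction is direction
        assert result.probability == pytest.approx(expected, abs=5e-5)

    def test_tie_reports_smaller_tail(self):
        result = group_binomial_test("g", 10, 5, 0.5)
        assert result.direction is Direction.TIE
        assert result.probability == pytest.approx(
            min(1 - binom_cdf(5, 10, 0.5), binom_cdf(5, 10, 0.5)), abs=1e-15
        )

    def test_more_probability_decreases_with_count(self):
        probs = [group_binomial_test("g", 50, k, 0.3).probability
                 for k in range(16, 50)]  # all MORE
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_less_probability_increases_with_count(self):
        probs = [group_binomial_test("g", 50, k, 0.7).probability
                 for k in range(0, 35)]  # all LESS
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_zero_snps_rejected(self):
        with pytest.raises(ValueError):
            group_binomial_test("g", 0, 0, 0.471)


class TestMetaAndSign:
    def test_bonferroni_values(self):
        assert bonferroni_threshold(0.05, 53) == pytest.approx(0.000943, abs=5e-7)
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 4) == 0.0025

    def test_meta_count_published_value(self):
        assert meta_count_probability(7, 53, 0.05) == pytest.approx(0.0046, abs=5e-5)

    def test_meta_none_significant_closed_form(self):
        assert meta_count_probability(0, 53, 0.05) == pytest.approx(
            1 - 0.95**53, abs=1e-12
        )

    def test_meta_all_significant_strict_tail_zero(self):
        assert meta_count_probability(53, 53, 0.05) == 0.0

    def test_meta_from_probability_list(self):
        probs = [0.01] * 7 + [0.5] * 46
        assert meta_group_count_test(probs, 0.05) == pytest.approx(0.0046, abs=5e-5)

    def test_sign_test_published_value(self):
        assert direction_sign_test(28, 25) == pytest.approx(0.392, abs=5e-4)

    def test_sign_test_enumeration(self):
        assert direction_sign_test(2, 2) == pytest.approx(11 / 16, abs=1e-12)

    def test_sign_test_unanimous(self):
        assert direction_sign_test(53, 0) == pytest.approx(2.0**-53, rel=1e-9)

    def test_sign_test_empty_rejected(self):
        with pytest.raises(ValueError):
            direction_sign_test(0, 0)


class TestRunEnrichment:
    def _mapping(self, groups):
        group_to_genes = {}
        gene_to_snps = {}
        for gi, (group, snps) in enumerate(groups.items()):
            gene = f"gene{gi}"
            group_to_genes[group] = [gene]
            gene_to_snps[gene] = snps
        return GroupMapping(group_to_genes, gene_to_snps)

    def test_groups_at_base_rate_not_significant(self):
        calls = []
        groups = {}
        for g in range(5):
            snps = [f"rs{g}_{i}" for i in range(100)]
            groups[f"group{g}"] = snps
            for i, snp in enumerate(snps):
                calls.append(_call(snp, DiffStatus.GREATER if i < 47 else
                                   DiffStatus.NOT_DIFFERENT))
        results, meta = run_enrichment(calls, self._mapping(groups),
                                       EnrichmentConfig(base_rate=0.47))
        assert meta.n_significant == 0
        # strict tail of zero significant groups: P(X > 0) = 1 - (1-alpha)^m
        assert meta.meta_probability == pytest.approx(1 - 0.95**5, abs=1e-12)

    def test_zero_comparable_group_reported_and_excluded(self):
        groups = {"good": [f"rs{i}" for i in range(20)], "empty": ["rsX", "rsY"]}
        calls = [_call(f"rs{i}", DiffStatus.LESS if i < 8 else DiffStatus.NOT_DIFFERENT)
                 for i in range(20)]
        calls += [_call("rsX", DiffStatus.INCOMPARABLE), _call("rsY", DiffStatus.INCOMPARABLE)]
        results, meta = run_enrichment(calls, self._mapping(groups),
                                       EnrichmentConfig(base_rate=0.4))
        by_group = {r.group: r for r in results}
        assert by_group["empty"].n_snps == 0
        assert meta.n_groups == 1

    def test_results_equal_per_group_oracle(self):
        rng = np.random.default_rng(2)
        groups = {}
        calls = []
        serial = 0
        for g in range(8):
            size = int(rng.integers(10, 40))
            snps = [f"rs{serial + i}" for i in range(size)]
            serial += size
            groups[f"group{g}"] = snps
            for snp in snps:
                status = DiffStatus.GREATER if rng.random() < 0.45 else DiffStatus.NOT_DIFFERENT
                calls.append(_call(snp, status))
        config = EnrichmentConfig(base_rate=0.471)
        results, _ = run_enrichment(calls, self._mapping(groups), config)
        by_snp = {c.snp_id: c for c in calls}
        for r in results:
            snps = groups[r.group]
            k = sum(by_snp[s].differing for s in snps)
            n = len(snps)
            assert (r.n_snps, r.n_differing) == (n, k)
            if k / n > 0.471:
                expected = 1 - binom_cdf_oracle(k, n, 0.471)
            elif k / n < 0.471:
                expected = binom_cdf_oracle(k, n, 0.471)
            else:
                expected = min(binom_cdf_oracle(k, n, 0.471),
                               1 - binom_cdf_oracle(k, n, 0.471))
            assert r.probability == pytest.approx(expected, abs=1e-10)

    def test_empirical_base_rate_used_when_unpinned(self):
        snps = [f"rs{i}" for i in range(10)]
        calls = [_call(s, DiffStatus.GREATER if i < 3 else DiffStatus.NOT_DIFFERENT)
                 for i, s in enumerate(snps)]
        results, _ = run_enrichment(calls, self._mapping({"g": snps}), EnrichmentConfig())
        # whole-set proportion equals the base rate, so the group is a TIE
        assert results[0].direction is Direction.TIE
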