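"""Library QC statistics: classification, AR, coverage, discrepancy, folding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smartrbs import (
    LibraryComposition,
    abundance_discrepancy,
    ar_efficiency,
    classify_clone,
    clones_for_coverage,
    coverage,
    coverage_probability,
    hairpin_dg_proxy,
    mean_coverage,
    qc_report,
)

MEMBERS = ["CCCCCC", "GGGGGG", "TTTTTT"]
WILD = "AAAAAA"


class TestClassification:
    def test_member_wild_indel_other(self):
        assert classify_clone("CCCCCC", MEMBERS, WILD) == "CCCCCC"
        assert classify_clone("AAAAAA", MEMBERS, WILD) == "wild"
        assert classify_clone("CCCCC", MEMBERS, WILD) == "indel"   # one short
        assert classify_clone("CCCCCCA", MEMBERS, WILD) == "indel"  # one long
        assert classify_clone("ACCCCC", MEMBERS, WILD) == "other"

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_clone("AAAAAA", [], WILD)

    @given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=8), max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_categories_partition_reads(self, reads):
        comp = LibraryComposition.from_reads(reads, MEMBERS, WILD)
        assert comp.total == len(reads)
        assert comp.mutant_count + comp.wild_count + comp.indel_count + comp.other_count == len(reads)


class TestArEfficiency:
    def test_ratio_of_mutants_to_total(self):
        comp = LibraryComposition({"CCCCCC": 48}, wild_count=52, n=18)
        assert ar_efficiency(comp) == pytest.approx(0.48)

    def test_zero_and_full(self):
        assert ar_efficiency(LibraryComposition({"CCCCCC": 0}, wild_count=10, n=18)) == 0.0
        assert ar_efficiency(LibraryComposition({"CCCCCC": 7}, n=18)) == 1.0

    def test_indel_denominator_policy(self):
        comp = LibraryComposition({"CCCCCC": 86}, wild_count=0, indel_count=2, n=18)
        assert ar_efficiency(comp) == pytest.approx(86 / 88)
        assert ar_efficiency(comp, exclude_indels=True) == pytest.approx(1.0)

    def test_no_clones_rejected(self):
        with pytest.raises(ValueError):
            ar_efficiency(LibraryComposition({"CCCCCC": 0}, n=18))


class TestCoverage:
    def test_replicate_means_match_reported_percents(self):
        # recovering 16 and 18 of 18 -> 94%; 5 and 9 of 18 -> 39%
        assert mean_coverage([(16, 18), (18, 18)]) == 94
        assert mean_coverage([(5, 18), (9, 18)]) == 39

    def test_all_members_seen_is_full_coverage(self):
        comp = LibraryComposition({m: 1 for m in MEMBERS}, n=3)
        assert coverage(comp) == 1.0
        assert mean_coverage([comp]) == 100

    def test_coverage_non_decreasing_as_clones_accumulate(self):
        rng = np.random.default_rng(3)
        reads = [MEMBERS[i] for i in rng.integers(0, 3, size=30)]
        prev = 0.0
        for k in range(1, len(reads) + 1):
            cov = coverage(LibraryComposition.from_reads(reads[:k], MEMBERS, WILD))
            assert cov >= prev
            prev = cov
        assert prev <= 1.0


class TestDiscrepancy:
    def test_exact_uniform_is_zero(self):
        assert abundance_discrepancy(1 / 18, 18) == pytest.approx(0.0)

    def test_one_decimal_convention_reproduces_printed_arithmetic(self):
        # 2.75% abundance against the truncated 5.5% share reads as -50%
        assert abundance_discrepancy(0.0275, 18, "one_decimal") == pytest.approx(-50.0)

    def test_double_expected_is_plus_100(self):
        assert abundance_discrepancy(2 / 18, 18) == pytest.approx(100.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            abundance_discrepancy(1.2, 18)
        with pytest.raises(ValueError):
            abundance_discrepancy(0.5, 18, "two_decimal")


class TestClonesForCoverage:
    def test_two_member_hand_case(self):
        # two uniform members, two draws: 2 of 4 outcomes cover both
        assert coverage_probability([0.5, 0.5], 2) == pytest.approx(0.5)

    def test_inclusion_exclusion_matches_direct_formula(self):
        """Independent oracle: the uniform-case closed form
        sum_k (-1)^k C(n,k) (1-k/n)^m."""
        n = 18
        for m in (60, 103, 150):
            direct = sum(
                (-1) ** k * math.comb(n, k) * (1 - k / n) ** m
                for k in range(n + 1)
            )
            assert coverage_probability([1 / n] * n, m) == pytest.approx(direct, abs=1e-12)

    def test_uniform_18_member_target(self):
        # frozen from the direct inclusion-exclusion oracle above:
        # P(102) = 0.94804..., P(103) = 0.95088...
        assert clones_for_coverage([1 / 18] * 18, 0.95) == 103

    def test_monotone_in_target(self):
        freqs = [1 / 5] * 5
        ms = [clones_for_coverage(freqs, p) for p in (0.5, 0.8, 0.95, 0.99)]
        assert ms == sorted(ms)

    def test_zero_frequency_member_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            clones_for_coverage([0.5, 0.5, 0.0], 0.9)

    @pytest.mark.parametrize("n", [2, 5, 18])
    def test_exact_matches_monte_carlo(self, n):
        freqs = [1 / n] * n
        m = clones_for_coverage(freqs, 0.9)
        p_exact = coverage_probability(freqs, m)
        n_rep = 20_000
        p_mc = coverage_probability(freqs, m, method="mc", seed=42, n_rep=n_rep)
        se = math.sqrt(p_exact * (1 - p_exact) / n_rep)
        assert abs(p_mc - p_exact) <= 3 * se


class TestHairpinProxy:
    def test_unstructured_is_zero(self):
        assert hairpin_dg_proxy("AAAAAAAAAA").dg == 0.0

    def test_stem_four_loop_three(self):
        fp = hairpin_dg_proxy("GGGGAAACCCC")
        assert (fp.stem_length, fp.loop_length, fp.dg) == (4, 3, -8.0)

    def test_short_or_loop_violating_stems_ignored(self):
        assert hairpin_dg_proxy("ACGTACGT").dg == 0.0

    def test_degenerate_bases_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hairpin_dg_proxy("GGGNAAACCC")


class TestReport:
    def test_report_fields_and_consistency(self):
        reads = ["CCCCCC"] * 40 + ["GGGGGG"] * 30 + ["AAAAAA"] * 20 + ["CCCCC"] * 10
        comp = LibraryComposition.from_reads(reads, MEMBERS, WILD)
        rep = qc_report(comp)
        assert rep["total_clones"] == 100
        assert rep["ar_efficiency"] == pytest.approx(0.70)
        assert rep["coverage"] == pytest.approx(2 / 3)
        assert rep["wild_fraction"] == pytest.approx(0.20)
        assert rep["indel_fraction"] == pytest.approx(0.10)
        # spearman correlation is reported descriptively (or None when flat)
        assert "dg_abundance_correlation" in rep

    def test_pool_abundance_drives_discrepancy(self):
        comp = LibraryComposition({m: 1 for m in MEMBERS}, n=3)
        rep = qc_report(comp, pool_abundance={"CCCCCC": 2, "GGGGGG": 1, "TTTTTT": 1})
        d = rep["member_discrepancy_percent"]
        assert d["CCCCCC"] == pytest.approx(50.0)
        assert d["GGGGGG"] == pytest.approx(-25.0)
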