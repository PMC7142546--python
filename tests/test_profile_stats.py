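import math

import pytest
from hypothesis import given, settings, strategies as st

from isomirkit.errors import ValidationError
from isomirkit.sequence_io import CollapsedRead, collapse
from isomirkit.isomir_engine import build_assignment_table
from isomirkit.mirna_classifier import classify_loci
from isomirkit.profile_stats import (
    NormalizationContext,
    build_profiles,
    categorize_reads,
    compute_iai,
    compute_idi,
    count_mapped_reads,
    report_round,
    rpm,
)


class TestRpm:
    def test_arithmetic(self):
        ctx = NormalizationContext(5_000_000)
        assert rpm(10, ctx) == 2.0
        assert rpm(0, ctx) == 0.0
        assert rpm(5_000_000, ctx) == 1_000_000.0

    def test_invalid_denominator(self):
        with pytest.raises(ValidationError):
            NormalizationContext(0)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.integers(0, 10**7), b=st.integers(0, 10**7),
        denom=st.integers(1, 10**8),
    )
    def test_linearity(self, a, b, denom):
        ctx = NormalizationContext(denom)
        assert math.isclose(rpm(a, ctx) + rpm(b, ctx), rpm(a + b, ctx), rel_tol=1e-12)


class TestIndices:
    def test_idi_zero_isomirs(self):
        assert compute_idi(0, 100.0) == 0.0

    def test_iai_zero_total(self):
        assert compute_iai(0.0, 50.0) == 0.0

    def test_undefined_when_mature_rpm_zero(self):
        assert math.isnan(compute_idi(5, 0.0))
        assert math.isnan(compute_iai(3.0, 0.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            compute_idi(-1, 1.0)
        with pytest.raises(ValidationError):
            compute_iai(-0.5, 1.0)

    def test_round_half_even_reporting(self):
        assert report_round(0.125) == 0.12
        assert report_round(0.135) == 0.14
        assert math.isnan(report_round(math.nan))


class TestProfiles:
    def test_tiny_arithmetic_example(self, toy_locus):
        mature = toy_locus.mature_seq
        star = toy_locus.arm_seq("star")
        ext = toy_locus.seq[toy_locus.mature.start:toy_locus.mature.end + 1]
        table = build_assignment_table(
            [CollapsedRead(mature, 5), CollapsedRead(star, 2), CollapsedRead(ext, 3)],
            [toy_locus],
        )
        results = classify_loci([toy_locus], {})
        (profile,) = build_profiles(table, results, NormalizationContext(10**6))
        assert profile.mature_rpm == 5.0
        assert profile.star_rpm == 2.0
        assert profile.isomir_rpm_total == 3.0
        assert profile.combined_rpm == 8.0
        assert profile.n_distinct_isomirs == 1
        assert math.isclose(profile.idi, 0.2)
        assert math.isclose(profile.iai, 0.6)

    def test_zero_mature_profile_still_emitted(self, toy_locus):
        ext = toy_locus.seq[toy_locus.mature.start:toy_locus.mature.end + 2]
        table = build_assignment_table([CollapsedRead(ext, 4)], [toy_locus])
        results = classify_loci([toy_locus], {})
        (profile,) = build_profiles(table, results, NormalizationContext(10**6))
        assert profile.mature_rpm == 0.0
        assert math.isnan(profile.idi) and math.isnan(profile.iai)

    def test_locus_set_mismatch_rejected(self, toy_locus, small_library):
        table = build_assignment_table([], [toy_locus])
        results = classify_loci(small_library.loci, {})
        with pytest.raises(ValidationError, match="locus sets differ"):
            build_profiles(table, results, NormalizationContext(10**6))

    def test_iai_identity_and_sorting_on_simulated_library(self, small_library):
        collapsed = collapse(small_library.reads)
        table = build_assignment_table(collapsed, small_library.loci)
        results = classify_loci(small_library.loci, small_library.mature_reference)
        ctx = NormalizationContext(len(small_library.reads))
        profiles = build_profiles(table, results, ctx)
        assert len(profiles) == len(small_library.loci)
        for p in profiles:
            if not math.isnan(p.iai):
                assert math.isclose(p.iai * p.mature_rpm, p.isomir_rpm_total, rel_tol=1e-9)
        rpms = [p.mature_rpm for p in profiles]
        assert rpms == sorted(rpms, reverse=True)


class TestCategories:
    def test_priority_order_wins(self):
        shared = "ACGUACGUACGUACGUACGU"
        refs = {"tRNA": ["CC" + shared + "GG"], "rRNA": ["AA" + shared + "UU"]}
        summary = categorize_reads([CollapsedRead(shared, 3)], refs)
        assert summary.counts["tRNA"] == 3
        assert summary.counts["rRNA"] == 0

    def test_unmatched_goes_unassigned(self):
        summary = categorize_reads(
            [CollapsedRead("GGGGGGGGGGGGGGGG", 2)], {"tRNA": ["ACAC" * 30]}
        )
        assert summary.counts["unassigned"] == 2
        assert summary.fractions()["unassigned"] == 1.0

    def test_each_read_in_exactly_one_category(self, small_library):
        collapsed = collapse(small_library.reads)
        refs = {"miRNA": [p.seq for p in small_library.loci],
                **small_library.category_references}
        summary = categorize_reads(collapsed, refs)
        assert sum(summary.counts.values()) == len(small_library.reads)
        assert math.isclose(sum(summary.fractions().values()), 1.0)
        assert summary.per_length.to_numpy().sum() == len(small_library.reads)

    def test_recovers_simulated_composition(self, small_library):
        """Background category fractions come back within sampling error
        of the configured composition."""
        truth = small_library.truth.reads
        bg = truth[truth.origin == "background"]
        collapsed = collapse(small_library.reads)
        refs = {"miRNA": [p.seq for p in small_library.loci],
                **small_library.category_references}
        summary = categorize_reads(collapsed, refs)
        n = len(bg)
        for cat, p_true in small_library.config.background_composition.items():
            if cat == "unassigned":
                continue  # unassigned also absorbs substituted miRNA reads
            observed = summary.counts[cat] / n
            se = math.sqrt(p_true * (1 - p_true) / n)
            assert abs(observed - p_true) <= 4 * se + 1e-9, cat

    def test_exact_substring_mapped_count(self, toy_locus):
        collapsed = [
            CollapsedRead(toy_locus.seq[5:25], 10),
            CollapsedRead("ACGUACGUACGUACGUACGU", 7),
        ]
        assert count_mapped_reads(collapsed, [toy_locus.seq]) == 10
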