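import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles
from isomirkit.errors import ValidationError
from isomirkit.sequence_io import CollapsedRead
from isomirkit.isomir_engine import (
    ArmAssignment,
    CANONICAL_MATURE,
    CANONICAL_STAR,
    ISOMIR,
    IsomirThresholds,
    NO_ALIGNMENT,
    OFFSET_OUT_OF_RANGE,
    Placement,
    align_read_to_precursor,
    assign_to_arm,
    build_assignment_table,
)


def mutate(seq, pos, base="X"):
    if base == "X":
        base = {"A": "C", "C": "G", "G": "U", "U": "A"}[seq[pos]]
    return seq[:pos] + base + seq[pos + 1:]


def records_as_tuples(table):
    return {
        (r.seq, r.count, r.locus_id, r.arm_role, r.offset5, r.offset3,
         r.n_mismatches, r.mismatch_positions, r.category, r.multi_locus)
        for r in table.records
    }


class TestAlignment:
    def test_exact_subsequence_placement(self, toy_locus):
        read = toy_locus.seq[10:30]
        placements = align_read_to_precursor(read, toy_locus, max_mismatches=1)
        assert placements[0] == Placement(start=10, end=30, n_mismatches=0)

    def test_single_mismatch_and_zero_budget(self, toy_locus):
        read = mutate(toy_locus.seq[10:30], 4)
        placements = align_read_to_precursor(read, toy_locus, max_mismatches=1)
        best = placements[0]
        assert (best.start, best.n_mismatches, best.mismatch_positions) == (10, 1, (14,))
        assert align_read_to_precursor(read, toy_locus, max_mismatches=0) == []

    def test_read_longer_than_precursor(self, toy_locus):
        assert align_read_to_precursor("A" * 100, toy_locus, 1) == []

    def test_matches_brute_force_on_random_pairs(self, toy_locus, rng):
        """200 random reads against the hairpin: placement sets must
        equal the direct enumeration oracle exactly."""
        bases = np.array(list("ACGU"))
        for _ in range(200):
            n = int(rng.integers(15, 30))
            if rng.random() < 0.5:
                start = int(rng.integers(0, len(toy_locus.seq) - n + 1))
                read = toy_locus.seq[start:start + n]
                for _ in range(int(rng.integers(0, 3))):
                    read = mutate(read, int(rng.integers(0, n)))
            else:
                read = "".join(bases[rng.integers(0, 4, size=n)])
            mm = int(rng.integers(0, 3))
            got = [
                (p.start, p.end, p.n_mismatches, p.mismatch_positions)
                for p in align_read_to_precursor(read, toy_locus, mm)
            ]
            assert got == _oracles.oracle_placements(read, toy_locus, mm)


class TestArmAssignment:
    def test_exact_mature_window(self, toy_locus):
        m = toy_locus.mature
        pl = Placement(start=m.start, end=m.end, n_mismatches=0)
        assert assign_to_arm(pl, toy_locus, IsomirThresholds()) == ArmAssignment(
            "mature", 0, 0
        )

    def test_extension_offsets(self, toy_locus):
        m = toy_locus.mature
        pl = Placement(start=m.start - 1, end=m.end + 2, n_mismatches=0)
        res = assign_to_arm(pl, toy_locus, IsomirThresholds())
        assert (res.arm_role, res.offset5, res.offset3) == ("mature", -1, 2)

    def test_offset5_beyond_box_rejected(self, toy_locus):
        m = toy_locus.mature
        pl = Placement(start=m.start + 3, end=m.end + 3, n_mismatches=0)
        assert assign_to_arm(pl, toy_locus, IsomirThresholds()) == OFFSET_OUT_OF_RANGE

    def test_star_window_attribution(self, toy_locus):
        s = toy_locus.star
        pl = Placement(start=s.start + 1, end=s.end, n_mismatches=0)
        res = assign_to_arm(pl, toy_locus, IsomirThresholds())
        assert (res.arm_role, res.offset5, res.offset3) == ("star", 1, 0)

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            IsomirThresholds(max_mismatches=-1)


class TestAssignmentTable:
    def test_canonical_star_isomir_partition(self, toy_locus):
        mature = toy_locus.mature_seq
        star = toy_locus.arm_seq("star")
        ext = toy_locus.seq[toy_locus.mature.start:toy_locus.mature.end + 1]
        collapsed = [
            CollapsedRead(mature, 5), CollapsedRead(star, 2), CollapsedRead(ext, 3)
        ]
        table = build_assignment_table(collapsed, [toy_locus])
        by_cat = {r.category: r for r in table.records}
        assert by_cat[CANONICAL_MATURE].count == 5
        assert by_cat[CANONICAL_STAR].count == 2
        iso = by_cat[ISOMIR]
        assert (iso.count, iso.offset5, iso.offset3, iso.n_mismatches) == (3, 0, 1, 0)

    def test_identical_loci_each_receive_full_count(self, toy_locus):
        """A read matching two (identical) precursor loci is reported at
        both with the full count and the multi-locus flag, while the
        library-level unique total counts it once."""
        twin = type(toy_locus)(
            locus_id="TOY_001.1_2", seq=toy_locus.seq,
            mature=toy_locus.mature, star=toy_locus.star,
        )
        collapsed = [CollapsedRead(toy_locus.mature_seq, 7)]
        table = build_assignment_table(collapsed, [toy_locus, twin])
        assert len(table.records) == 2
        assert all(r.count == 7 and r.multi_locus for r in table.records)
        assert {r.locus_id for r in table.records} == {"TOY_001.1_1", "TOY_001.1_2"}
        assert table.unique_assigned_count() == 7

    def test_unmatched_read_reason(self, toy_locus):
        table = build_assignment_table(
            [CollapsedRead("ACGUACGUACGUACGUACGU", 4)], [toy_locus]
        )
        assert not table.records
        (un,) = table.unassigned
        assert (un.count, un.reason) == (4, NO_ALIGNMENT)

    def test_duplicate_collapsed_input_rejected(self, toy_locus):
        with pytest.raises(ValidationError):
            build_assignment_table(
                [CollapsedRead("A" * 20, 1), CollapsedRead("A" * 20, 2)], [toy_locus]
            )

    def test_determinism_byte_identical(self, small_library):
        from isomirkit.sequence_io import collapse

        collapsed = collapse(small_library.reads)
        t1 = build_assignment_table(collapsed, small_library.loci)
        t2 = build_assignment_table(collapsed, small_library.loci)
        assert t1.to_dataframe().to_csv() == t2.to_dataframe().to_csv()

    def test_threshold_box_holds_on_simulated_runs(self, small_library):
        from isomirkit.sequence_io import collapse

        thresholds = IsomirThresholds()
        table = build_assignment_table(
            collapse(small_library.reads), small_library.loci, thresholds
        )
        assert table.records
        for r in table.records:
            assert abs(r.offset5) <= thresholds.max_offset5
            assert abs(r.offset3) <= thresholds.max_offset3
            assert r.n_mismatches <= thresholds.max_mismatches
            canonical = r.offset5 == 0 and r.offset3 == 0 and r.n_mismatches == 0
            if r.category in (CANONICAL_MATURE, CANONICAL_STAR):
                assert canonical
            else:
                assert not canonical

    def test_canonical_exclusivity(self, small_library):
        """A sequence canonical at an arm never doubles as an isomiR at
        the same arm."""
        from isomirkit.sequence_io import collapse

        table = build_assignment_table(collapse(small_library.reads), small_library.loci)
        canonical_keys = {
            (r.locus_id, r.arm_role, r.seq)
            for r in table.records
            if r.category in (CANONICAL_MATURE, CANONICAL_STAR)
        }
        isomir_keys = {
            (r.locus_id, r.arm_role, r.seq)
            for r in table.records
            if r.category == ISOMIR
        }
        assert not canonical_keys & isomir_keys


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_engine_equals_oracle_on_random_instances(seed):
    """Property check of the whole assignment against the exhaustive
    oracle on small random instances (the acceptance suite runs the
    larger campaign)."""
    from isomirkit.sequence_io import collapse
    from isomirkit.synthetic_data import SimulationConfig, generate_loci, generate_reads

    cfg = SimulationConfig(
        n_loci=3, total_reads=60, seed=seed, background_fraction=0.3,
        out_of_box_fraction=0.15,
    )
    loci = generate_loci(cfg)
    reads, _ = generate_reads(cfg, loci)
    collapsed = collapse(reads)
    thresholds = IsomirThresholds()
    table = build_assignment_table(collapsed, loci, thresholds)
    oracle_records, oracle_unassigned = _oracles.oracle_assignment(
        collapsed, loci, thresholds
    )
    assert records_as_tuples(table) == oracle_records
    assert {(u.seq, u.count, u.reason) for u in table.unassigned} == oracle_unassigned
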