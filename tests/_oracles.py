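"""Independent brute-force oracles used to validate the engine.

These restate the assignment and overlap rules with direct character
comparison and exhaustive enumeration, sharing no code with the
implementation paths they check.
"""

from __future__ import annotations

from isomirkit.isomir_engine import (
    IsomirThresholds,
    NO_ALIGNMENT,
    OFFSET_OUT_OF_RANGE,
    TOO_MANY_MISMATCHES,
)


def oracle_placements(read_seq: str, locus, max_mismatches: int):
    """Every start position, direct character comparison."""
    out = []
    for start in range(len(locus.seq) - len(read_seq) + 1):
        window = locus.seq[start:start + len(read_seq)]
        mism = tuple(
            start + i for i in range(len(read_seq)) if read_seq[i] != window[i]
        )
        if len(mism) <= max_mismatches:
            out.append((start, start + len(read_seq), len(mism), mism))
    out.sort(key=lambda p: (p[2], abs(p[0] - locus.mature.start), p[0]))
    return out


def _oracle_arm(start: int, end: int, locus, thresholds: IsomirThresholds):
    arm = min(
        locus.arms(),
        key=lambda a: (abs(start - a.start), 0 if a.role == "mature" else 1),
    )
    o5 = start - arm.start
    o3 = end - arm.end
    if abs(o5) > thresholds.max_offset5 or abs(o3) > thresholds.max_offset3:
        return None
    return arm.role, o5, o3


def oracle_assignment(collapsed, loci, thresholds: IsomirThresholds):
    """Exhaustive re-derivation of the assignment table.

    Returns (records, unassigned): records as a set of tuples
    (seq, count, locus_id, arm_role, offset5, offset3, n_mismatches,
    mismatch_positions, category, multi_locus); unassigned as a set of
    (seq, count, reason).
    """
    records = set()
    unassigned = set()
    for c in collapsed:
        per_locus = []
        saw_offset_reject = False
        saw_over_budget = False
        for locus in loci:
            best = None
            locus_offset_reject = False
            for start in range(len(locus.seq) - len(c.seq) + 1):
                window = locus.seq[start:start + len(c.seq)]
                mism = tuple(
                    start + i for i in range(len(c.seq)) if c.seq[i] != window[i]
                )
                if len(mism) > thresholds.max_mismatches:
                    if len(mism) == thresholds.max_mismatches + 1:
                        saw_over_budget = True
                    continue
                end = start + len(c.seq)
                res = _oracle_arm(start, end, locus, thresholds)
                if res is None:
                    locus_offset_reject = True
                    continue
                role, o5, o3 = res
                key = (len(mism), abs(o5) + abs(o3), o5, start)
                if best is None or key < best[0]:
                    best = (key, start, end, mism, role, o5, o3)
            if best is not None:
                per_locus.append((locus, best))
            elif locus_offset_reject:
                saw_offset_reject = True

        if per_locus:
            multi = len(per_locus) > 1
            for locus, (_, start, end, mism, role, o5, o3) in per_locus:
                if o5 == 0 and o3 == 0 and not mism:
                    cat = "canonical_mature" if role == "mature" else "canonical_star"
                else:
                    cat = "isomir"
                records.add(
                    (c.seq, c.count, locus.locus_id, role, o5, o3,
                     len(mism), mism, cat, multi)
                )
        else:
            saw_alignment = False  # any in-budget placement would have been
            # either accepted or offset-rejected; reaching here with no
            # offset reject means there was none within budget
            if saw_offset_reject:
                reason = OFFSET_OUT_OF_RANGE
            elif saw_over_budget and not saw_alignment:
                reason = TOO_MANY_MISMATCHES
            else:
                reason = NO_ALIGNMENT
            unassigned.add((c.seq, c.count, reason))
    return records, unassigned


def oracle_overlap(a: str, b: str, min_overlap: int = 15):
    """Exhaustive ungapped overlap scan, returning the minimum mismatch
    count and its overlap length (ties toward larger overlap, smaller
    |shift|, smaller shift)."""
    best = None
    for shift in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        lo, hi = max(0, shift), min(len(a), shift + len(b))
        ov = hi - lo
        if ov < min_overlap:
            continue
        mm = sum(1 for i in range(lo, hi) if a[i] != b[i - shift])
        key = (mm, -ov, abs(shift), shift)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[0], -best[1]
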