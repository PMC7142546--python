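"""Assignment of collapsed reads to precursor arms and isomiR calling.

A read is assigned to a precursor locus when it matches the hairpin
sequence end-to-end (templated, sense strand, no indels) with a small
Hamming mismatch budget.  Relative to the annotated arm window the read
then has a 5' offset (read start minus arm start; negative = extension
upstream) and a 3' offset (read end minus arm end; positive = extension
downstream).  Retention thresholds follow the standard isomiR
definition used for this analysis:

* at most ``max_mismatches`` substitutions (default 1),
* |5' offset| <= ``max_offset5`` (default 2 nt),
* |3' offset| <= ``max_offset3`` (default 5 nt).

A read reproducing the annotated mature window exactly (offsets 0/0,
no mismatch) is the *canonical mature* sequence; likewise for the star
arm; everything else retained is an *isomiR*.  Reads matching several
loci are reported at every locus with a ``multi_locus`` flag; library
totals de-duplicate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._alphabet import hamming
from .annotation_model import ArmAnnotation, PrecursorLocus
from .errors import ValidationError
from .sequence_io import CollapsedRead

# rejection reason codes
NO_ALIGNMENT = "no_alignment"
OFFSET_OUT_OF_RANGE = "offset_out_of_range"
TOO_MANY_MISMATCHES = "too_many_mismatches"
AMBIGUOUS_RESOLVED_ELSEWHERE = "ambiguous_resolved_elsewhere"

CANONICAL_MATURE = "canonical_mature"
CANONICAL_STAR = "canonical_star"
ISOMIR = "isomir"

ISOMIR_TSV_COLUMNS = [
    "locus_id", "arm", "seq", "count", "rpm", "offset5", "offset3",
    "n_mismatches", "mismatch_positions", "category", "multi_locus",
]


@dataclass(frozen=True, slots=True)
class IsomirThresholds:
    """Retention box for isomiR calling (defaults: 1 mismatch, ±2 nt at
    the 5' end, ±5 nt at the 3' end)."""

    max_mismatches: int = 1
    max_offset5: int = 2
    max_offset3: int = 5

    def __post_init__(self):
        if min(self.max_mismatches, self.max_offset5, self.max_offset3) < 0:
            raise ValidationError("thresholds must be non-negative")


@dataclass(frozen=True, slots=True)
class Placement:
    """One templated placement of a read on a precursor: [start, end)
    precursor window, mismatch count and mismatch positions (precursor
    offsets)."""

    start: int
    end: int
    n_mismatches: int
    mismatch_positions: tuple[int, ...] = ()


@dataclass(frozen=True, slots=True)
class IsomirRecord:
    seq: str
    count: int
    locus_id: str
    arm_role: str
    offset5: int
    offset3: int
    n_mismatches: int
    mismatch_positions: tuple[int, ...]
    category: str
    multi_locus: bool = False


@dataclass(frozen=True, slots=True)
class UnassignedRead:
    seq: str
    count: int
    reason: str


@dataclass(slots=True)
class ArmAssignmentTable:
    """Retained read-to-arm assignments plus the unassigned remainder.

    ``records`` may contain the same sequence at several loci
    (multi-locus reads); :meth:`unique_assigned_count` counts each
    distinct sequence once for library-level accounting.
    """

    locus_ids: list[str]
    records: list[IsomirRecord] = field(default_factory=list)
    unassigned: list[UnassignedRead] = field(default_factory=list)

    def records_for(self, locus_id: str, arm_role: str | None = None) -> list[IsomirRecord]:
        return [
            r for r in self.records
            if r.locus_id == locus_id and (arm_role is None or r.arm_role == arm_role)
        ]

    def unique_assigned_count(self) -> int:
        seen: dict[str, int] = {}
        for r in self.records:
            seen[r.seq] = r.count
        return sum(seen.values())

    def unassigned_count(self) -> int:
        return sum(u.count for u in self.unassigned)

    def to_dataframe(self, mapped_reads_total: int | None = None) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rpm = (
                r.count / mapped_reads_total * 1e6
                if mapped_reads_total else float("nan")
            )
            rows.append({
                "locus_id": r.locus_id, "arm": r.arm_role, "seq": r.seq,
                "count": r.count, "rpm": rpm,
                "offset5": r.offset5, "offset3": r.offset3,
                "n_mismatches": r.n_mismatches,
                "mismatch_positions": ",".join(map(str, r.mismatch_positions)),
                "category": r.category, "multi_locus": r.multi_locus,
            })
        return pd.DataFrame(rows, columns=ISOMIR_TSV_COLUMNS)

    def write_tsv(self, path: str | Path, mapped_reads_total: int | None = None) -> None:
        self.to_dataframe(mapped_reads_total).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_read_to_precursor(
    read_seq: str, precursor: PrecursorLocus, max_mismatches: int
) -> list[Placement]:
    """All templated placements of ``read_seq`` on the precursor with
    Hamming distance <= ``max_mismatches``, at every sliding position
    that keeps the read fully inside the hairpin (sense strand only).

    Sorted by mismatch count, then by distance of the placement start
    from the annotated mature start (then by start, for determinism).
    """
    p = np.frombuffer(precursor.seq.encode(), dtype=np.uint8)
    r = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    if len(r) == 0 or len(r) > len(p):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(p, len(r))
    neq = windows != r
    mm = neq.sum(axis=1)
    placements = []
    for start in np.nonzero(mm <= max_mismatches)[0]:
        positions = tuple(int(j) + int(start) for j in np.nonzero(neq[start])[0])
        placements.append(
            Placement(
                start=int(start), end=int(start) + len(r),
                n_mismatches=int(mm[start]), mismatch_positions=positions,
            )
        )
    anchor = precursor.mature.start
    placements.sort(key=lambda pl: (pl.n_mismatches, abs(pl.start - anchor), pl.start))
    return placements


@dataclass(frozen=True, slots=True)
class ArmAssignment:
    arm_role: str
    offset5: int
    offset3: int


def assign_to_arm(
    placement: Placement, locus: PrecursorLocus, thresholds: IsomirThresholds
) -> ArmAssignment | str:
    """Attribute a placement to the arm whose annotated 5' start is
    nearest the read start (mature wins ties), then accept it iff the
    5'/3' offsets fall inside the retention box.  Returns an
    :class:`ArmAssignment` or a rejection reason string.
    """
    arm: ArmAnnotation = min(
        locus.arms(),
        key=lambda a: (abs(placement.start - a.start), 0 if a.role == "mature" else 1),
    )
    offset5 = placement.start - arm.start
    offset3 = placement.end - arm.end
    if abs(offset5) > thresholds.max_offset5 or abs(offset3) > thresholds.max_offset3:
        return OFFSET_OUT_OF_RANGE
    return ArmAssignment(arm_role=arm.role, offset5=offset5, offset3=offset3)


def _categorize(arm_role: str, offset5: int, offset3: int, n_mismatches: int) -> str:
    if offset5 == 0 and offset3 == 0 and n_mismatches == 0:
        return CANONICAL_MATURE if arm_role == "mature" else CANONICAL_STAR
    return ISOMIR


# ---------------------------------------------------------------------------
# pigeonhole substring index (internal speed-up)
#
# For a Hamming budget m, a read split into m+1 chunks must match one
# chunk exactly; an exact-substring index over all precursors therefore
# yields a complete candidate list that is verified directly.  Results
# are identical to the exhaustive sliding scan (property-tested).
# ---------------------------------------------------------------------------

class _PrecursorIndex:
    def __init__(self, loci: Sequence[PrecursorLocus]):
        self.loci = list(loci)
        self._index: dict[str, list[tuple[int, int]]] = {}
        for li, locus in enumerate(self.loci):
            seq = locus.seq
            n = len(seq)
            for length in range(5, n + 1):
                for start in range(n - length + 1):
                    self._index.setdefault(seq[start:start + length], []).append((li, start))

    def placements(self, read_seq: str, max_mismatches: int) -> dict[int, list[Placement]]:
        """Per-locus-index placement lists with Hamming <= budget."""
        L = len(read_seq)
        n_chunks = max_mismatches + 1
        if L < 5 * n_chunks:
            # chunks would be shorter than the indexed minimum; fall back
            # to the exhaustive scan for completeness
            out_full: dict[int, list[Placement]] = {}
            for li, locus in enumerate(self.loci):
                pls = align_read_to_precursor(read_seq, locus, max_mismatches)
                if pls:
                    out_full[li] = pls
            return out_full
        bounds = [round(i * L / n_chunks) for i in range(n_chunks + 1)]
        candidates: set[tuple[int, int]] = set()
        for i in range(n_chunks):
            lo, hi = bounds[i], bounds[i + 1]
            if hi - lo < 1:
                continue
            for li, start in self._index.get(read_seq[lo:hi], ()):
                read_start = start - lo
                if read_start >= 0 and read_start + L <= len(self.loci[li].seq):
                    candidates.add((li, read_start))
        out: dict[int, list[Placement]] = {}
        for li, read_start in candidates:
            prec = self.loci[li].seq
            window = prec[read_start:read_start + L]
            d = hamming(read_seq, window, limit=max_mismatches)
            if d <= max_mismatches:
                positions = tuple(
                    read_start + j for j, (x, y) in enumerate(zip(read_seq, window)) if x != y
                )
                out.setdefault(li, []).append(
                    Placement(start=read_start, end=read_start + L,
                              n_mismatches=d, mismatch_positions=positions)
                )
        for li, pls in out.items():
            anchor = self.loci[li].mature.start
            pls.sort(key=lambda pl: (pl.n_mismatches, abs(pl.start - anchor), pl.start))
        return out


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_assignment_table(
    collapsed: Iterable[CollapsedRead],
    loci: Sequence[PrecursorLocus],
    thresholds: IsomirThresholds = IsomirThresholds(),
) -> ArmAssignmentTable:
    """Assign every collapsed read to at most one arm per matching locus.

    Per locus the best acceptable placement wins: fewest mismatches,
    then smallest |offset5| + |offset3|, then smallest offset5 (final
    tie on placement start).  Reads matching several loci appear at
    each with ``multi_locus`` set.  Unassigned reads carry a reason:
    ``offset_out_of_range`` if some placement existed but fell outside
    the retention box, ``too_many_mismatches`` if a placement exists
    only one mismatch over budget, ``no_alignment`` otherwise.
    """
    collapsed = list(collapsed)
    seen: set[str] = set()
    for c in collapsed:
        if c.seq in seen:
            raise ValidationError(f"duplicate sequence in collapsed input: {c.seq}")
        seen.add(c.seq)

    index = _PrecursorIndex(loci)
    diagnostic_budget = thresholds.max_mismatches + 1

    table = ArmAssignmentTable(locus_ids=[p.locus_id for p in loci])
    for c in collapsed:
        per_locus = index.placements(c.seq, diagnostic_budget)
        assignments: list[tuple[int, Placement, ArmAssignment]] = []
        saw_offset_reject = False
        saw_over_budget = False
        saw_alignment = False
        for li, placements in per_locus.items():
            locus = loci[li]
            best: tuple | None = None
            locus_offset_reject = False
            for pl in placements:
                if pl.n_mismatches > thresholds.max_mismatches:
                    saw_over_budget = True
                    continue
                saw_alignment = True
                res = assign_to_arm(pl, locus, thresholds)
                if isinstance(res, str):
                    locus_offset_reject = True
                    continue
                key = (
                    pl.n_mismatches,
                    abs(res.offset5) + abs(res.offset3),
                    res.offset5,
                    pl.start,
                )
                if best is None or key < best[0]:
                    best = (key, pl, res)
            if best is not None:
                assignments.append((li, best[1], best[2]))
            elif locus_offset_reject:
                saw_offset_reject = True

        if assignments:
            multi = len(assignments) > 1
            for li, pl, res in sorted(assignments, key=lambda t: t[0]):
                table.records.append(
                    IsomirRecord(
                        seq=c.seq, count=c.count,
                        locus_id=loci[li].locus_id,
                        arm_role=res.arm_role,
                        offset5=res.offset5, offset3=res.offset3,
                        n_mismatches=pl.n_mismatches,
                        mismatch_positions=pl.mismatch_positions,
                        category=_categorize(
                            res.arm_role, res.offset5, res.offset3, pl.n_mismatches
                        ),
                        multi_locus=multi,
                    )
                )
        else:
            if saw_offset_reject:
                reason = OFFSET_OUT_OF_RANGE
            elif saw_over_budget and not saw_alignment:
                reason = TOO_MANY_MISMATCHES
            else:
                reason = NO_ALIGNMENT
            table.unassigned.append(UnassignedRead(seq=c.seq, count=c.count, reason=reason))
    return table
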