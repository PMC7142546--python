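"""RPM normalization, per-arm expression profiles, IDI/IAI, and read
category summaries.

Normalized expression is reads per million (RPM): a read count scaled
by 1e6 over the number of reads mapping to the reference genome (the
denominator is an input; a convenience exact-substring matcher can
compute it for synthetic data).

Two indices summarize how prone a miRNA locus is to producing isomiRs,
both using the mature-arm RPM as denominator:

* IDI (isomiR diversity index) = number of distinct isomiR sequences
  of the miRNA / mature RPM,
* IAI (isomiR abundance index) = total isomiR RPM (excluding the
  mature sequence itself) / mature RPM.

Both are undefined (NaN, written as ``NA``) when the mature RPM is 0.
Star reads and star-arm isomiRs are excluded from the mature arm's
indices and reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .isomir_engine import (
    ArmAssignmentTable,
    CANONICAL_MATURE,
    CANONICAL_STAR,
    ISOMIR,
)
from .mirna_classifier import ClassificationResult
from .sequence_io import CollapsedRead

PROFILE_TSV_COLUMNS = [
    "provisional_name", "locus_id", "mature_rpm", "star_rpm", "combined_rpm",
    "n_distinct_isomirs", "isomir_rpm_total", "idi", "iai",
]

DEFAULT_CATEGORY_ORDER = (
    "tRNA", "rRNA", "miRNA", "repetitive_element",
    "other_families", "other_genome", "unassigned",
)


@dataclass(frozen=True, slots=True)
class NormalizationContext:
    """RPM denominator: total reads mapping to the reference genome."""

    mapped_reads_total: int

    def __post_init__(self):
        if self.mapped_reads_total < 1:
            raise ValidationError(
                f"mapped_reads_total must be >= 1, got {self.mapped_reads_total}"
            )


def rpm(count: float, ctx: NormalizationContext) -> float:
    """count / mapped_reads_total * 1e6 (linear in count)."""
    if count < 0:
        raise ValidationError(f"negative count {count}")
    return count / ctx.mapped_reads_total * 1e6


def compute_idi(n_distinct_isomirs: int, mature_rpm: float) -> float:
    """IsomiR diversity index; NaN when the mature RPM is zero."""
    if n_distinct_isomirs < 0 or mature_rpm < 0:
        raise ValidationError("IDI inputs must be non-negative")
    if mature_rpm == 0:
        return math.nan
    return n_distinct_isomirs / mature_rpm


def compute_iai(isomir_rpm_total: float, mature_rpm: float) -> float:
    """IsomiR abundance index; NaN when the mature RPM is zero."""
    if isomir_rpm_total < 0 or mature_rpm < 0:
        raise ValidationError("IAI inputs must be non-negative")
    if mature_rpm == 0:
        return math.nan
    return isomir_rpm_total / mature_rpm


def report_round(x: float, ndigits: int = 2) -> float:
    """Round-half-even to ``ndigits`` decimals for reporting (full
    precision is kept internally); NaN passes through."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# per-arm profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ArmProfile:
    """Quantification of one mature arm: canonical mature and star RPM,
    the mature-arm isomiR complement, and the two indices."""

    provisional_name: str
    locus_id: str
    mature_rpm: float
    star_rpm: float
    combined_rpm: float  # mature + mature-arm isomiRs, the merged count
    n_distinct_isomirs: int
    isomir_rpm_total: float
    idi: float
    iai: float


def build_profiles(
    table: ArmAssignmentTable,
    classification: Sequence[ClassificationResult] | Mapping[str, ClassificationResult],
    ctx: NormalizationContext,
) -> list[ArmProfile]:
    """One profile per locus mature arm, sorted by descending mature RPM
    (ties broken by provisional name).

    The locus sets of the assignment table and the classification must
    agree.  ``combined_rpm`` merges mature and mature-arm isomiR reads,
    mirroring quantifiers that do not separate the two.
    """
    if not isinstance(classification, Mapping):
        classification = {c.locus_id: c for c in classification}
    table_loci = set(table.locus_ids)
    class_loci = set(classification)
    if table_loci != class_loci:
        raise ValidationError(
            f"locus sets differ between assignment table and classification: "
            f"only in table {sorted(table_loci - class_loci)[:5]}, "
            f"only in classification {sorted(class_loci - table_loci)[:5]}"
        )

    profiles = []
    for locus_id in table.locus_ids:
        mature_count = star_count = isomir_count = 0
        n_distinct = 0
        for rec in table.records_for(locus_id):
            if rec.category == CANONICAL_MATURE:
                mature_count += rec.count
            elif rec.category == CANONICAL_STAR:
                star_count += rec.count
            elif rec.category == ISOMIR and rec.arm_role == "mature":
                isomir_count += rec.count
                n_distinct += 1
        mature_rpm = rpm(mature_count, ctx)
        isomir_rpm_total = rpm(isomir_count, ctx)
        profiles.append(
            ArmProfile(
                provisional_name=classification[locus_id].provisional_name,
                locus_id=locus_id,
                mature_rpm=mature_rpm,
                star_rpm=rpm(star_count, ctx),
                combined_rpm=mature_rpm + isomir_rpm_total,
                n_distinct_isomirs=n_distinct,
                isomir_rpm_total=isomir_rpm_total,
                idi=compute_idi(n_distinct, mature_rpm),
                iai=compute_iai(isomir_rpm_total, mature_rpm),
            )
        )
    profiles.sort(key=lambda p: (-p.mature_rpm, p.provisional_name))
    return profiles


def profiles_dataframe(profiles: Iterable[ArmProfile]) -> pd.DataFrame:
    rows = [
        {
            "provisional_name": p.provisional_name, "locus_id": p.locus_id,
            "mature_rpm": p.mature_rpm, "star_rpm": p.star_rpm,
            "combined_rpm": p.combined_rpm,
            "n_distinct_isomirs": p.n_distinct_isomirs,
            "isomir_rpm_total": p.isomir_rpm_total,
            "idi": p.idi, "iai": p.iai,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=PROFILE_TSV_COLUMNS)


def write_profiles_tsv(profiles: Iterable[ArmProfile], path: str | Path) -> None:
    profiles_dataframe(profiles).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# category bookkeeping
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class CategorySummary:
    """Redundant read counts per RNA category, with a per-length
    breakdown.  Each read lands in exactly one category (first match in
    priority order wins)."""

    counts: dict[str, int]
    per_length: pd.DataFrame  # index: length, columns: categories
    total: int

    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.total for k, v in self.counts.items()}

    def to_dataframe(self) -> pd.DataFrame:
        fr = self.fractions()
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [fr[k] for k in self.counts],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_length_tsv(self, path: str | Path) -> None:
        self.per_length.to_csv(path, sep="\t")


def categorize_reads(
    collapsed: Iterable[CollapsedRead],
    category_references: Mapping[str, Iterable[str]],
    order: Sequence[str] | None = None,
) -> CategorySummary:
    """Assign each unique read to the first category (in priority order)
    whose reference set contains it as an exact substring; the remainder
    is ``unassigned``.

    This reproduces the category bookkeeping of an Rfam-style triage
    with exact membership, not homology search.
    """
    if order is None:
        order = [k for k in DEFAULT_CATEGORY_ORDER if k in category_references]
        order += [k for k in category_references if k not in order]
    # concatenate each category's references with a separator outside the
    # alphabet so Python's C-level substring search does the matching
    haystacks = {
        name: "#" + "#".join(category_references[name]) + "#" for name in order
    }
    categories = list(order) + ["unassigned"]
    counts = {name: 0 for name in categories}
    per_length: dict[int, dict[str, int]] = {}
    total = 0
    for c in collapsed:
        hit = "unassigned"
        for name in order:
            if c.seq in haystacks[name]:
                hit = name
                break
        counts[hit] += c.count
        total += c.count
        per_length.setdefault(len(c.seq), {})[hit] = (
            per_length.get(len(c.seq), {}).get(hit, 0) + c.count
        )
    pl = (
        pd.DataFrame.from_dict(per_length, orient="index")
        .reindex(columns=categories)
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    pl.index.name = "length"
    return CategorySummary(counts=counts, per_length=pl, total=total)


def count_mapped_reads(
    collapsed: Iterable[CollapsedRead], reference_seqs: Iterable[str]
) -> int:
    """Convenience exact-substring matcher: redundant count of reads
    occurring verbatim in any reference sequence.  Stands in for a
    genome aligner when an exact denominator is wanted for synthetic
    libraries."""
    haystack = "#" + "#".join(reference_seqs) + "#"
    return sum(c.count for c in collapsed if c.seq in haystack)
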