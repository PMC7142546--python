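"""Canonical/novel classification of mature miRNAs and provisional naming.

A locus's mature sequence is compared against every reference mature
miRNA with an ungapped overlap scan: across all relative shifts with at
least ``min_overlap`` aligned bases (default 15), the mismatch count
inside the overlap is minimized; overhanging bases on either side cost
nothing, so length differences between candidate and reference are
ignored.  A candidate within ``max_mismatches`` (default 2) of any
reference is *canonical*; otherwise it is *novel*.

Provisional names carry a species prefix (default ``asp``):

* canonical loci inherit the reference's core name with the arm side of
  the annotated mature strand, e.g. a match to ``dme-bantam-3p`` whose
  mature arm is 3p becomes ``asp-bantam-3p``;
* novel loci get a numeric identifier derived from the trailing index
  of the locus id (index 13195 -> ``miR-131950``), chosen to stay clear
  of existing miRNA family numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_model import MatureReference, PrecursorLocus, seed_of
from .errors import ValidationError

CANONICAL = "canonical"
NOVEL = "novel"

CLASSIFICATION_TSV_COLUMNS = [
    "locus_id", "provisional_name", "status", "best_match",
    "best_mismatches", "overlap_len", "seed_match",
]

_SIDE_SUFFIX = re.compile(r"-(5p|3p)$")
_LOCUS_INDEX = re.compile(r"_(\d+)$")


@dataclass(frozen=True, slots=True)
class OverlapResult:
    """Best ungapped overlap between two sequences: minimum mismatch
    count, the overlap length achieving it, and the shift (reference
    start position relative to candidate start)."""

    mismatches: int
    overlap_len: int
    shift: int


@dataclass(slots=True)
class ClassificationResult:
    locus_id: str
    mature_seq: str
    status: str
    best_match: str | None = None
    best_mismatches: int | None = None
    overlap_len: int | None = None
    seed_match: bool = False
    provisional_name: str = ""


def overlap_mismatches(
    candidate_seq: str, reference_seq: str, min_overlap: int = 15
) -> OverlapResult | None:
    """Minimum mismatch count over all ungapped overlaps of length >=
    ``min_overlap``; ``None`` if no such overlap exists.

    Ties on mismatches are resolved toward the larger overlap, then the
    smaller |shift|, then the smaller shift, so the result is unique.
    """
    a, b = candidate_seq, reference_seq
    if min_overlap < 1:
        raise ValidationError("min_overlap must be >= 1")
    if len(a) < min_overlap or len(b) < min_overlap:
        return None
    best: tuple[int, int, int, int] | None = None  # (mm, -ov, |shift|, shift)
    result: OverlapResult | None = None
    for shift in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        a_lo, a_hi = max(0, shift), min(len(a), shift + len(b))
        ov = a_hi - a_lo
        if ov < min_overlap:
            continue
        mm = sum(1 for i in range(a_lo, a_hi) if a[i] != b[i - shift])
        key = (mm, -ov, abs(shift), shift)
        if best is None or key < best:
            best = key
            result = OverlapResult(mismatches=mm, overlap_len=ov, shift=shift)
    return result


def classify(
    mature_seq: str,
    references: Mapping[str, MatureReference] | Iterable[MatureReference],
    max_mismatches: int = 2,
    min_overlap: int = 15,
    locus_id: str = "",
) -> ClassificationResult:
    """Classify a mature sequence as canonical (<= ``max_mismatches``
    overlap mismatches against some reference) or novel.

    The best match minimizes mismatches; ties prefer the larger
    overlap, then the lexicographically smaller reference name.
    """
    if isinstance(references, Mapping):
        references = references.values()
    best_name = None
    best_key: tuple[int, int, str] | None = None
    best_res: OverlapResult | None = None
    for ref in references:
        res = overlap_mismatches(mature_seq, ref.seq, min_overlap=min_overlap)
        if res is None:
            continue
        key = (res.mismatches, -res.overlap_len, ref.name)
        if best_key is None or key < best_key:
            best_key, best_name, best_res = key, ref, res

    if best_res is not None and best_res.mismatches <= max_mismatches:
        seed_match = (
            len(mature_seq) >= 8 and seed_of(mature_seq) == best_name.seed
        )
        return ClassificationResult(
            locus_id=locus_id, mature_seq=mature_seq, status=CANONICAL,
            best_match=best_name.name, best_mismatches=best_res.mismatches,
            overlap_len=best_res.overlap_len, seed_match=seed_match,
        )
    return ClassificationResult(
        locus_id=locus_id, mature_seq=mature_seq, status=NOVEL,
        best_match=best_name.name if best_name is not None else None,
        best_mismatches=best_res.mismatches if best_res is not None else None,
        overlap_len=best_res.overlap_len if best_res is not None else None,
    )


def _core_name(reference_name: str) -> str:
    """Strip the species code and any -5p/-3p suffix from a miRBase-style
    name: ``dme-miR-276a-3p`` -> ``miR-276a``; ``api-mir-8`` -> ``mir-8``."""
    name = _SIDE_SUFFIX.sub("", reference_name)
    parts = name.split("-", 1)
    return parts[1] if len(parts) == 2 else name


def _novel_numeric_id(locus_id: str) -> str:
    m = _LOCUS_INDEX.search(locus_id)
    if m:
        return str(int(m.group(1)) * 10)
    # no numeric tail: fall back to a sanitized locus id
    return re.sub(r"[^A-Za-z0-9]", "", locus_id)


def assign_name(
    result: ClassificationResult,
    locus: PrecursorLocus,
    used_names: set[str],
    prefix: str = "asp",
) -> str:
    """Derive the provisional name for a classified locus and register it
    in ``used_names`` (collisions get a deterministic ``-2``, ``-3``...
    suffix).  The arm side comes from the locus's mature annotation."""
    side = locus.mature.side
    if result.status == CANONICAL:
        base = f"{prefix}-{_core_name(result.best_match)}-{side}"
    else:
        base = f"{prefix}-miR-{_novel_numeric_id(locus.locus_id)}-{side}"
    name = base
    k = 2
    while name in used_names:
        name = f"{base}-{k}"
        k += 1
    used_names.add(name)
    result.provisional_name = name
    return name


def classify_loci(
    loci: Sequence[PrecursorLocus],
    references: Mapping[str, MatureReference],
    max_mismatches: int = 2,
    min_overlap: int = 15,
    prefix: str = "asp",
) -> list[ClassificationResult]:
    """Classify and name every locus's mature sequence, in input order."""
    used: set[str] = set()
    results = []
    for locus in loci:
        res = classify(
            locus.mature_seq, references,
            max_mismatches=max_mismatches, min_overlap=min_overlap,
            locus_id=locus.locus_id,
        )
        assign_name(res, locus, used, prefix=prefix)
        results.append(res)
    return results


def classification_dataframe(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": r.locus_id, "provisional_name": r.provisional_name,
            "status": r.status, "best_match": r.best_match or "",
            "best_mismatches": r.best_mismatches if r.best_mismatches is not None else "",
            "overlap_len": r.overlap_len if r.overlap_len is not None else "",
            "seed_match": r.seed_match,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=CLASSIFICATION_TSV_COLUMNS)


def write_classification_tsv(
    results: Iterable[ClassificationResult], path: str | Path
) -> None:
    classification_dataframe(results).to_csv(path, sep="\t", index=False)
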