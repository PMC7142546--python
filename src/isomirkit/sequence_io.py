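"""Reading, filtering and collapsing of small-RNA reads.

A raw small-RNA library (FASTQ or FASTA, single-end) is reduced to the
working representation used by the rest of the pipeline:

1. reads are length-filtered to a window (default 15-35 nt, the usual
   size range kept for small-RNA analysis after adapter removal),
2. reads containing ambiguous bases (N) are dropped,
3. identical sequences are collapsed to unique entries with counts.

Sequences are held internally in the RNA alphabet (U); FASTQ input in
the DNA alphabet is converted on read.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO

from ._alphabet import normalize, to_dna
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 15
DEFAULT_MAX_LEN = 35


@dataclass(frozen=True, slots=True)
class RawRead:
    """One sequencing read: identifier, U-alphabet sequence, optional
    Phred+33 quality string of the same length."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize(self.seq))
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, slots=True)
class CollapsedRead:
    """A unique sequence with its multiplicity in the library."""

    seq: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValidationError(f"collapsed read count must be >= 1, got {self.count}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path | TextIO) -> Iterator[RawRead]:
    """Iterate reads from a FASTA file (plain text)."""
    for i, rec in enumerate(SeqIO.parse(path, "fasta")):
        try:
            yield RawRead(id=rec.id, seq=str(rec.seq))
        except ValidationError as exc:
            raise FormatError(f"FASTA record {i} ({rec.id}): {exc}", record_index=i) from exc


def read_fastq(path: str | Path | TextIO) -> Iterator[RawRead]:
    """Iterate reads from a 4-line FASTQ file (Phred+33).

    A record whose quality string does not match its sequence length is
    reported with its record index.
    """
    it = SeqIO.parse(path, "fastq")
    i = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:  # Biopython signals seq/qual mismatch here
            raise FormatError(f"FASTQ record {i}: {exc}", record_index=i) from exc
        quals = rec.letter_annotations.get("phred_quality")
        qual = "".join(chr(q + 33) for q in quals) if quals is not None else None
        try:
            yield RawRead(id=rec.id, seq=str(rec.seq), qual=qual)
        except ValidationError as exc:
            raise FormatError(f"FASTQ record {i} ({rec.id}): {exc}", record_index=i) from exc
        i += 1


def read_reads(path: str | Path) -> Iterator[RawRead]:
    """Dispatch on file extension: .fq/.fastq -> FASTQ, otherwise FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(reads: Iterable[RawRead], path: str | Path, alphabet: str = "U") -> None:
    conv = (lambda s: s) if alphabet == "U" else to_dna
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{conv(r.seq)}\n")


def write_fastq(reads: Iterable[RawRead], path: str | Path, alphabet: str = "T") -> None:
    conv = (lambda s: s) if alphabet == "U" else to_dna
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{conv(r.seq)}\n+\n{qual}\n")


def write_collapsed_fasta(
    collapsed: Iterable[CollapsedRead], path: str | Path, alphabet: str = "U"
) -> None:
    """Write collapsed reads as FASTA with ``>seq<rank>_x<count>`` headers
    (the common collapsed-library convention)."""
    conv = (lambda s: s) if alphabet == "U" else to_dna
    with open(path, "w") as fh:
        for rank, c in enumerate(collapsed, start=1):
            fh.write(f">seq{rank}_x{c.count}\n{conv(c.seq)}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            count = int(rec.id.rsplit("_x", 1)[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(
                f"collapsed FASTA record {i}: header {rec.id!r} lacks _x<count> suffix",
                record_index=i,
            ) from exc
        out.append(CollapsedRead(seq=normalize(str(rec.seq)), count=count))
    return out


# ---------------------------------------------------------------------------
# filtering / collapsing
# ---------------------------------------------------------------------------

def filter_by_length(
    reads: Iterable[RawRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> Iterator[RawRead]:
    """Keep exactly the reads with ``min_len <= len <= max_len`` (both
    boundaries inclusive), preserving input order."""
    if not (1 <= min_len <= max_len):
        raise ValidationError(f"bad length window [{min_len}, {max_len}]")

    def _gen() -> Iterator[RawRead]:
        for r in reads:
            if min_len <= len(r.seq) <= max_len:
                yield r

    return _gen()


def drop_ambiguous(reads: Iterable[RawRead]) -> Iterator[RawRead]:
    """Drop reads containing N; the number dropped is logged.

    Downstream mismatch counting is ambiguous for N, so such reads are
    removed rather than matched permissively.
    """
    dropped = 0
    for r in reads:
        if "N" in r.seq:
            dropped += 1
        else:
            yield r
    if dropped:
        logger.info("dropped %d reads containing N", dropped)


def trim_adapter3(
    reads: Iterable[RawRead], adapter: str, min_overlap: int = 5
) -> Iterator[RawRead]:
    """Optional exact-prefix 3' adapter trimmer (off by default in the
    pipeline; libraries are normally adapter-trimmed upstream).

    The leftmost position where the remainder of the read is an exact
    prefix of the adapter (overlap >= ``min_overlap``) is trimmed.
    Reads that would become empty are dropped.
    """
    ad = normalize(adapter)
    for r in reads:
        cut = None
        for i in range(len(r.seq) - min_overlap + 1):
            tail = r.seq[i:]
            if ad.startswith(tail[: len(ad)]):
                cut = i
                break
        if cut is None:
            yield r
        elif cut > 0:
            yield RawRead(id=r.id, seq=r.seq[:cut], qual=r.qual[:cut] if r.qual else None)


def collapse(reads: Iterable[RawRead]) -> list[CollapsedRead]:
    """Collapse reads to unique sequences with counts.

    Output order is deterministic: descending count, ties broken
    lexicographically by sequence. The counts sum to the number of input
    reads.
    """
    counts = Counter(r.seq for r in reads)
    return [
        CollapsedRead(seq=s, count=n)
        for s, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def expand(collapsed: Iterable[CollapsedRead]) -> Iterator[RawRead]:
    """Inverse of :func:`collapse` up to read identity: emit each unique
    sequence ``count`` times (synthetic ids)."""
    for i, c in enumerate(collapsed):
        for j in range(c.count):
            yield RawRead(id=f"seq{i + 1}_{j + 1}", seq=c.seq)


# ---------------------------------------------------------------------------
# length distribution
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class LengthDistribution:
    """Per-length read counts for the redundant library (all reads) and
    the unique view (distinct sequences)."""

    min_len: int
    max_len: int
    redundant: dict[int, int] = field(default_factory=dict)
    unique: dict[int, int] = field(default_factory=dict)

    @property
    def total_redundant(self) -> int:
        return sum(self.redundant.values())

    @property
    def total_unique(self) -> int:
        return sum(self.unique.values())

    def modal_length(self, which: str = "redundant") -> int | None:
        hist = self.redundant if which == "redundant" else self.unique
        if not any(hist.values()):
            return None
        return max(hist, key=lambda k: (hist[k], -k))

    def to_dataframe(self) -> pd.DataFrame:
        lengths = range(self.min_len, self.max_len + 1)
        return pd.DataFrame(
            {
                "length": list(lengths),
                "redundant": [self.redundant.get(k, 0) for k in lengths],
                "unique": [self.unique.get(k, 0) for k in lengths],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def length_distribution(
    collapsed: Iterable[CollapsedRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> LengthDistribution:
    """Histogram of read lengths for both library views.

    The collapsed view determines both: each entry contributes ``count``
    to the redundant histogram and 1 to the unique histogram at its
    length.
    """
    dist = LengthDistribution(min_len=min_len, max_len=max_len)
    for c in collapsed:
        n = len(c.seq)
        dist.redundant[n] = dist.redundant.get(n, 0) + c.count
        dist.unique[n] = dist.unique.get(n, 0) + 1
    return dist
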