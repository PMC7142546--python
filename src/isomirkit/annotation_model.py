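"""Precursor-hairpin and mature-miRNA reference annotation.

A miRNA locus is a precursor (stem-loop) sequence carrying one or two
annotated arm windows: the *mature* strand and optionally its duplex
partner, the *star* strand.  Each arm records which side of the hairpin
it comes from (5p or 3p).  Precursor sequences are stored strand
resolved: a locus on the minus strand of the genome is represented by
the already reverse-complemented sequence, and reads are matched
sense-only.

The mature reference database is a FASTA of known mature miRNAs
(miRBase-style names such as ``dme-miR-276a-3p``); the *seed* of a
mature miRNA is nucleotide positions 2-8 (1-based), the principal
target-recognition determinant in metazoans.

Coordinates are 0-based half-open internally; the TSV and GFF3
interfaces are 1-based closed per the GFF3 convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import gffutils
import pandas as pd
from Bio import SeqIO

from ._alphabet import normalize
from .errors import ValidationError

PRECURSOR_TSV_COLUMNS = [
    "locus_id", "precursor_seq",
    "mature_start", "mature_end", "mature_side",
    "star_start", "star_end", "star_side",
    "scaffold", "g_start", "g_end", "strand",
]


def seed_of(seq: str) -> str:
    """Seed of a mature miRNA: positions 2-8, 1-based inclusive (a 7-mer)."""
    if len(seq) < 8:
        raise ValidationError(f"sequence too short for a seed (len {len(seq)} < 8)")
    return seq[1:8]


@dataclass(frozen=True, slots=True)
class ArmAnnotation:
    """One arm window within a precursor; [start, end) 0-based."""

    role: Literal["mature", "star"]
    start: int
    end: int
    side: Literal["5p", "3p"]

    def __post_init__(self):
        if self.role not in ("mature", "star"):
            raise ValidationError(f"arm role must be mature/star, got {self.role!r}")
        if self.side not in ("5p", "3p"):
            raise ValidationError(f"arm side must be 5p/3p, got {self.side!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad arm window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class GenomeRef:
    """Optional genomic placement of a precursor (1-based closed)."""

    scaffold: str
    start: int
    end: int
    strand: Literal["+", "-"]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be +/-, got {self.strand!r}")
        if self.end < self.start:
            raise ValidationError(f"genome end {self.end} < start {self.start}")


@dataclass(frozen=True, slots=True)
class PrecursorLocus:
    locus_id: str
    seq: str
    mature: ArmAnnotation
    star: ArmAnnotation | None = None
    genome_ref: GenomeRef | None = None

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize(self.seq))
        for arm in self.arms():
            if arm.end > len(self.seq):
                raise ValidationError(
                    f"locus {self.locus_id}: {arm.role} window "
                    f"[{arm.start}, {arm.end}) exceeds precursor length {len(self.seq)}"
                )
        if self.mature.role != "mature":
            raise ValidationError(f"locus {self.locus_id}: mature slot holds role {self.mature.role!r}")
        if self.star is not None:
            if self.star.role != "star":
                raise ValidationError(f"locus {self.locus_id}: star slot holds role {self.star.role!r}")
            if self.mature.start < self.star.end and self.star.start < self.mature.end:
                raise ValidationError(f"locus {self.locus_id}: mature and star windows overlap")

    def arms(self) -> list[ArmAnnotation]:
        return [self.mature] if self.star is None else [self.mature, self.star]

    def arm(self, role: str) -> ArmAnnotation:
        for a in self.arms():
            if a.role == role:
                return a
        raise KeyError(role)

    def arm_seq(self, role: str) -> str:
        a = self.arm(role)
        return self.seq[a.start:a.end]

    @property
    def mature_seq(self) -> str:
        return self.arm_seq("mature")


@dataclass(frozen=True, slots=True)
class MatureReference:
    """A known mature miRNA from the reference database."""

    name: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize(self.seq))
        if len(self.seq) < 15:
            raise ValidationError(
                f"reference {self.name}: mature sequence shorter than 15 nt"
            )

    @property
    def seed(self) -> str:
        return seed_of(self.seq)


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

def _check_unique_ids(loci: Iterable[PrecursorLocus]) -> list[PrecursorLocus]:
    out: list[PrecursorLocus] = []
    seen: set[str] = set()
    for locus in loci:
        if locus.locus_id in seen:
            raise ValidationError(f"duplicate locus_id {locus.locus_id!r}")
        seen.add(locus.locus_id)
        out.append(locus)
    return out


def load_precursors_tsv(path: str | Path) -> list[PrecursorLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "strand": str})
    missing = set(PRECURSOR_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"precursor TSV missing columns: {sorted(missing)}")

    loci = []
    for _, row in df.iterrows():
        mature = ArmAnnotation(
            role="mature",
            start=int(row.mature_start),
            end=int(row.mature_end),
            side=str(row.mature_side),
        )
        star = None
        if pd.notna(row.star_start) and str(row.star_start) != "":
            star = ArmAnnotation(
                role="star",
                start=int(row.star_start),
                end=int(row.star_end),
                side=str(row.star_side),
            )
        genome_ref = None
        if pd.notna(row.scaffold) and str(row.scaffold) != "":
            genome_ref = GenomeRef(
                scaffold=str(row.scaffold),
                start=int(row.g_start),
                end=int(row.g_end),
                strand=str(row.strand),
            )
        loci.append(
            PrecursorLocus(
                locus_id=str(row.locus_id),
                seq=str(row.precursor_seq),
                mature=mature,
                star=star,
                genome_ref=genome_ref,
            )
        )
    return _check_unique_ids(loci)


def write_precursors_tsv(loci: Iterable[PrecursorLocus], path: str | Path) -> None:
    rows = []
    for p in loci:
        rows.append({
            "locus_id": p.locus_id,
            "precursor_seq": p.seq,
            "mature_start": p.mature.start,
            "mature_end": p.mature.end,
            "mature_side": p.mature.side,
            "star_start": p.star.start if p.star else "",
            "star_end": p.star.end if p.star else "",
            "star_side": p.star.side if p.star else "",
            "scaffold": p.genome_ref.scaffold if p.genome_ref else "",
            "g_start": p.genome_ref.start if p.genome_ref else "",
            "g_end": p.genome_ref.end if p.genome_ref else "",
            "strand": p.genome_ref.strand if p.genome_ref else "",
        })
    pd.DataFrame(rows, columns=PRECURSOR_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 interface
#
# Features are expressed in precursor-local coordinates (seqid ==
# locus_id): one miRNA_primary_transcript spanning the hairpin and one
# miRNA child per arm, with role/side attributes.  Precursor sequences
# travel in the ##FASTA section.  Genomic placement, when present, is
# carried as attributes on the primary transcript.
# ---------------------------------------------------------------------------

def write_precursors_gff3(loci: Iterable[PrecursorLocus], path: str | Path) -> None:
    loci = list(loci)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in loci:
            attrs = [f"ID={p.locus_id}"]
            if p.genome_ref:
                g = p.genome_ref
                attrs.append(
                    f"genome_scaffold={g.scaffold};genome_start={g.start};"
                    f"genome_end={g.end};genome_strand={g.strand}"
                )
            fh.write(
                f"{p.locus_id}\tisomirkit\tmiRNA_primary_transcript\t1\t{len(p.seq)}"
                f"\t.\t+\t.\t{';'.join(attrs)}\n"
            )
            for arm in p.arms():
                fh.write(
                    f"{p.locus_id}\tisomirkit\tmiRNA\t{arm.start + 1}\t{arm.end}"
                    f"\t.\t+\t.\tID={p.locus_id}.{arm.role};Parent={p.locus_id};"
                    f"role={arm.role};side={arm.side}\n"
                )
        fh.write("##FASTA\n")
        for p in loci:
            fh.write(f">{p.locus_id}\n{p.seq}\n")


def load_precursors_gff3(path: str | Path) -> list[PrecursorLocus]:
    text = Path(path).read_text()
    if "##FASTA" in text:
        gff_part, fasta_part = text.split("##FASTA", 1)
    else:
        raise ValidationError("precursor GFF3 must carry sequences in a ##FASTA section")
    seqs = {
        rec.id: normalize(str(rec.seq))
        for rec in SeqIO.parse(io.StringIO(fasta_part.lstrip("\n")), "fasta")
    }
    db = gffutils.create_db(
        gff_part, ":memory:", from_string=True, keep_order=True, merge_strategy="error"
    )
    loci = []
    for feat in db.features_of_type("miRNA_primary_transcript", order_by="start"):
        locus_id = feat.attributes["ID"][0]
        if locus_id not in seqs:
            raise ValidationError(f"locus {locus_id}: no sequence in ##FASTA section")
        mature = star = None
        for child in db.children(feat, featuretype="miRNA", order_by="start"):
            arm = ArmAnnotation(
                role=child.attributes["role"][0],
                start=child.start - 1,
                end=child.end,
                side=child.attributes["side"][0],
            )
            if arm.role == "mature":
                mature = arm
            else:
                star = arm
        if mature is None:
            raise ValidationError(f"locus {locus_id}: no mature arm feature")
        genome_ref = None
        if "genome_scaffold" in feat.attributes:
            genome_ref = GenomeRef(
                scaffold=feat.attributes["genome_scaffold"][0],
                start=int(feat.attributes["genome_start"][0]),
                end=int(feat.attributes["genome_end"][0]),
                strand=feat.attributes["genome_strand"][0],
            )
        loci.append(
            PrecursorLocus(
                locus_id=locus_id, seq=seqs[locus_id],
                mature=mature, star=star, genome_ref=genome_ref,
            )
        )
    return _check_unique_ids(loci)


def load_precursors(path: str | Path) -> list[PrecursorLocus]:
    """Load precursor loci from TSV or GFF3 (dispatch on extension)."""
    if Path(path).suffix.lower() in {".gff", ".gff3"}:
        return load_precursors_gff3(path)
    return load_precursors_tsv(path)


# ---------------------------------------------------------------------------
# mature reference database
# ---------------------------------------------------------------------------

def load_mature_reference(path: str | Path) -> dict[str, MatureReference]:
    """Load the mature-miRNA reference FASTA, keyed by name.

    Names must be unique; sequences are U-normalized.  An empty file
    yields an empty collection (classification then labels every locus
    novel).
    """
    refs: dict[str, MatureReference] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in refs:
            raise ValidationError(f"duplicate reference name {rec.id!r}")
        refs[rec.id] = MatureReference(name=rec.id, seq=str(rec.seq))
    return refs


def write_mature_reference(refs: Iterable[MatureReference], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.name}\n{r.seq}\n")
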