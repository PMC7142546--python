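"""Synthetic small-RNA library generator with ground truth.

Emulates a collapsed insect small-RNA library as seen after adapter
trimming and quality filtering: a bimodal read-length profile with
modes near 21 nt (miRNA-sized) and 28 nt, a minority of reads derived
from miRNA precursor hairpins, and per-locus isomiR spectra (5'/3'
offsets drawn from configurable distributions, occasional single-base
substitutions).  Locus abundances follow a log-normal law, the usual
shape of miRNA expression.  A configurable fraction of hairpin-derived
reads deliberately violates the retention thresholds (5' offset beyond
±2, 3' offset beyond ±5, or two substitutions) to exercise the
rejection paths.  Background reads are drawn from synthetic category
reference pools (tRNA, rRNA, ...) so the category bookkeeping can be
tested, plus a purely random unassigned remainder.

Every generated read is recorded in a truth table (origin, locus, arm,
offsets, substitutions), and all randomness flows from the config seed,
so identical configs give byte-identical outputs.

Hairpin realism is structural only: the star arm is a degenerate
reverse complement of the mature arm across a loop, with no
thermodynamic folding (no pipeline stage in scope evaluates folding).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._alphabet import RNA_BASES, reverse_complement
from .annotation_model import (
    ArmAnnotation,
    GenomeRef,
    MatureReference,
    PrecursorLocus,
    write_mature_reference,
    write_precursors_tsv,
)
from .errors import ValidationError
from .sequence_io import RawRead, write_fasta, write_fastq


def _default_offset5() -> dict[int, float]:
    return {-2: 0.05, -1: 0.10, 0: 0.70, 1: 0.10, 2: 0.05}


def _default_offset3() -> dict[int, float]:
    return {
        -5: 0.01, -4: 0.02, -3: 0.04, -2: 0.08, -1: 0.15,
        0: 0.40, 1: 0.15, 2: 0.08, 3: 0.04, 4: 0.02, 5: 0.01,
    }


def _default_background_composition() -> dict[str, float]:
    # roughly the triage of a whitefly-style library once miRNA reads
    # are set aside: tRNA-dominated, a large unassigned remainder
    return {
        "tRNA": 0.32, "rRNA": 0.08, "repetitive_element": 0.02,
        "other_families": 0.06, "other_genome": 0.07, "unassigned": 0.45,
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic library."""

    n_loci: int = 50
    total_reads: int = 100_000
    seed: int = 0

    # locus geometry
    mature_len: tuple[int, int] = (20, 24)
    loop_len: tuple[int, int] = (8, 15)
    flank_len: tuple[int, int] = (6, 10)
    star_max_mutations: int = 3  # degeneracy of the star arm vs revcomp(mature)

    # abundance and isomiR spectrum
    abundance_sigma: float = 1.0  # log-normal sigma of locus weights
    offset5_probs: dict[int, float] = field(default_factory=_default_offset5)
    offset3_probs: dict[int, float] = field(default_factory=_default_offset3)
    substitution_prob: float = 0.05
    star_fraction: float = 0.10
    out_of_box_fraction: float = 0.05

    # background
    background_fraction: float = 0.90
    background_modes: tuple[int, int] = (21, 28)
    background_mode_weights: tuple[float, float] = (0.5, 0.5)
    background_sd: float = 1.5
    background_composition: dict[str, float] = field(
        default_factory=_default_background_composition
    )

    # read-length window the library is destined for
    min_len: int = 15
    max_len: int = 35

    def validate(self) -> None:
        for name, probs in (
            ("offset5_probs", self.offset5_probs),
            ("offset3_probs", self.offset3_probs),
            ("background_composition", self.background_composition),
        ):
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValidationError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in probs.values()):
                raise ValidationError(f"{name} has negative entries")
        if not math.isclose(sum(self.background_mode_weights), 1.0, abs_tol=1e-9):
            raise ValidationError("background_mode_weights must sum to 1")
        for name, frac in (
            ("substitution_prob", self.substitution_prob),
            ("star_fraction", self.star_fraction),
            ("out_of_box_fraction", self.out_of_box_fraction),
            ("background_fraction", self.background_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {frac}")
        if self.n_loci < 1 or self.total_reads < 0:
            raise ValidationError("n_loci must be >= 1 and total_reads >= 0")
        if self.mature_len[0] > self.mature_len[1] or self.mature_len[0] < 15:
            raise ValidationError(f"infeasible mature_len range {self.mature_len}")
        if self.flank_len[0] < 6:
            # 5'/3' extensions (in-box up to 2/5 nt, out-of-box probes up
            # to 3/6 nt) must stay templated within the hairpin
            raise ValidationError("flank_len must allow >= 6 nt flanks")
        if not (1 <= self.min_len <= self.max_len):
            raise ValidationError(f"bad length window [{self.min_len}, {self.max_len}]")

    # -- JSON round-trip (offset keys are ints; JSON forces strings) --

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("offset5_probs", "offset3_probs"):
            raw[key] = {int(k): v for k, v in raw[key].items()}
        for key in ("mature_len", "loop_len", "flank_len",
                    "background_modes", "background_mode_weights"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# loci
# ---------------------------------------------------------------------------

def _rng_for(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(RNA_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, n: int) -> str:
    """Apply n substitutions at distinct positions, each to a different base."""
    s = list(seq)
    positions = rng.choice(len(s), size=n, replace=False)
    for pos in positions:
        choices = [b for b in RNA_BASES if b != s[pos]]
        s[pos] = choices[rng.integers(0, 3)]
    return "".join(s)


def generate_loci(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[PrecursorLocus]:
    """Generate hairpin-shaped precursor loci: 5' flank, one arm, loop,
    partner arm (degenerate reverse complement), 3' flank.  The mature
    window sits on a random side; the star window is its partner.
    Deterministic under the config seed."""
    cfg.validate()
    rng = rng if rng is not None else _rng_for(cfg, 1)
    loci = []
    seen_matures: set[str] = set()
    for i in range(cfg.n_loci):
        while True:
            mlen = int(rng.integers(cfg.mature_len[0], cfg.mature_len[1] + 1))
            mature_seq = _random_seq(rng, mlen)
            if mature_seq not in seen_matures:
                seen_matures.add(mature_seq)
                break
        loop = _random_seq(rng, int(rng.integers(cfg.loop_len[0], cfg.loop_len[1] + 1)))
        f5 = _random_seq(rng, int(rng.integers(cfg.flank_len[0], cfg.flank_len[1] + 1)))
        f3 = _random_seq(rng, int(rng.integers(cfg.flank_len[0], cfg.flank_len[1] + 1)))
        n_mut = int(rng.integers(1, cfg.star_max_mutations + 1))
        partner = _mutate(rng, reverse_complement(mature_seq), n_mut)
        side = "5p" if rng.random() < 0.5 else "3p"
        if side == "5p":
            seq = f5 + mature_seq + loop + partner + f3
            mature = ArmAnnotation("mature", len(f5), len(f5) + mlen, "5p")
            star_start = len(f5) + mlen + len(loop)
            star = ArmAnnotation("star", star_start, star_start + len(partner), "3p")
        else:
            seq = f5 + partner + loop + mature_seq + f3
            star = ArmAnnotation("star", len(f5), len(f5) + len(partner), "5p")
            m_start = len(f5) + len(partner) + len(loop)
            mature = ArmAnnotation("mature", m_start, m_start + mlen, "3p")
        scaffold = f"SYNSCF{(i // 5) + 1:03d}.1"
        g_start = 10_000 * (i % 5) + 1
        loci.append(
            PrecursorLocus(
                locus_id=f"{scaffold}_{i + 1}",
                seq=seq, mature=mature, star=star,
                genome_ref=GenomeRef(
                    scaffold=scaffold, start=g_start, end=g_start + len(seq) - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                ),
            )
        )
    return loci


def generate_mature_reference(
    loci: list[PrecursorLocus],
    rng: np.random.Generator | None = None,
    canonical_fraction: float = 0.6,
    n_decoys: int = 20,
    species: str = "dsy",
    seed: int = 0,
) -> tuple[dict[str, MatureReference], set[str]]:
    """Synthetic mature-miRNA reference database.

    A ``canonical_fraction`` of loci get a reference derived from their
    mature sequence with 0-2 substitutions (so they classify canonical
    under the 2-mismatch rule); the rest have no counterpart.  Random
    decoy references are added.  Returns the database plus the set of
    locus_ids with a planted reference.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([seed, 3])
    )
    refs: dict[str, MatureReference] = {}
    planted: set[str] = set()
    for i, locus in enumerate(loci):
        if rng.random() < canonical_fraction:
            n_mut = int(rng.integers(0, 3))
            seq = _mutate(rng, locus.mature_seq, n_mut) if n_mut else locus.mature_seq
            name = f"{species}-miR-{i + 1}-{locus.mature.side}"
            refs[name] = MatureReference(name=name, seq=seq)
            planted.add(locus.locus_id)
    for j in range(n_decoys):
        name = f"{species}-miR-d{j + 1}-5p"
        refs[name] = MatureReference(name=name, seq=_random_seq(rng, 22))
    return refs, planted


def generate_category_references(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_refs: int = 4,
    ref_len: int = 400,
) -> dict[str, list[str]]:
    """Reference pools for the background categories (excluding the
    purely random ``unassigned`` class)."""
    rng = rng if rng is not None else _rng_for(cfg, 4)
    return {
        name: [_random_seq(rng, ref_len) for _ in range(n_refs)]
        for name in cfg.background_composition
        if name != "unassigned"
    }


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

TRUTH_READ_COLUMNS = [
    "read_id", "seq", "length", "origin", "category", "locus_id",
    "arm_role", "offset5", "offset3", "n_subs", "out_of_box",
]


@dataclass
class TruthTable:
    """Per-read ground truth plus a per-locus summary."""

    reads: pd.DataFrame
    loci: pd.DataFrame
    locus_weights: dict[str, float]

    def write(self, reads_path: str | Path, loci_path: str | Path) -> None:
        self.reads.to_csv(reads_path, sep="\t", index=False)
        self.loci.to_csv(loci_path, sep="\t", index=False)


def _sample_discrete(rng: np.random.Generator, probs: dict[int, float]) -> int:
    keys = sorted(probs)
    return int(rng.choice(keys, p=[probs[k] for k in keys]))


def _background_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    mode = cfg.background_modes[
        0 if rng.random() < cfg.background_mode_weights[0] else 1
    ]
    n = int(round(rng.normal(mode, cfg.background_sd)))
    return max(cfg.min_len, min(cfg.max_len, n))


def _sample_offsets(
    cfg: SimulationConfig, rng: np.random.Generator, arm_len: int,
    force_off5: int | None = None, force_off3: int | None = None,
) -> tuple[int, int]:
    """Sample (offset5, offset3), rejecting combinations whose read
    length falls outside the library window (so every generated hairpin
    read survives length filtering)."""
    for _ in range(1000):
        o5 = force_off5 if force_off5 is not None else _sample_discrete(rng, cfg.offset5_probs)
        o3 = force_off3 if force_off3 is not None else _sample_discrete(rng, cfg.offset3_probs)
        if cfg.min_len <= arm_len + o3 - o5 <= cfg.max_len:
            return o5, o3
    raise ValidationError("cannot sample offsets within the length window")


def generate_reads(
    cfg: SimulationConfig,
    loci: list[PrecursorLocus],
    rng: np.random.Generator | None = None,
    category_references: dict[str, list[str]] | None = None,
) -> tuple[list[RawRead], TruthTable]:
    """Sample the library: hairpin-derived reads (with truth offsets and
    substitutions) and background reads (with truth categories)."""
    cfg.validate()
    rng = rng if rng is not None else _rng_for(cfg, 2)
    if category_references is None:
        category_references = generate_category_references(cfg, _rng_for(cfg, 4))

    weights = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=len(loci))
    weights = weights / weights.sum()
    locus_weights = {p.locus_id: float(w) for p, w in zip(loci, weights)}

    bg_names = sorted(cfg.background_composition)
    bg_probs = [cfg.background_composition[k] for k in bg_names]

    reads: list[RawRead] = []
    rows: list[tuple] = []
    for i in range(cfg.total_reads):
        rid = f"read{i + 1}"
        if rng.random() < cfg.background_fraction:
            cat = bg_names[int(rng.choice(len(bg_names), p=bg_probs))]
            length = _background_length(cfg, rng)
            if cat == "unassigned" or not category_references.get(cat):
                seq = _random_seq(rng, length)
            else:
                pool = category_references[cat]
                ref = pool[int(rng.integers(0, len(pool)))]
                start = int(rng.integers(0, len(ref) - length + 1))
                seq = ref[start:start + length]
            reads.append(RawRead(id=rid, seq=seq))
            rows.append((rid, seq, length, "background", cat, "", "", 0, 0, 0, False))
            continue

        li = int(rng.choice(len(loci), p=weights))
        locus = loci[li]
        arm = locus.star if (locus.star and rng.random() < cfg.star_fraction) else locus.mature
        arm_len = len(arm)
        out_of_box = rng.random() < cfg.out_of_box_fraction
        n_subs = 0
        if not out_of_box:
            o5, o3 = _sample_offsets(cfg, rng, arm_len)
            window = locus.seq[arm.start + o5:arm.end + o3]
            if rng.random() < cfg.substitution_prob:
                window = _mutate(rng, window, 1)
                n_subs = 1
        else:
            kind = ("off5", "off3", "mm")[int(rng.integers(0, 3))]
            if kind == "off5":
                o5 = 3 if rng.random() < 0.5 else -3
                _, o3 = _sample_offsets(cfg, rng, arm_len, force_off5=o5)
                window = locus.seq[arm.start + o5:arm.end + o3]
            elif kind == "off3":
                o3 = 6
                o5, _ = _sample_offsets(cfg, rng, arm_len, force_off3=o3)
                window = locus.seq[arm.start + o5:arm.end + o3]
            else:
                o5, o3 = _sample_offsets(cfg, rng, arm_len)
                window = _mutate(rng, locus.seq[arm.start + o5:arm.end + o3], 2)
                n_subs = 2
        reads.append(RawRead(id=rid, seq=window))
        rows.append((
            rid, window, len(window), "mirna", "miRNA", locus.locus_id,
            arm.role, o5, o3, n_subs, out_of_box,
        ))

    reads_df = pd.DataFrame(rows, columns=TRUTH_READ_COLUMNS)

    mirna = reads_df[reads_df.origin == "mirna"]
    loci_rows = []
    for locus in loci:
        sub = mirna[mirna.locus_id == locus.locus_id]
        clean = (sub.offset5 == 0) & (sub.offset3 == 0) & (sub.n_subs == 0)
        loci_rows.append({
            "locus_id": locus.locus_id,
            "weight": locus_weights[locus.locus_id],
            "n_reads": len(sub),
            "mature_clean": int((clean & (sub.arm_role == "mature")).sum()),
            "star_clean": int((clean & (sub.arm_role == "star")).sum()),
            "n_isomir_reads": int((~clean & ~sub.out_of_box).sum()),
            "n_out_of_box": int(sub.out_of_box.sum()),
        })
    loci_df = pd.DataFrame(loci_rows)
    truth = TruthTable(reads=reads_df, loci=loci_df, locus_weights=locus_weights)
    return reads, truth


# ---------------------------------------------------------------------------
# analytic expectations (used to check parameter recovery)
# ---------------------------------------------------------------------------

def _conditional_offset_joint(
    cfg: SimulationConfig, arm_len: int
) -> dict[tuple[int, int], float]:
    """Joint (offset5, offset3) law conditioned on the read length
    falling inside the library window, as the generator samples it."""
    joint = {}
    for o5, p5 in cfg.offset5_probs.items():
        for o3, p3 in cfg.offset3_probs.items():
            if cfg.min_len <= arm_len + o3 - o5 <= cfg.max_len:
                joint[(o5, o3)] = p5 * p3
    z = sum(joint.values())
    if z == 0:
        raise ValidationError(f"no feasible offsets for arm length {arm_len}")
    return {k: v / z for k, v in joint.items()}


def expected_offset_marginals(
    cfg: SimulationConfig,
    loci: list[PrecursorLocus],
    locus_weights: dict[str, float],
) -> tuple[dict[int, float], dict[int, float]]:
    """Expected marginal offset distributions among retained (in-box)
    hairpin reads, mixing loci and arms by their sampling weights."""
    m5: dict[int, float] = {}
    m3: dict[int, float] = {}
    for locus in loci:
        w = locus_weights[locus.locus_id]
        arm_parts = [(locus.mature, 1.0 - cfg.star_fraction)]
        if locus.star is not None:
            arm_parts.append((locus.star, cfg.star_fraction))
        for arm, frac in arm_parts:
            joint = _conditional_offset_joint(cfg, len(arm))
            for (o5, o3), p in joint.items():
                m5[o5] = m5.get(o5, 0.0) + w * frac * p
                m3[o3] = m3.get(o3, 0.0) + w * frac * p
    return m5, m3


def expected_clean_mature_probability(
    cfg: SimulationConfig,
    locus: PrecursorLocus,
    locus_weights: dict[str, float],
) -> float:
    """Per-read probability of producing this locus's exact canonical
    mature sequence (no offsets, no substitution)."""
    joint = _conditional_offset_joint(cfg, len(locus.mature))
    return (
        (1.0 - cfg.background_fraction)
        * locus_weights[locus.locus_id]
        * (1.0 - cfg.star_fraction)
        * (1.0 - cfg.out_of_box_fraction)
        * joint.get((0, 0), 0.0)
        * (1.0 - cfg.substitution_prob)
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedLibrary:
    config: SimulationConfig
    loci: list[PrecursorLocus]
    reads: list[RawRead]
    truth: TruthTable
    mature_reference: dict[str, MatureReference]
    planted_reference_loci: set[str]
    category_references: dict[str, list[str]]


def simulate(cfg: SimulationConfig) -> SimulatedLibrary:
    """Run the whole generator from one config: loci, reference
    database, category pools, reads and truth."""
    cfg.validate()
    loci = generate_loci(cfg, _rng_for(cfg, 1))
    refs, planted = generate_mature_reference(loci, _rng_for(cfg, 3))
    cat_refs = generate_category_references(cfg, _rng_for(cfg, 4))
    reads, truth = generate_reads(cfg, loci, _rng_for(cfg, 2), cat_refs)
    return SimulatedLibrary(
        config=cfg, loci=loci, reads=reads, truth=truth,
        mature_reference=refs, planted_reference_loci=planted,
        category_references=cat_refs,
    )


def write_library(lib: SimulatedLibrary, outdir: str | Path, fastq: bool = True) -> dict[str, Path]:
    """Write the library to disk: precursors.tsv, reads.fastq (or .fa),
    truth_reads.tsv, truth_loci.tsv, config.json, plus the mature
    reference FASTA and the category reference pools."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "precursors": outdir / "precursors.tsv",
        "reads": outdir / ("reads.fastq" if fastq else "reads.fa"),
        "truth_reads": outdir / "truth_reads.tsv",
        "truth_loci": outdir / "truth_loci.tsv",
        "config": outdir / "config.json",
        "mature_reference": outdir / "mature_reference.fa",
        "category_references": outdir / "category_references.tsv",
    }
    write_precursors_tsv(lib.loci, paths["precursors"])
    if fastq:
        write_fastq(lib.reads, paths["reads"])
    else:
        write_fasta(lib.reads, paths["reads"])
    lib.truth.write(paths["truth_reads"], paths["truth_loci"])
    lib.config.to_json(paths["config"])
    write_mature_reference(lib.mature_reference.values(), paths["mature_reference"])
    with open(paths["category_references"], "w") as fh:
        fh.write("category\tseq\n")
        for name, seqs in lib.category_references.items():
            for s in seqs:
                fh.write(f"{name}\t{s}\n")
    return paths
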