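# Methods

## Scope and data model

`isomirkit` operates downstream of adapter trimming and quality
filtering: its inputs are (i) a small-RNA read set (FASTQ/FASTA,
single-end), (ii) precursor hairpins with annotated mature and star arm
windows (TSV or a GFF3 dialect carrying sequences in a `##FASTA`
section), and (iii) optionally a mature-miRNA reference FASTA and
category reference sets. Precursor prediction, genome alignment and
homology search against RNA family databases are deliberately out of
scope; their outputs enter as inputs (arm coordinates, the RPM
denominator, category sets). An optional exact-prefix 3′ adapter
trimmer is provided but off by default, since libraries are normally
trimmed upstream with dedicated tools.

All sequences are stored internally in the RNA alphabet (U); readers
accept T or U and writers can emit either. Reads containing N are
dropped (with a logged count) rather than matched permissively, because
mismatch counting against a precursor is ambiguous for N. Precursor
sequences are stored strand-resolved — a minus-strand locus is
represented by its reverse-complemented sequence — and reads are
matched sense-only, so a hairpin expressed from both genomic strands is
two loci.

## Read preprocessing

Reads are filtered to a length window (default 15–35 nt, both bounds
inclusive) and collapsed to unique sequences with multiplicities.
Collapse order is fixed (count descending, then lexicographic) so all
derived files are byte-reproducible. Length histograms are kept for
both the redundant (all reads) and unique (distinct sequences) views;
both are derived from the collapsed view, whose counts determine the
redundant histogram exactly.

## Arm assignment and isomiR calling

A read is placed on a precursor by sliding it along the hairpin and
counting Hamming mismatches over its full length; indels are not
modeled, because length variation is expressed entirely through the
5′/3′ offsets, and the read must lie fully inside the hairpin (no
overhang past its ends, so non-templated tail additions are
representable only within the mismatch budget). For each matching
locus the read is attributed to the arm whose annotated 5′ start is
nearest the read start (mature wins exact ties), giving offsets
δ₅ = read_start − arm_start and δ₃ = read_end − arm_end. Retention
requires mismatches ≤ 1, |δ₅| ≤ 2 and |δ₃| ≤ 5 (all three
configurable). Among acceptable placements at one locus the best is
chosen by (mismatches, |δ₅|+|δ₃|, δ₅, start) — a deterministic total
order. Offsets 0/0 with no mismatch define the canonical mature or
star sequence; everything else retained is an isomiR.

Reads matching several loci are reported at every locus with a
`multi_locus` flag and full count (per-locus view), while library-level
accounting counts each distinct sequence once, so conservation
(filtered = assigned-unique + unassigned) holds exactly. Unassigned
sequences carry a reason code; to distinguish "nearly matched" from
"no match", placements are probed with a diagnostic budget of one
mismatch above the retention budget: `too_many_mismatches` means a
placement exists exactly one over budget, `offset_out_of_range` means
an in-budget placement fell outside the offset box, `no_alignment`
otherwise.

Internally the engine uses a pigeonhole substring index (a read within
m mismatches must match one of m+1 chunks exactly), which makes
assignment of ~10⁵ unique sequences against dozens of loci take under
a second; it falls back to the exhaustive scan when reads are too short
to chunk. The index path and the plain sliding scan are both checked
against an independent brute-force oracle in the test suite, and must
agree exactly.

## Canonical/novel classification and naming

A locus's mature sequence is compared to each reference with an
ungapped overlap scan: over all relative shifts with ≥ 15 aligned
bases, the mismatch count inside the overlap is minimized; overhanging
bases cost nothing, so a 21-nt candidate matching a 22-nt reference
except for a 3′ overhang scores 0. This reproduces the behavior of a
short-sequence BLASTN match for this use case without its statistics
(no e-values). The verdict is canonical iff the best reference is
within 2 mismatches (configurable — some earlier annotation efforts
used 4); ties are broken toward the larger overlap, then the
lexicographically smaller name. A `seed_match` flag (identity of
positions 2–8, the standard metazoan seed) is reported but does not
affect the verdict.

Provisional names take a configurable species prefix (default `asp`):
canonical loci inherit the reference's core name (species code and any
-5p/-3p suffix stripped) plus the annotated mature arm side; novel loci
get `miR-` plus ten times the trailing numeric index of their locus id
— a deterministic, purely cosmetic scheme that stays clear of existing
family numbers. Name collisions receive deterministic `-2`, `-3`, ...
suffixes.

## Normalization and indices

RPM(x) = 10⁶ · x / D, where the denominator D is the number of reads
mapping to the reference genome — an input, since genome alignment is
out of scope; for synthetic data a convenience exact-substring matcher
can compute it. Per mature arm the pipeline reports mature RPM, star
RPM, the distinct-isomiR count, total isomiR RPM, and

    IDI = n_distinct_isomirs / mature_rpm
    IAI = isomir_rpm_total / mature_rpm

The denominator is the mature-arm RPM alone (not mature + isomiRs):
the published worked examples fix this reading arithmetically
(181 / 281.9 = 0.64; 1249.29 / 281.9 = 4.43). Star reads and star-arm
isomiRs are excluded from both indices and reported separately, since
the indices describe "a miRNA", which per-locus tables equate with the
mature arm. Both indices are NaN (written `NA`) when the mature RPM is
zero; profiles are still emitted for such loci. Values are kept at
full precision internally; reports round half-even to two decimals,
matching the printed style of the source analysis.

Category summaries replace homology search with exact substring
membership against user-supplied reference sets, checked in a fixed
priority order (tRNA, rRNA, miRNA, repetitive elements, other
families, other genome, unassigned; first match wins). This reproduces
the bookkeeping — each read in exactly one category, fractions summing
to 1, per-length breakdowns — not the sensitivity of a real Rfam scan.

## Synthetic libraries

The generator emulates a collapsed insect small-RNA library after
quality filtering, at the scale used for the recovery tests: 50 loci
and 100 000 reads by default, which keeps the full acceptance run
under a minute while leaving ~10 000 hairpin-derived reads for the
statistics. Defaults, chosen once to match the shape of real whitefly
libraries: 90% background with a bimodal length law (modes 21 and
28 nt, σ = 1.5, equal weights) and a composition dominated by tRNA
(0.32) and unassigned (0.45) reads; hairpin loci weighted log-normally
(σ = 1); star fraction 0.10; offset spectra concentrated at 0 (70% at
δ₅ = 0, 40% at δ₃ = 0, decaying symmetrically); per-read substitution
probability 0.05; and 5% "out-of-box" reads that deliberately violate
one threshold (δ₅ = ±3, δ₃ = +6, or two substitutions) to exercise
every rejection path. Offset pairs are rejection-sampled so every
generated read stays inside the 15–35 nt window; the analytic helpers
(`expected_offset_marginals`, `expected_clean_mature_probability`)
apply the same conditioning, so observed and expected distributions
are directly comparable.

Hairpins are structural only: flank + arm + loop + degenerate reverse
complement + flank, with no thermodynamic folding — sufficient because
no stage in scope evaluates folding. Quality strings are constant high
quality. The mature reference generator plants references (0–2
substitutions from the true mature) for a configurable fraction of
loci plus random decoys, giving known canonical/novel ground truth.
All randomness derives from one config seed through fixed substreams,
so loci, reads and references are individually and jointly
reproducible; the seed is recorded in the truth output.

What passing the recovery tests shows — and does not show: the
pipeline exactly recovers templated variants drawn from the configured
spectra in the presence of a random background, and rejects threshold
violations at the configured rate. Real libraries additionally contain
non-templated 3′ additions, indel isomiRs, adapter artifacts,
position-dependent sequencing error and cross-mapping between
paralogous precursors; none of these are simulated, and the first two
are explicitly outside the matching model.

## Numerical and design choices

- Coordinates: 0-based half-open internally; GFF3/TSV interfaces
  1-based closed per convention.
- Determinism everywhere: all tie-breaks are total orders; identical
  inputs give byte-identical output files.
- The seed of a mature miRNA is fixed as positions 2–8 (1-based); the
  reference "same seed" grouping does not define bounds, so the
  standard metazoan definition is used.
- Degenerate inputs: empty read files produce empty-but-valid outputs;
  an empty reference database classifies every locus novel; a zero
  mapped-read denominator is rejected.
- CLI exit codes separate usage (2), validation (3) and I/O (4)
  failures.

## Known limitations

- No probabilistic resolution of multi-mapping reads; both the
  per-locus (double-counted) and unique views are emitted instead.
- No indel isomiRs and no non-templated additions beyond the mismatch
  budget.
- The overlap classifier is ungapped; a reference matchable only with
  a gap will score as novel.
- Category assignment is exact-membership, not homology; it
  understates categories whose reads diverge from the reference sets.
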