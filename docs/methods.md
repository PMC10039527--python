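# Methods

This note documents the models, numerical choices, and design decisions
behind `plasmidcheck`, and what the synthetic-data tests do and do not
demonstrate about real sequencing data.

## Setting and assumptions

The pipeline verifies a *linearized* plasmid: the circular molecule is cut
once, so every read is colinear with a single linear reference frame and —
for intact templates — spans the full template length in one of two
orientations. This assumption drives three simplifications relative to
general-purpose assembly/variant tooling:

- **Alignment is global.** Each read is aligned end-to-end (free end gaps)
  against the draft or reference; there is no seeding, chaining, split
  mapping, or circular-rotation handling. Reads that are not near-full-length
  copies are removed by the length filter before alignment.
- **One consensus.** The read pool is assumed to be one template, possibly
  with subclonal variants; deconvolution into multiple consensus sequences
  is out of scope. Mixed evidence surfaces as `N` calls, pass disagreement,
  or a depressed pairing rate.
- **Strand is latent.** Read orientation is inferred from alignment, never
  from metadata.

## Read filters

A read passes the quality filter iff *every* base has Phred quality ≥
`min_qscore` (default 12) — a per-read minimum, not a mean — and passes the
length filter iff its length is within `length_tolerance` (default 250,
inclusive) of the expected reference length. Both filters are idempotent
and order-independent; stage counters are reported in the run summary.

## Pairwise alignment

A banded Gotoh dynamic program over three states (diagonal, read-gap,
reference-gap) with affine costs: match +2, mismatch −4, gap of length k
costs 4 + 2k. Leading and trailing gaps on either sequence are free, so
ragged read ends are soft-clipped rather than forced into the alignment.

- **Orientation and band sizing.** Both read orientations are screened with
  edlib's unit-cost edit distance under staged cutoffs (64 → 512 → 2048);
  the winning orientation (ties prefer forward) is aligned with band
  half-width `min(band_width/2, d + 16)`, where `d` is the screened
  distance. When both orientations exceed every cutoff the sequences are
  effectively unrelated; the forward frame is used with the band capped at
  `band_width/2` (default 300). The banded score is then a lower bound on
  the optimum, which is immaterial: for any alignment, matched bases are
  bounded above by `(len_a + len_b − d)/2`, far below the pairing
  qualification threshold for unrelated plasmid-scale sequences. For
  related sequences the adaptive band reproduces the unbanded optimum; this
  is property-tested against an independent unbanded implementation.
- **Identity shortcut.** A screened distance of 0 yields the all-match
  alignment directly.
- **Left normalization.** After traceback, every indel block is shifted to
  its leftmost column-equivalent placement (possible only across equal
  flanking bases, i.e. within homopolymers). Score is unchanged; the pileup
  relies on this convention so that run-length errors pile up at a run's
  first columns. The position report's convention is left-aligned;
  right-aligned display can be obtained by running the reverse pass, whose
  frame flips the convention.
- **Matched-base count.** "Aligned bases" for pairing qualification means
  identical aligned residues (mirroring PAF column 10), not alignment span —
  otherwise a global aligner would qualify anything.

## Pseudopairing and contamination

Reads qualify for pairing iff they have a single alignment to the expected
reference with matched bases ≥ reference length − 500 (inclusive).
Qualified sense and antisense lists are sorted by read length (ties by read
id) and zipped index-by-index, pairing reads of similar length. The pairing
rate is `100 · 2·|pairs| / (filtered reads)` — the denominator is the
quality- and length-filtered pool, not the qualified pool. A rate below 90%
(strict) flags contamination.

`collapse_pair` is a sequence-level stand-in for raw-signal duplex
basecalling: the pair is aligned, agreements pass through, substitution
conflicts resolve by higher base quality (`N` on a tie), one-sided gaps
emit the present base (optionally gated by a quality threshold), and output
qualities are per-column maxima. The default operating mode is
*pre-collapsed*: input reads are treated as already duplex-grade, and
pairing serves only as the contamination metric. Collapse mode is exposed
(`collapse_mode=True`) but changes subclonal sensitivity, since a pair
containing one wildtype and one variant read collapses its disagreement to
`N` or to the higher-quality base.

## Draft construction

The draft stands in for an external de-novo assembler. From a deterministic
subsample (default 500 reads), the read whose length is closest to the
subsample median seeds the draft; all subsampled reads are aligned to it,
a majority consensus is taken, and one polish round repeats alignment
against the updated draft. Draft calling differs from a plain majority in
three deliberate ways:

1. **Retention floor instead of gap majority.** A base column keeps its top
   base unless support falls below 10% of the maximum depth. A plain
   majority would delete the tail of any long homopolymer (under-called by
   most reads) and oscillate between polish rounds.
2. **Homopolymer-aware extension.** A between-column insertion enters the
   draft when it holds a strict majority over the pass-through count, *or*
   when it extends an adjacent homopolymer and clears the 10% floor. This
   restores full-length runs (e.g. a 17-mer supported in full by only ~17%
   of reads) while keeping subclonal non-homopolymer insertions out of the
   draft below 50%.
3. **Terminal extension from overhangs.** Because end gaps are free, read
   bases beyond the draft ends leave no trace in draft columns; a truncated
   seed read could never recover the template's termini. Read overhangs at
   each end are therefore tallied per offset and the draft is extended
   outward while the majority overhang base clears the 10% floor.

### Reference-guided reconciliation

A base deleted in a fraction f of templates and a base inserted in a
fraction 1−f produce *identical* pileups; which allele a reference-free
draft carries at such a site is decided by the seed read. The calling
criteria, however, derive their asymmetric detection limits (insertions
from 20%, deletions only beyond 90%) from a draft that carries the
*expected* allele wherever it retains ≥ 10%-of-max support. Verification
always has the expected sequence in hand, so before consensus calling the
draft is aligned to it and, at each disagreement, the expected allele is
restored iff its full-depth pileup support clears the coverage floor.
Majority-supported novel draft content is never removed — that is variant
signal for the calling stage to report. With a wrong (contaminating)
reference no allele has support, so reconciliation is a no-op.
Reconciliation is evaluated at full read depth because the 10% boundary is
exact on the mixture grid and subsample noise would flip it.

## Consensus calling

Columns are traversed 5′ terminal → base/between alternating → 3′ terminal.

- **Base columns.** Candidates are A/C/G/T counts only; deletions compete
  solely through the coverage criterion. Coverage is tested first (top
  count < 10% of max depth → dropped), then the ratio (top < 5× second, or
  a tie at the top → `N`). Both thresholds are inclusive ("at least").
- **Between columns.** At offset k the candidates are the inserted bases at
  that offset and the *stop* count (spanning reads whose insertion is
  shorter than k; at offset 0, the classic pass-through). When the stop
  count leads (ties included) it competes in the ratio: stop ≥ 5× best
  insertion → `no_insertion`, else `N`. When an inserted base leads, the
  base-column criteria apply with the second *inserted* base as the
  competitor, mirroring the gap exclusion at base columns. Offsets are
  evaluated ascending and assembly stops at the first
  `no_insertion`/`dropped`.
- **Normalization choice.** `max_coverage` is the maximum base-column depth
  rather than the total read count: terminal coverage decays (ragged ends),
  and normalizing by total reads would drop genuine terminal bases.
- **Confidence.** Per-column confidence is `100 · top/(reads at column)`,
  the denominator including deletion observations. The QC statistic is the
  median over all called bases, required to exceed 99.9% (strict).
  Signal:noise is top/second, reported as `inf` when the second count is 0.
- **Dual pass.** The consensus is computed against the draft and against
  its reverse complement (result mapped back to the draft frame, `N`
  self-mapping). Left-alignment is frame-dependent, so a variant diluted by
  alignment artefacts near a homopolymer in one frame is concentrated in
  the other; the passes must agree, and any discrepancy found in *either*
  pass is reported (union, deduplicated by kind/position/bases).

Verdict precedence: `contaminated` > `qc_fail` > `variant_detected` >
`inspect_required` (N calls or pass disagreement only) > `verified`.

## Synthetic data

`simulate_reads` emulates duplex-grade reads of a linearized plasmid:
full-template-length copies in both orientations (exact reverse count),
corrupted by an explicit error model. What it models:

- dispersed substitutions/insertions/deletions at configurable per-base
  rates;
- homopolymer run-length undercalling: per run ≥ 5 bases, either an
  explicit distribution over reported lengths or a binomial loss (each base
  beyond the 4th dropped independently, default probability 0.08);
- strand-specific systematic miscalls at designated template positions;
- ragged ends (uniform truncation up to `end_raggedness` per end);
- template mixtures at exact largest-remainder counts, with hidden per-read
  provenance for tests.

The default duplex-grade model is substitutions 5×10⁻⁴, insertions 2×10⁻⁴,
deletions 1×10⁻⁴ per base, binomial undercall 0.08, raggedness ≤ 5 —
dispersed point error near 0.1% with the remaining error mass concentrated
in homopolymers, which is where duplex-called nanopore residual error
actually sits. A `simplex` preset (≈5% error, indel-heavy) models
single-pass reads. Raggedness is kept at ≤ 5 so that terminal coverage
(≈17% at the outermost base) stays above the 10% retention floor; heavier
raggedness reproduces the known terminal coverage decay and may truncate
consensus ends — that is a property of the calling criteria, not a bug.

Base qualities default to a constant q=20 for all bases, *including* error
bases. An alternative `flag_errors` profile marks simulator-introduced
errors at q=10; it is not the default because the quality filter is a
per-read *minimum* — flagging every error base would make the default
filter discard every read carrying any error, leaving the consensus stages
nothing but perfect reads to chew on. The quality filter is instead
exercised by an explicit junk-read class (short fragments, concatemers,
reads with one q=11 base).

What the simulator does **not** model: raw-signal artefacts, chimeric
reads, basecaller-realistic quality score distributions, coverage bias, or
correlated errors beyond homopolymers and fixed strand-bias sites. Passing
tests therefore demonstrate the pipeline's logic — filtering semantics,
calling criteria, detection limits, contamination behavior — under
idealized noise, not its end-to-end accuracy on any particular instrument's
output.

## Detection limits measured here

On the exact mixture grid with error-free reads (1,000 reads per mixture,
3 kb template, defaults), the measured minimum detected variant fractions
are 20% for an SNV and a non-homopolymer insertion and 95% for a
non-homopolymer single-base deletion, matching the closed-form arithmetic
of the two criteria. Under the duplex-grade noisy model the three-SNV scan
detects each SNV by 20–25%. Detection is monotone on the grid for
noiseless reads. The deletion limit is a genuine blind spot of the 10%
coverage floor (needed for homopolymers); a context-dependent coverage
threshold (strict outside homopolymers, relaxed inside) would trade this
away at the cost of a second tunable, and is left out deliberately.

## Problem sizes and determinism

Tests and the acceptance script use 3 kb templates with 200–2,000 reads per
condition and 500-read draft subsamples — depths at which every threshold
in the method operates on hundreds of observations, so results are
insensitive to depth while remaining desk-scale. Every stochastic operation
takes an explicit seed (numpy `default_rng`); identical config + seed gives
byte-identical FASTQ/TSV/FASTA outputs. The alignment kernel is
numba-compiled; the first call in a fresh environment pays a one-time JIT
cost.
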