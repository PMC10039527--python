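# plasmidcheck

Sequence verification of linearized plasmids from nanopore-style long reads.

Plasmids used in research and clinical manufacturing must be verified
base-by-base before use: a single point mutation, insertion, or deletion —
or a subclonal variant present in part of the bacterial culture — can
invalidate downstream work. `plasmidcheck` implements a pileup-consensus
verification pipeline for duplex-grade long reads of a linearized plasmid,
for anyone who needs to confirm that a sequenced plasmid matches its
expected reference (or to characterize how it differs): read filtering,
strand pseudopairing, draft construction, dual-pass consensus calling with
per-base confidence, comparison against the expected sequence, and a
contamination check. A synthetic read simulator (error rates, homopolymer
run-length undercalling, strand-specific miscalls, template mixtures) makes
every stage testable without sequencing data.

## The method

Reads are full-template-length copies of the plasmid in either orientation.
After filtering (every base quality ≥ 12; read length within 250 bases of
the expected length), reads are aligned to a draft and tallied into a
*position array*: one column per draft base, one *between-base* column per
junction (plus 5′/3′ terminals), 2L+1 columns in all. Base columns count
observed bases and deletions; between columns count inserted bases by
offset, against the *pass-through* count of reads crossing the junction
without insertion.

At each column the most-evidenced base is added to the consensus iff

1. **ratio** — the top base count is at least 5× the second base count, and
2. **coverage** — the top base count is at least 10% of the maximum
   base-column depth.

Failing (1) alone emits an `N` (flagged for manual inspection); failing (2)
emits nothing. Per-base confidence is the percent of reads at the column
supporting the called base; the run passes QC when the median confidence
across the plasmid exceeds 99.9%. Because indel placement inside
homopolymers depends on the alignment frame, the consensus is computed
twice — against the draft and against its reverse complement — and the two
passes must agree.

These thresholds fix the subclonal-variant detection limits on an exact
mixture grid: SNVs and (non-homopolymer) insertions become detectable at a
20% variant fraction (0.80 < 5 × 0.20 fails the ratio test), while
single-base deletions stay invisible until 95% (a base retained by 10% of
templates still clears the coverage criterion at 90%). The low coverage
floor is deliberate: it is what keeps weakly supported homopolymer tails —
where reads systematically under-report run length — in the consensus at
full length.

Contamination by an unrelated plasmid of the same length is caught by the
*pseudopairing rate*: sense and antisense reads are paired by similar
length, but only reads with a single alignment to the expected reference
covering at least its length minus 500 bases qualify. A pairing rate below
90% of the filtered reads signals contamination; against a wrong reference
it is exactly 0%.

Alignment is a banded Gotoh dynamic program (affine gaps, free end gaps,
match +2 / mismatch −4 / gap open −4 / gap extend −2) with indels
normalized to their leftmost placement in homopolymers; since reads are
colinear with the reference, no seed-and-extend heuristics are needed.
Pre-computed PAF alignments from an external aligner are also accepted.

## Worked example

Simulate a duplex-grade run of a 3 kb plasmid containing a 17-base
homopolymer, then verify it against its own reference:

```bash
plasmidcheck simulate --length 3000 --n-reads 300 --seed 7 \
    --error-model duplex --homopolymer 1500:A:17 \
    --reads-out reads.fastq --reference-out expected.fasta
plasmidcheck verify reads.fastq expected.fasta --out-dir out --seed 1
```

The run log shows the read funnel and verdict:

```
reads in: 300
quality pass: 300  length pass: 300  qualified: 300  paired: 300
verdict: verified
```

`out/report.json` holds the machine-readable summary — pairing rate 100.0%,
median per-base confidence 100.0% in both passes, pass agreement `true`, no
discrepancies, so the verdict is `verified`. `out/positions_forward.tsv`
has one row per pileup column; a clean base column and its junction look
like:

```
column  kind     A   C  G  T  gap_or_pass  ...  top_base  top_count  confidence_pct  signal_noise  status
751     base     299 0  1  0  0                 A         299        99.67           299.00        base
751/752 between  0   0  0  0  300               .         0          100.00          inf           no_insertion
```

A variant plasmid instead yields `verdict: variant_detected` with each
discrepancy typed (SNV / insertion / deletion / N_call), positioned on the
expected reference, and annotated with its top/second counts. The
`mixscan` command runs the subclonal sensitivity experiment: mixtures of
wildtype and variant reads from 0–100% in 5% steps, reporting the minimum
fraction at which each mutation is detected.

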