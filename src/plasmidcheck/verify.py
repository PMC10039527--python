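"""Consensus-versus-expected comparison, verdicts, and the mixture scan.

A sequenced plasmid is *verified* when both consensus passes match the
expected reference exactly, both pass the median-confidence QC, the passes
agree with each other, and the pseudopairing rate shows no contamination.
Any discrepancy found in either pass is reported (union over passes);
N calls are flagged for manual inspection rather than treated as variants.

The mixture scan reproduces the subclonal-variant sensitivity experiment:
wildtype and variant reads are mixed in silico on a 0-100% grid in 5%
increments, the full consensus pipeline is run on each mixture, and each
mutation's minimum detected variant fraction is recorded. With the default
calling thresholds (5x ratio, 10% coverage) the theoretical limits are 20%
for SNVs and insertions and >90% for deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import OP_DELETION, OP_INSERTION, OP_MISMATCH, align_read
from .pileup import (
    ConsensusResult,
    DEFAULT_COVERAGE_FRACTION,
    DEFAULT_RATIO_THRESHOLD,
    build_draft,
    dual_pass_consensus,
)
from .pseudopair import DEFAULT_PAIRING_RATE_THRESHOLD, contamination_check
from .readfilter import FilterConfig, apply_filters
from .seqio import SequencedRead, TemplateSequence
from .simulate import ErrorModel, MutationSpec, simulate_mixture


@dataclass
class Discrepancy:
    """One difference between a consensus pass and the expected reference."""

    kind: str  # "SNV" | "insertion" | "deletion" | "N_call"
    position: int  # 1-based on the expected reference
    expected_base: str
    observed_base: str
    passes: list[str] = field(default_factory=list)
    top_count: int | None = None
    second_count: int | None = None
    confidence: float | None = None

    @property
    def key(self) -> tuple:
        return (self.kind, self.position, self.expected_base, self.observed_base)


@dataclass
class VerificationReport:
    verdict: str  # verified | variant_detected | inspect_required | contaminated | qc_fail
    discrepancies: list[Discrepancy]
    pairing_rate: float | None
    median_confidence: dict[str, float]
    qc_pass: dict[str, bool]
    agreement: bool

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "pairing_rate": self.pairing_rate,
            "median_confidence": self.median_confidence,
            "qc_pass": self.qc_pass,
            "agreement": self.agreement,
            "discrepancies": [
                {
                    "kind": d.kind,
                    "position": d.position,
                    "expected": d.expected_base,
                    "observed": d.observed_base,
                    "passes": d.passes,
                    "top_count": d.top_count,
                    "second_count": d.second_count,
                    "confidence": d.confidence,
                }
                for d in self.discrepancies
            ],
        }


def compare_to_expected(
    consensus: ConsensusResult,
    expected: TemplateSequence,
    band_width: int = 600,
) -> list[Discrepancy]:
    """Globally align a consensus to the expected reference and type every
    difference. Positions are 1-based on the expected reference; indels are
    left-aligned by the aligner. N columns become N_call discrepancies
    carrying the underlying top/second counts for manual inspection."""
    if not consensus.sequence:
        raise ValueError("empty consensus")
    read = SequencedRead(
        read_id="consensus",
        sequence=consensus.sequence,
        qualities=np.full(len(consensus.sequence), 40, dtype=np.int16),
    )
    aln = align_read(read, expected, band_width=band_width)
    if aln.strand != "forward":
        raise ValueError(
            "consensus aligns to the expected reference in reverse orientation"
        )
    emitted = [c for c in consensus.calls if c.status in ("base", "N")]

    out: list[Discrepancy] = []

    def counts_for(seq_pos: int):
        if 0 <= seq_pos < len(emitted):
            c = emitted[seq_pos]
            return c.top_count, c.second_count, c.confidence
        return None, None, None

    for op, rp, qp in zip(aln.ops, aln.ref_pos, aln.read_pos):
        if op == OP_MISMATCH:
            obs = consensus.sequence[qp]
            top, second, conf = counts_for(qp)
            out.append(
                Discrepancy(
                    kind="N_call" if obs == "N" else "SNV",
                    position=int(rp) + 1,
                    expected_base=expected.sequence[rp],
                    observed_base=obs,
                    top_count=top,
                    second_count=second,
                    confidence=conf,
                )
            )
        elif op == OP_INSERTION:
            obs = consensus.sequence[qp]
            top, second, conf = counts_for(qp)
            out.append(
                Discrepancy(
                    kind="N_call" if obs == "N" else "insertion",
                    position=int(rp),  # inserted after this 1-based position
                    expected_base="",
                    observed_base=obs,
                    top_count=top,
                    second_count=second,
                    confidence=conf,
                )
            )
        elif op == OP_DELETION:
            out.append(
                Discrepancy(
                    kind="deletion",
                    position=int(rp) + 1,
                    expected_base=expected.sequence[rp],
                    observed_base="",
                )
            )

    # free end gaps: expected bases or consensus bases falling outside the
    # aligned span are still real differences
    s, e = aln.aligned_span
    for p in range(0, s):
        out.append(
            Discrepancy(
                kind="deletion",
                position=p + 1,
                expected_base=expected.sequence[p],
                observed_base="",
            )
        )
    for p in range(e, expected.length):
        out.append(
            Discrepancy(
                kind="deletion",
                position=p + 1,
                expected_base=expected.sequence[p],
                observed_base="",
            )
        )
    qmin = int(aln.read_pos[aln.read_pos >= 0].min()) if len(aln.read_pos) else 0
    qmax = int(aln.read_pos.max()) if len(aln.read_pos) else -1
    for q in range(0, qmin):
        obs = consensus.sequence[q]
        out.append(
            Discrepancy(
                kind="N_call" if obs == "N" else "insertion",
                position=0,
                expected_base="",
                observed_base=obs,
            )
        )
    for q in range(qmax + 1, len(consensus.sequence)):
        obs = consensus.sequence[q]
        out.append(
            Discrepancy(
                kind="N_call" if obs == "N" else "insertion",
                position=expected.length,
                expected_base="",
                observed_base=obs,
            )
        )
    for d in out:
        d.passes = [consensus.pass_label]
    return sorted(out, key=lambda d: (d.position, d.kind))


def assemble_report(
    forward_discrepancies: Sequence[Discrepancy],
    reverse_discrepancies: Sequence[Discrepancy],
    forward_consensus: ConsensusResult,
    reverse_consensus: ConsensusResult,
    agreement: bool,
    pairing_rate: float | None = None,
    pairing_rate_threshold: float = DEFAULT_PAIRING_RATE_THRESHOLD,
) -> VerificationReport:
    """Union of discrepancies over the two passes and the final verdict.

    Verdict precedence: contaminated > qc_fail > variant_detected >
    inspect_required (N calls or pass disagreement only) > verified.
    """
    merged: dict[tuple, Discrepancy] = {}
    for d in list(forward_discrepancies) + list(reverse_discrepancies):
        if d.key in merged:
            for p in d.passes:
                if p not in merged[d.key].passes:
                    merged[d.key].passes.append(p)
        else:
            merged[d.key] = Discrepancy(**{**d.__dict__, "passes": list(d.passes)})
    discrepancies = sorted(merged.values(), key=lambda d: (d.position, d.kind))

    contaminated = pairing_rate is not None and contamination_check(
        pairing_rate, pairing_rate_threshold
    )
    qc = {
        "forward_draft": forward_consensus.qc_pass,
        "reverse_draft": reverse_consensus.qc_pass,
    }
    has_variant = any(d.kind != "N_call" for d in discrepancies)
    has_n = any(d.kind == "N_call" for d in discrepancies)
    if contaminated:
        verdict = "contaminated"
    elif not all(qc.values()):
        verdict = "qc_fail"
    elif has_variant:
        verdict = "variant_detected"
    elif has_n or not agreement:
        verdict = "inspect_required"
    else:
        verdict = "verified"
    return VerificationReport(
        verdict=verdict,
        discrepancies=discrepancies,
        pairing_rate=pairing_rate,
        median_confidence={
            "forward_draft": forward_consensus.median_confidence,
            "reverse_draft": reverse_consensus.median_confidence,
        },
        qc_pass=qc,
        agreement=agreement,
    )


def mutations_from_templates(
    wildtype: TemplateSequence, variant: TemplateSequence, band_width: int = 600
) -> list[MutationSpec]:
    """Infer the wildtype -> variant edit list by pairwise alignment."""
    read = SequencedRead(
        read_id="variant",
        sequence=variant.sequence,
        qualities=np.full(variant.length, 40, dtype=np.int16),
    )
    aln = align_read(read, wildtype, band_width=band_width)
    muts: list[MutationSpec] = []
    for op, rp, qp in zip(aln.ops, aln.ref_pos, aln.read_pos):
        if op == OP_MISMATCH:
            muts.append(
                MutationSpec(
                    kind="SNV",
                    position=int(rp) + 1,
                    ref_base=wildtype.sequence[rp],
                    alt_base=variant.sequence[qp],
                )
            )
        elif op == OP_INSERTION:
            muts.append(
                MutationSpec(
                    kind="insertion",
                    position=max(int(rp), 1),
                    alt_base=variant.sequence[qp],
                )
            )
        elif op == OP_DELETION:
            muts.append(
                MutationSpec(
                    kind="deletion",
                    position=int(rp) + 1,
                    ref_base=wildtype.sequence[rp],
                )
            )
    return muts


DEFAULT_FRACTIONS = tuple(range(0, 101, 5))


@dataclass
class MixtureScanResult:
    """Per-mutation minimum detected variant fraction on the scan grid."""

    minimum_detected: dict[str, int | None]  # mutation label -> % or None
    detected_at: dict[str, list[int]]  # mutation label -> all detected fractions
    fractions: tuple[int, ...]

    def rows(self):
        for label, mn in self.minimum_detected.items():
            yield label, ("not_detected" if mn is None else mn)


def _detected_positions(discrepancies: Sequence[Discrepancy]) -> list[int]:
    return [d.position for d in discrepancies]


def mixture_scan(
    wildtype: TemplateSequence,
    variant: TemplateSequence,
    mutations: Sequence[MutationSpec],
    n_reads: int = 10_000,
    fractions: Sequence[int] = DEFAULT_FRACTIONS,
    error_model: ErrorModel | None = None,
    seed: int = 0,
    position_window: int = 10,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
    draft_subsample: int = 500,
    band_width: int = 600,
) -> MixtureScanResult:
    """Scan variant-read fractions and find each mutation's detection limit.

    At each fraction, ``n_reads`` total reads are simulated from the
    wildtype/variant mixture (exact counts), the full pipeline runs (draft
    built from the mixed reads, dual-pass consensus), and both passes are
    compared to the *wildtype* expected sequence. A mutation counts as
    detected when either pass shows any discrepancy (N, changed base, novel
    insertion, or dropped base) within ``position_window`` bases of it.
    """
    for f in fractions:
        if not 0 <= f <= 100:
            raise ValueError(f"fraction {f} outside [0, 100]")
    if not mutations:
        raise ValueError("templates identical: no mutations to scan for")
    rng = np.random.default_rng(seed)
    model = error_model or ErrorModel.error_free()
    detected_at: dict[str, list[int]] = {m.label: [] for m in mutations}

    for f in fractions:
        mix_seed = int(rng.integers(0, 2**31 - 1))
        reads = simulate_mixture(
            [(wildtype, 1 - f / 100.0), (variant, f / 100.0)],
            n_reads,
            model,
            seed=mix_seed,
        )
        cfg = FilterConfig(expected_length=wildtype.length)
        filtered, _ = apply_filters(reads, cfg)
        if not filtered:
            continue
        draft = build_draft(
            filtered,
            subsample_size=draft_subsample,
            seed=mix_seed,
            band_width=band_width,
            coverage_fraction=coverage_fraction,
        )
        fwd, rev, _agree, _draft = dual_pass_consensus(
            filtered,
            draft,
            band_width=band_width,
            ratio_threshold=ratio_threshold,
            coverage_fraction=coverage_fraction,
            expected=wildtype,
        )
        positions = _detected_positions(
            compare_to_expected(fwd, wildtype, band_width)
        ) + _detected_positions(compare_to_expected(rev, wildtype, band_width))
        for m in mutations:
            if any(abs(p - m.position) <= position_window for p in positions):
                detected_at[m.label].append(f)

    minimum = {
        label: (min(fs) if fs else None) for label, fs in detected_at.items()
    }
    return MixtureScanResult(
        minimum_detected=minimum, detected_at=detected_at, fractions=tuple(fractions)
    )
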