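"""End-to-end verification workflow and its configuration.

The published workflow, as one function: quality/length filtering,
strand classification and pseudopairing against the expected reference
(yielding the contamination metric), optional pair collapsing, draft
construction from the reads themselves, dual-pass pileup consensus, and
comparison to the expected sequence. Every numeric threshold lives in
PipelineConfig and is serialized verbatim into the run summary.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

from .align import align_read
from .pileup import (
    DEFAULT_COVERAGE_FRACTION,
    DEFAULT_DRAFT_SUBSAMPLE,
    DEFAULT_MEDIAN_CONFIDENCE,
    DEFAULT_RATIO_THRESHOLD,
    ConsensusResult,
    build_draft,
    dual_pass_consensus,
)
from .pseudopair import (
    DEFAULT_PAIRING_RATE_THRESHOLD,
    DEFAULT_QUALIFICATION_SLACK,
    PseudopairSet,
    collapse_pair,
    make_pseudopairs,
    qualify_reads,
)
from .readfilter import FilterConfig, apply_filters
from .seqio import SequencedRead, TemplateSequence
from .verify import VerificationReport, assemble_report, compare_to_expected


class InsufficientDataError(RuntimeError):
    """No reads survive filtering/qualification."""


@dataclass
class PipelineConfig:
    """All pipeline thresholds (defaults are the published operating point)."""

    min_qscore: int = 12
    length_tolerance: int = 250
    pair_qualification_slack: int = DEFAULT_QUALIFICATION_SLACK
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION
    median_confidence_threshold: float = DEFAULT_MEDIAN_CONFIDENCE
    pairing_rate_threshold: float = DEFAULT_PAIRING_RATE_THRESHOLD
    draft_subsample: int = DEFAULT_DRAFT_SUBSAMPLE
    band_width: int = 600
    seed: int = 0
    collapse_mode: bool = False

    def __post_init__(self):
        if self.min_qscore < 0 or self.length_tolerance < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.ratio_threshold < 1:
            raise ValueError("ratio_threshold must be >= 1")
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if not 0 <= self.pairing_rate_threshold <= 100:
            raise ValueError("pairing_rate_threshold must be a percentage")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    report: VerificationReport
    forward_consensus: ConsensusResult
    reverse_consensus: ConsensusResult
    draft: TemplateSequence
    counters: dict
    pairing: PseudopairSet | None

    def summary(self, config: PipelineConfig) -> dict:
        fwd_sn = self.forward_consensus.min_signal_noise()
        rev_sn = self.reverse_consensus.min_signal_noise()
        return {
            "config": config.to_dict(),
            "counters": self.counters,
            "pairing_rate": None if self.pairing is None else self.pairing.pairing_rate,
            "qualified_reads": None
            if self.pairing is None
            else self.pairing.qualified_count,
            "pseudopairs": None if self.pairing is None else len(self.pairing.pairs),
            "draft_length": self.draft.length,
            "min_signal_noise": {
                "forward_draft": {"value": fwd_sn[0], "column": fwd_sn[1]},
                "reverse_draft": {"value": rev_sn[0], "column": rev_sn[1]},
            },
            "report": self.report.to_dict(),
        }


def run_verification(
    reads: Sequence[SequencedRead],
    expected: TemplateSequence,
    config: PipelineConfig | None = None,
    compute_pairing: bool = True,
) -> PipelineResult:
    """Filter -> pseudopair -> (collapse) -> draft -> dual-pass -> verdict."""
    cfg = config or PipelineConfig()
    fcfg = FilterConfig(
        expected_length=expected.length,
        min_qscore=cfg.min_qscore,
        length_tolerance=cfg.length_tolerance,
    )
    filtered, counters = apply_filters(reads, fcfg)
    if not filtered:
        raise InsufficientDataError("no reads survive the quality/length filters")

    pairing = None
    pairing_rate = None
    if compute_pairing or cfg.collapse_mode:
        alignments = [
            align_read(r, expected, band_width=cfg.band_width) for r in filtered
        ]
        fwd_q, rev_q = qualify_reads(
            alignments, expected.length, slack=cfg.pair_qualification_slack
        )
        pairing = make_pseudopairs(fwd_q, rev_q, filtered_input_count=len(filtered))
        pairing_rate = pairing.pairing_rate
        counters["qualified"] = pairing.qualified_count
        counters["paired"] = 2 * len(pairing.pairs)

    if cfg.collapse_mode:
        by_id = {r.read_id: r for r in filtered}
        consensus_reads = [
            collapse_pair(by_id[f], by_id[r]) for f, r in pairing.pairs
        ]
        if not consensus_reads:
            raise InsufficientDataError("no pseudopairs available to collapse")
    else:
        # pre-collapsed mode: input reads are treated as already duplex-grade
        consensus_reads = filtered

    draft = build_draft(
        consensus_reads,
        subsample_size=cfg.draft_subsample,
        seed=cfg.seed,
        band_width=cfg.band_width,
        coverage_fraction=cfg.coverage_fraction,
    )
    fwd, rev, agreement, draft = dual_pass_consensus(
        consensus_reads,
        draft,
        band_width=cfg.band_width,
        ratio_threshold=cfg.ratio_threshold,
        coverage_fraction=cfg.coverage_fraction,
        median_confidence_threshold=cfg.median_confidence_threshold,
        expected=expected,
    )
    report = assemble_report(
        compare_to_expected(fwd, expected, cfg.band_width),
        compare_to_expected(rev, expected, cfg.band_width),
        fwd,
        rev,
        agreement,
        pairing_rate=pairing_rate,
        pairing_rate_threshold=cfg.pairing_rate_threshold,
    )
    return PipelineResult(
        report=report,
        forward_consensus=fwd,
        reverse_consensus=rev,
        draft=draft,
        counters=counters,
        pairing=pairing,
    )
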