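"""Read quality and length filters.

A read is kept by the quality filter only if *every* base meets the minimum
quality score (the per-read minimum, not the mean), and by the length filter
only if its length is within the tolerance of the expected template length
(inclusive on both boundaries). Filters are idempotent and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seqio import SequencedRead


@dataclass(frozen=True)
class FilterConfig:
    """Quality/length filter thresholds.

    min_qscore: minimum per-base Phred quality a read's worst base must meet.
    length_tolerance: allowed |read length - expected length| in bases.
    expected_length: the expected (reference) template length.
    """

    expected_length: int
    min_qscore: int = 12
    length_tolerance: int = 250

    def __post_init__(self):
        if self.min_qscore < 0:
            raise ValueError("min_qscore must be >= 0")
        if self.length_tolerance < 0:
            raise ValueError("length_tolerance must be >= 0")
        if self.expected_length <= 0:
            raise ValueError("expected_length must be > 0")


def filter_by_quality(
    reads: Sequence[SequencedRead], min_qscore: int = 12
) -> tuple[list[SequencedRead], int]:
    """Keep reads whose minimum base quality is >= min_qscore."""
    kept = [r for r in reads if len(r) and r.min_quality >= min_qscore]
    return kept, len(reads) - len(kept)


def filter_by_length(
    reads: Sequence[SequencedRead], expected_length: int, tolerance: int = 250
) -> tuple[list[SequencedRead], int]:
    """Keep reads with |length - expected_length| <= tolerance (inclusive)."""
    if expected_length <= 0:
        raise ValueError("expected_length must be > 0")
    kept = [r for r in reads if abs(len(r) - expected_length) <= tolerance]
    return kept, len(reads) - len(kept)


def apply_filters(
    reads: Sequence[SequencedRead], config: FilterConfig
) -> tuple[list[SequencedRead], dict]:
    """Run quality then length filter; return kept reads and stage counters."""
    after_quality, rej_q = filter_by_quality(reads, config.min_qscore)
    after_length, rej_l = filter_by_length(
        after_quality, config.expected_length, config.length_tolerance
    )
    counters = {
        "input": len(reads),
        "after_quality": len(after_quality),
        "after_length": len(after_length),
        "rejected_quality": rej_q,
        "rejected_length": rej_l,
    }
    return after_length, counters
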