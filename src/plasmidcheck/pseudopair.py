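"""Pseudopairing of sense and antisense reads.

Every read from a pure linearized-plasmid library carries the same sequence
in one of two orientations, so a sense read and an antisense read of similar
length can be paired as if they were the two strands of one molecule. Strand
comes from the alignment to the expected reference; a read qualifies for
pairing only if it has a single alignment whose matched-base count is no
shorter than the reference length minus a slack (500 bases by default).

The fraction of filtered reads that end up in pairs is itself a QC metric:
reads from a contaminating, unrelated plasmid do not qualify, so a pairing
rate below 90% signals contamination (it is exactly 0% against a wrong
reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import PairwiseAlignment, encode, decode, reverse_complement
from .seqio import SequencedRead

DEFAULT_QUALIFICATION_SLACK = 500
DEFAULT_PAIRING_RATE_THRESHOLD = 90.0


@dataclass
class PseudopairSet:
    """Pairing outcome: pairs, leftovers, and the pairing-rate metric.

    pairing_rate is 100 * (2 * |pairs|) / filtered_input_count — i.e. the
    percentage of quality- and length-filtered reads that were successfully
    pseudopaired (not of qualified reads).
    """

    pairs: list[tuple[str, str]]
    unpaired_forward: list[str]
    unpaired_reverse: list[str]
    qualified_count: int
    filtered_input_count: int

    @property
    def pairing_rate(self) -> float:
        if self.filtered_input_count == 0:
            return 0.0
        return 100.0 * (2 * len(self.pairs)) / self.filtered_input_count


def qualify_reads(
    alignments: Sequence[PairwiseAlignment],
    reference_length: int,
    slack: int = DEFAULT_QUALIFICATION_SLACK,
) -> tuple[list[PairwiseAlignment], list[PairwiseAlignment]]:
    """Partition qualifying alignments by strand.

    A read qualifies iff it is not multi-alignment and its matched-base
    count is at least reference_length - slack (inclusive).
    """
    threshold = reference_length - slack
    forward, reverse = [], []
    for aln in alignments:
        if aln.multi_alignment or aln.match_count < threshold:
            continue
        (forward if aln.strand == "forward" else reverse).append(aln)
    return forward, reverse


def make_pseudopairs(
    forward: Sequence[PairwiseAlignment],
    reverse: Sequence[PairwiseAlignment],
    filtered_input_count: int,
) -> PseudopairSet:
    """Pair sense and antisense reads by similar length.

    Both lists are sorted ascending by read length (ties broken by read id)
    and zipped index-by-index; the longer list's tail stays unpaired.
    """
    key = lambda a: (a.read_length, a.read_id)
    fwd = sorted(forward, key=key)
    rev = sorted(reverse, key=key)
    n = min(len(fwd), len(rev))
    return PseudopairSet(
        pairs=[(fwd[i].read_id, rev[i].read_id) for i in range(n)],
        unpaired_forward=[a.read_id for a in fwd[n:]],
        unpaired_reverse=[a.read_id for a in rev[n:]],
        qualified_count=len(fwd) + len(rev),
        filtered_input_count=filtered_input_count,
    )


def contamination_check(
    pairing_rate: float, threshold: float = DEFAULT_PAIRING_RATE_THRESHOLD
) -> bool:
    """Flag contamination iff pairing_rate < threshold (strict)."""
    return pairing_rate < threshold


class PairingError(ValueError):
    """A putative pseudopair whose members do not align to each other."""


def collapse_pair(
    forward: SequencedRead,
    reverse: SequencedRead,
    indel_quality_threshold: int = 0,
    min_identity: float = 80.0,
) -> SequencedRead:
    """Collapse a pseudopair into one higher-accuracy read.

    This is a sequence-level stand-in for raw-signal duplex basecalling: the
    reverse read is reverse-complemented, the two sequences are aligned to
    each other, and per column agreement emits the shared base, substitution
    disagreement emits the higher-quality base (N on a quality tie), and a
    one-sided gap emits the present base only if its quality is at least
    ``indel_quality_threshold`` (default 0: always emit). Output qualities
    are the per-column maximum of the contributing qualities.
    """
    from .align import align_read  # local import to keep module load light

    rc_seq = reverse_complement(reverse.sequence)
    rc_quals = reverse.qualities[::-1].copy()
    aln = align_read(
        SequencedRead(read_id=reverse.read_id, sequence=rc_seq, qualities=rc_quals),
        forward.sequence,
        band_width=600,
    )
    n_cols = max(len(aln.ops), 1)
    identity = 100.0 * aln.match_count / n_cols
    if identity < min_identity:
        raise PairingError(
            f"pair {forward.read_id!r}/{reverse.read_id!r}: alignment identity "
            f"{identity:.1f}% < {min_identity}%"
        )

    fwd_codes = encode(forward.sequence)
    rev_codes = encode(rc_seq)
    out_seq: list[int] = []
    out_qual: list[int] = []
    N = 4
    for op, fpos, rpos in zip(aln.ops, aln.ref_pos, aln.read_pos):
        if op == 0:  # agreement
            out_seq.append(int(fwd_codes[fpos]))
            out_qual.append(max(int(forward.qualities[fpos]), int(rc_quals[rpos])))
        elif op == 1:  # substitution disagreement: higher quality wins, N on tie
            qf = int(forward.qualities[fpos])
            qr = int(rc_quals[rpos])
            if qf > qr:
                out_seq.append(int(fwd_codes[fpos]))
                out_qual.append(qf)
            elif qr > qf:
                out_seq.append(int(rev_codes[rpos]))
                out_qual.append(qr)
            else:
                out_seq.append(N)
                out_qual.append(qf)
        elif op == 2:  # base only in the reverse read
            q = int(rc_quals[rpos])
            if q >= indel_quality_threshold:
                out_seq.append(int(rev_codes[rpos]))
                out_qual.append(q)
        else:  # base only in the forward read
            q = int(forward.qualities[fpos])
            if q >= indel_quality_threshold:
                out_seq.append(int(fwd_codes[fpos]))
                out_qual.append(q)
    return SequencedRead(
        read_id=f"{forward.read_id}|{reverse.read_id}",
        sequence=decode(np.array(out_seq, dtype=np.uint8)),
        qualities=np.array(out_qual, dtype=np.int16),
    )
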