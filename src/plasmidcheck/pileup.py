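"""Pileup construction and consensus calling with per-base confidence.

The pileup is a position array over a draft of length L: one column per
draft base, one *between-base* column per adjacent base pair, plus 5' and 3'
terminal columns (2L + 1 columns in all). Base columns tally the bases and
deletions observed at that draft position; between columns tally inserted
bases by offset (the first inserted base at a junction is offset 0, the
second offset 1, ...) together with the *pass-through* count, the number of
reads aligned across the junction without inserting anything.

Consensus calling takes the most-evidenced base at each column subject to
two criteria: (1) the top base must be at least 5x as abundant as the second
top base, and (2) the top base's coverage must be at least 10% of the
maximum base-column depth. Failing (1) alone emits an N (a flag for manual
inspection); failing (2) emits nothing (the base is dropped). At base
columns deletions are excluded from the ratio contest and compete only
through criterion (2) — this is what limits subclonal-deletion sensitivity
while letting weakly-supported homopolymer tails survive. At between
columns the pass-through count competes in the ratio when it leads (which
sets the ~20% insertion detection limit); when an inserted base leads, the
ratio is taken against the second inserted base, mirroring the gap
exclusion at base columns.

Per-base confidence is the percent of reads at a column supporting the
called base; the run-level QC statistic is the median over all called
bases, required to exceed 99.9%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import (
    OP_DELETION,
    OP_INSERTION,
    OP_MISMATCH,
    PairwiseAlignment,
    align_read,
    reverse_complement,
)
from .seqio import SequencedRead, TemplateSequence

DEFAULT_RATIO_THRESHOLD = 5.0
DEFAULT_COVERAGE_FRACTION = 0.10
DEFAULT_MEDIAN_CONFIDENCE = 99.9
DEFAULT_DRAFT_SUBSAMPLE = 500

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "": ""}


class PileupMatrix:
    """Per-column observation counts over the draft position array."""

    def __init__(self, draft: TemplateSequence):
        L = draft.length
        self.draft = draft
        self.draft_length = L
        self.base_counts = np.zeros((L, 4), dtype=np.int64)
        self.gap_counts = np.zeros(L, dtype=np.int64)
        # junction j sits between draft bases j-1 and j; j=0 and j=L are the
        # 5' and 3' terminal columns
        self.spanning = np.zeros(L + 1, dtype=np.int64)
        # junction -> list (by offset) of per-base insertion counts
        self.insertions: dict[int, list[np.ndarray]] = {}
        # read bases overhanging the draft ends (reads are globally aligned
        # with free end gaps, so bases beyond the draft are otherwise
        # invisible); offset 0 is the base adjacent to the draft terminus
        self.five_prime_overhang: list[np.ndarray] = []
        self.three_prime_overhang: list[np.ndarray] = []
        self.max_overhang = 200
        self.n_reads = 0

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=1) + self.gap_counts

    @property
    def max_coverage(self) -> int:
        return int(self.depth.max())

    def insertion_columns(self, junction: int) -> list[np.ndarray]:
        return self.insertions.get(junction, [])

    def add_alignment(self, aln: PairwiseAlignment) -> None:
        if aln.read_codes is None:
            raise ValueError("alignment lacks read base codes")
        ops = aln.ops
        rp = aln.ref_pos
        qp = aln.read_pos
        if rp.size and (rp.min() < 0 or rp.max() > self.draft_length):
            raise ValueError("alignment references positions outside the draft")

        sub = ops <= 1  # match | mismatch
        if sub.any():
            bases = aln.read_codes[qp[sub]]
            ok = bases < 4  # read Ns are not counted anywhere
            np.add.at(self.base_counts, (rp[sub][ok], bases[ok]), 1)
        dels = ops == OP_DELETION
        if dels.any():
            np.add.at(self.gap_counts, rp[dels], 1)
        ins = ops == OP_INSERTION
        if ins.any():
            idx = np.nonzero(ins)[0]
            offset = 0
            prev_j = -1
            prev_t = -2
            for t in idx:
                j = int(rp[t])
                # consecutive insertion columns at one junction advance the offset
                offset = offset + 1 if (j == prev_j and t == prev_t + 1) else 0
                prev_j = j
                prev_t = int(t)
                base = int(aln.read_codes[qp[t]])
                if base >= 4:
                    continue
                cols = self.insertions.setdefault(j, [])
                while len(cols) <= offset:
                    cols.append(np.zeros(4, dtype=np.int64))
                cols[offset][base] += 1

        s, e = aln.aligned_span
        if e > s:
            js = 0 if s == 0 else s + 1
            je = self.draft_length if e == self.draft_length else e - 1
            if je >= js:
                self.spanning[js : je + 1] += 1
        self._add_overhangs(aln, s, e)
        self.n_reads += 1

    def _add_overhangs(self, aln: PairwiseAlignment, s: int, e: int) -> None:
        consumed = aln.ops != OP_DELETION
        if not consumed.any():
            return
        qp = aln.read_pos[consumed]
        codes = aln.read_codes
        if s == 0 and qp[0] > 0:
            over = codes[qp[0] - 1 :: -1][: self.max_overhang]
            for off, base in enumerate(over):
                if base >= 4:
                    continue
                while len(self.five_prime_overhang) <= off:
                    self.five_prime_overhang.append(np.zeros(4, dtype=np.int64))
                self.five_prime_overhang[off][base] += 1
        if e == self.draft_length and qp[-1] + 1 < len(codes):
            over = codes[qp[-1] + 1 :][: self.max_overhang]
            for off, base in enumerate(over):
                if base >= 4:
                    continue
                while len(self.three_prime_overhang) <= off:
                    self.three_prime_overhang.append(np.zeros(4, dtype=np.int64))
                self.three_prime_overhang[off][base] += 1


def build_pileup(
    alignments: Sequence[PairwiseAlignment], draft: TemplateSequence
) -> PileupMatrix:
    """Tally all alignments (computed against the draft) into a pileup."""
    pm = PileupMatrix(draft)
    for aln in alignments:
        pm.add_alignment(aln)
    return pm


@dataclass
class PositionCall:
    """The calling outcome at one pileup column (or insertion sub-column)."""

    column_id: str
    kind: str  # "base" | "between" | "terminal"
    status: str  # "base" | "N" | "dropped" | "no_insertion"
    called_base: str = ""
    top_base: str = ""
    top_count: int = 0
    second_base: str = ""
    second_count: int = 0
    confidence: float | None = None  # percent
    signal_noise: float | None = None
    counts: dict = field(default_factory=dict)
    gap_or_pass: int = 0
    depth: int = 0
    insertion_counts: list = field(default_factory=list)  # (offset, base, count)


@dataclass
class ConsensusResult:
    """A called consensus with its per-position evidence and QC verdict."""

    sequence: str
    calls: list[PositionCall]
    median_confidence: float
    qc_pass: bool
    pass_label: str  # "forward_draft" | "reverse_draft"
    n_calls_N: int = 0

    def min_signal_noise(self) -> tuple[float, str]:
        """Smallest finite signal:noise over called bases and its column."""
        best = (float("inf"), "")
        for c in self.calls:
            if c.status == "base" and c.signal_noise is not None:
                if c.signal_noise < best[0]:
                    best = (c.signal_noise, c.column_id)
        return best

    def percent_identity_to(self, template: TemplateSequence) -> float:
        """Percent identity of this consensus to a template (global)."""
        aln = align_read(
            SequencedRead(
                read_id="consensus",
                sequence=self.sequence,
                qualities=np.full(len(self.sequence), 40, dtype=np.int16),
            ),
            template,
            band_width=600,
        )
        span = max(len(template.sequence), len(self.sequence))
        return 100.0 * aln.match_count / span


def _top_two(counts: np.ndarray) -> tuple[int, int, int, int]:
    """(top index, top count, second index, second count); ties on the top
    count are reported deterministically in A<C<G<T order."""
    top = int(np.argmax(counts))
    top_count = int(counts[top])
    rest = counts.copy()
    rest[top] = -1
    second = int(np.argmax(rest))
    return top, top_count, second, int(counts[second])


def call_base_column(
    counts: np.ndarray,
    gap_count: int,
    max_coverage: int,
    column_id: str,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
) -> PositionCall:
    """Call one base column. Deletions (gap_count) are excluded from the
    ratio contest and act only through the coverage criterion."""
    top, top_count, second, second_count = _top_two(counts)
    depth = int(counts.sum()) + int(gap_count)
    call = PositionCall(
        column_id=column_id,
        kind="base",
        status="dropped",
        top_base=_BASES[top] if top_count else "",
        top_count=top_count,
        second_base=_BASES[second] if second_count else "",
        second_count=second_count,
        counts={b: int(c) for b, c in zip(_BASES, counts)},
        gap_or_pass=int(gap_count),
        depth=depth,
    )
    if depth > 0:
        call.confidence = 100.0 * top_count / depth
    call.signal_noise = (
        float("inf") if second_count == 0 else top_count / second_count
    )
    if top_count < coverage_fraction * max_coverage or top_count == 0:
        call.status = "dropped"
    elif int(np.sum(counts == top_count)) > 1 or top_count < ratio_threshold * second_count:
        call.status = "N"
        call.called_base = "N"
    else:
        call.status = "base"
        call.called_base = _BASES[top]
    return call


def call_between_column(
    insertion_cols: list[np.ndarray],
    spanning: int,
    max_coverage: int,
    column_id: str,
    kind: str = "between",
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
) -> list[PositionCall]:
    """Call a between-base column, one sub-column per insertion offset.

    At each offset the candidates are the inserted bases at that offset and
    the *stop* count (reads spanning the junction whose insertion is shorter
    than the offset; at offset 0 this is the classic pass-through). When the
    stop count leads it competes in the ratio test; when an inserted base
    leads, the ratio is taken against the second inserted base. Evaluation
    stops at the first offset whose status is no_insertion or dropped.
    """
    calls: list[PositionCall] = []
    offset = 0
    while True:
        ext = (
            insertion_cols[offset]
            if offset < len(insertion_cols)
            else np.zeros(4, dtype=np.int64)
        )
        n_continue = int(ext.sum())
        stop = max(int(spanning) - n_continue, 0)
        top, top_count, second, second_count = _top_two(ext)
        call = PositionCall(
            column_id=column_id if offset == 0 else f"{column_id}+{offset}",
            kind=kind,
            status="no_insertion",
            top_base=_BASES[top] if top_count else "",
            top_count=top_count,
            second_base=_BASES[second] if second_count else "",
            second_count=second_count,
            counts={b: int(c) for b, c in zip(_BASES, ext)},
            gap_or_pass=stop,
            depth=int(spanning),
            insertion_counts=[
                (off, b, int(c))
                for off, col in enumerate(insertion_cols)
                for b, c in zip(_BASES, col)
                if c
            ]
            if offset == 0
            else [],
        )
        if stop >= top_count:  # pass-through leads (ties go to pass-through)
            if top_count == 0 or stop >= ratio_threshold * top_count:
                call.status = "no_insertion"
                if spanning > 0:
                    call.confidence = 100.0 * stop / spanning
                call.signal_noise = (
                    float("inf") if top_count == 0 else stop / top_count
                )
            else:
                call.status = "N"
                call.called_base = "N"
                if spanning > 0:
                    call.confidence = 100.0 * stop / spanning
                call.signal_noise = stop / top_count
        else:  # an inserted base leads
            if spanning > 0:
                call.confidence = 100.0 * top_count / spanning
            call.signal_noise = (
                float("inf") if second_count == 0 else top_count / second_count
            )
            if top_count < coverage_fraction * max_coverage:
                call.status = "dropped"
            elif int(np.sum(ext == top_count)) > 1 or top_count < ratio_threshold * second_count:
                call.status = "N"
                call.called_base = "N"
            else:
                call.status = "base"
                call.called_base = _BASES[top]
        calls.append(call)
        if call.status in ("no_insertion", "dropped"):
            break
        offset += 1
        if offset > len(insertion_cols):
            break
    return calls


def consensus_from_pileup(
    pileup: PileupMatrix,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
    median_confidence_threshold: float = DEFAULT_MEDIAN_CONFIDENCE,
    pass_label: str = "forward_draft",
) -> ConsensusResult:
    """Traverse the position array 5' terminal -> base/between -> 3' terminal
    and assemble the called sequence with its per-position records."""
    if pileup.n_reads == 0 or pileup.max_coverage == 0:
        raise ValueError("empty pileup: no aligned reads")
    L = pileup.draft_length
    max_cov = pileup.max_coverage
    seq_parts: list[str] = []
    calls: list[PositionCall] = []
    confidences: list[float] = []
    n_N = 0

    def handle_between(j: int, kind: str, column_id: str):
        nonlocal n_N
        sub = call_between_column(
            pileup.insertion_columns(j),
            int(pileup.spanning[j]),
            max_cov,
            column_id,
            kind=kind,
            ratio_threshold=ratio_threshold,
            coverage_fraction=coverage_fraction,
        )
        for c in sub:
            if c.status == "base":
                seq_parts.append(c.called_base)
            elif c.status == "N":
                seq_parts.append("N")
                n_N += 1
        calls.extend(sub)

    handle_between(0, "terminal", "5'")
    for i in range(L):
        call = call_base_column(
            pileup.base_counts[i],
            int(pileup.gap_counts[i]),
            max_cov,
            column_id=str(i + 1),
            ratio_threshold=ratio_threshold,
            coverage_fraction=coverage_fraction,
        )
        if call.status == "base":
            seq_parts.append(call.called_base)
            confidences.append(call.confidence)
        elif call.status == "N":
            seq_parts.append("N")
            n_N += 1
        calls.append(call)
        if i + 1 < L:
            handle_between(i + 1, "between", f"{i + 1}/{i + 2}")
    handle_between(L, "terminal", "3'")

    for c in calls:
        if c.kind != "base" and c.status == "base":
            confidences.append(c.confidence)
    median_conf = float(np.median(confidences)) if confidences else 0.0
    return ConsensusResult(
        sequence="".join(seq_parts),
        calls=calls,
        median_confidence=median_conf,
        qc_pass=median_conf > median_confidence_threshold,
        pass_label=pass_label,
        n_calls_N=n_N,
    )


# ---------------------------------------------------------------------------
# draft construction


def _draft_from_pileup(
    pileup: PileupMatrix, coverage_fraction: float = DEFAULT_COVERAGE_FRACTION
) -> str:
    """Draft calling: majority base per column, no Ns.

    Base columns keep the majority base unless its support falls below the
    coverage fraction of the maximum depth (deletions never out-vote a
    retained base directly, matching the final calling criteria). Between
    columns extend the draft when inserted-base support either holds a
    strict majority over the pass-through count or — for insertions that
    extend an adjacent homopolymer — reaches the coverage fraction, so that
    undercalled long runs are restored to full length in the draft. The
    draft is also extended outward at its termini from read-overhang
    evidence, since a truncated seed read could otherwise never recover the
    template's ends (end gaps are free in the alignment, so overhanging read
    bases leave no trace inside the draft columns).
    """
    L = pileup.draft_length
    draft_seq = pileup.draft.sequence
    max_cov = pileup.max_coverage
    min_count = coverage_fraction * max_cov
    parts: list[str] = []

    def extend(j: int):
        left = draft_seq[j - 1] if j > 0 else ""
        right = draft_seq[j] if j < L else ""
        for col in pileup.insertion_columns(j):
            n_continue = int(col.sum())
            stop = int(pileup.spanning[j]) - n_continue
            top = int(np.argmax(col))
            top_count = int(col[top])
            if top_count == 0:
                break
            base = _BASES[top]
            is_hp = base == left or base == right
            if top_count > stop or (is_hp and top_count >= min_count):
                parts.append(base)
            else:
                break

    extend(0)
    for i in range(L):
        counts = pileup.base_counts[i]
        top = int(np.argmax(counts))
        if counts[top] >= min_count and counts[top] > 0:
            parts.append(_BASES[top])
        extend(i + 1)
    body = "".join(parts)

    def terminal_extension(overhang: list[np.ndarray]) -> str:
        ext = []
        for col in overhang:
            top = int(np.argmax(col))
            if col[top] >= min_count and col[top] > 0:
                ext.append(_BASES[top])
            else:
                break
        return "".join(ext)

    head = terminal_extension(pileup.five_prime_overhang)[::-1]
    tail = terminal_extension(pileup.three_prime_overhang)
    return head + body + tail


def build_draft(
    reads: Sequence[SequencedRead],
    subsample_size: int = DEFAULT_DRAFT_SUBSAMPLE,
    seed: int = 0,
    band_width: int = 600,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
    n_rounds: int = 2,
) -> TemplateSequence:
    """Draft consensus by seed-read selection plus iterative polish.

    A deterministic subsample of the reads is aligned to a seed read (the
    read whose length is closest to the subsample's median length), a
    majority pileup consensus is computed, and one polish iteration repeats
    the alignment against the updated draft.
    """
    if not reads:
        raise ValueError("no reads to build a draft from")
    rng = np.random.default_rng(seed)
    if len(reads) > subsample_size:
        idx = rng.choice(len(reads), size=subsample_size, replace=False)
        subsample = [reads[i] for i in sorted(idx)]
    else:
        subsample = list(reads)

    lengths = np.array([len(r) for r in subsample])
    median = float(np.median(lengths))
    seed_read = min(subsample, key=lambda r: (abs(len(r) - median), r.read_id))
    current = seed_read.sequence.replace("N", "A")  # draft must be plain ACGT

    for _ in range(n_rounds):
        draft = TemplateSequence(name="draft", sequence=current)
        alignments = [align_read(r, draft, band_width=band_width) for r in subsample]
        pileup = build_pileup(alignments, draft)
        updated = _draft_from_pileup(pileup, coverage_fraction)
        if not updated:
            raise ValueError("draft collapsed to an empty sequence")
        if updated == current:
            break
        current = updated
    return TemplateSequence(name="draft", sequence=current)


def orient_draft(draft: TemplateSequence, expected: TemplateSequence) -> TemplateSequence:
    """Return the draft in the expected reference's orientation.

    The seed read behind the draft has a random orientation, so the draft
    may come out reverse-complemented relative to the expected sequence;
    verification reports positions on the expected frame, so the draft is
    flipped when its reverse complement is the closer match.
    """
    from .align import _screen_orientation

    strand, oriented, _ = _screen_orientation(
        draft.sequence, reverse_complement(draft.sequence), expected.sequence
    )
    if strand == "reverse":
        return TemplateSequence(name=draft.name, sequence=oriented)
    return draft


def reconcile_draft(
    draft: TemplateSequence,
    expected: TemplateSequence,
    pileup: PileupMatrix,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
    band_width: int = 600,
) -> TemplateSequence:
    """Restore expected alleles the draft lost to mixed evidence.

    A base deleted in a fraction f of templates and a base inserted in a
    fraction 1-f produce identical pileups, so a reference-free draft cannot
    distinguish the two; which allele the draft carries at such a site is
    decided by the seed read. The calling criteria, however, presume the
    draft carries the *expected* allele wherever that allele keeps at least
    the coverage-retention level of support (that is what makes subclonal
    insertions detectable from 20% but deletions only beyond 90%). This step
    aligns the draft to the expected reference and, at each disagreement,
    restores the expected base when its support in the pileup is at least
    coverage_fraction x max_coverage. Novel draft content with majority
    support is never removed — that is genuine variant signal for the
    calling stage to report.
    """
    if draft.sequence == expected.sequence:
        return draft
    read = SequencedRead(
        read_id="draft",
        sequence=draft.sequence,
        qualities=np.full(draft.length, 40, dtype=np.int16),
    )
    aln = align_read(read, expected, band_width=band_width)
    if aln.strand != "forward":
        # unrelated or flipped relative to expected; leave the draft alone
        return draft
    min_count = coverage_fraction * pileup.max_coverage
    subs: list[tuple[int, str]] = []  # (draft position, base)
    ins: dict[int, list[str]] = {}  # draft junction -> bases (by offset)
    last_qp = -1
    del_junction = -1
    del_offset = 0
    del_ok = True
    for op, rp, qp in zip(aln.ops, aln.ref_pos, aln.read_pos):
        if op == OP_DELETION:  # expected base absent from the draft
            j = last_qp + 1
            if j != del_junction:
                del_junction, del_offset, del_ok = j, 0, True
            exp_base = expected.sequence[rp]
            cols = pileup.insertion_columns(j)
            support = (
                int(cols[del_offset][_BASES.index(exp_base)])
                if del_offset < len(cols)
                else 0
            )
            # offsets must be restored as a prefix to keep base order valid
            if del_ok and support >= min_count and support > 0:
                ins.setdefault(j, []).append(exp_base)
            else:
                del_ok = False
            del_offset += 1
            continue
        del_junction = -1
        if op == OP_MISMATCH:
            exp_base = expected.sequence[rp]
            if int(pileup.base_counts[qp][_BASES.index(exp_base)]) >= min_count:
                subs.append((int(qp), exp_base))
        last_qp = int(qp)
    if not subs and not ins:
        return draft
    seq = list(draft.sequence)
    for pos, base in subs:
        seq[pos] = base
    for j in sorted(ins, reverse=True):
        seq[j:j] = ins[j]
    return TemplateSequence(name=draft.name, sequence="".join(seq))


def reverse_complement_consensus(result: ConsensusResult, draft_length: int) -> ConsensusResult:
    """Map a consensus called against the reverse-complemented draft back to
    the draft frame: sequence reverse-complemented (N self-maps), calls
    reversed with bases complemented and column ids relabeled."""
    L = draft_length

    def relabel(c: PositionCall) -> PositionCall:
        if c.kind == "base":
            cid = str(L - int(c.column_id) + 1)
        elif c.kind == "terminal":
            cid = "3'" if c.column_id.startswith("5") else "5'"
        else:
            base_id = c.column_id.split("+")[0]
            i = int(base_id.split("/")[0])
            cid = f"{L - i}/{L - i + 1}"
            if "+" in c.column_id:
                cid += "+" + c.column_id.split("+")[1]
        return PositionCall(
            column_id=cid,
            kind=c.kind,
            status=c.status,
            called_base=_COMP[c.called_base],
            top_base=_COMP[c.top_base],
            top_count=c.top_count,
            second_base=_COMP[c.second_base],
            second_count=c.second_count,
            confidence=c.confidence,
            signal_noise=c.signal_noise,
            counts={_COMP[b]: n for b, n in c.counts.items()},
            gap_or_pass=c.gap_or_pass,
            depth=c.depth,
            insertion_counts=[
                (off, _COMP[b], n) for off, b, n in c.insertion_counts
            ],
        )

    return ConsensusResult(
        sequence=reverse_complement(result.sequence),
        calls=[relabel(c) for c in reversed(result.calls)],
        median_confidence=result.median_confidence,
        qc_pass=result.qc_pass,
        pass_label=result.pass_label,
        n_calls_N=result.n_calls_N,
    )


def dual_pass_consensus(
    reads: Sequence[SequencedRead],
    draft: TemplateSequence,
    band_width: int = 600,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    coverage_fraction: float = DEFAULT_COVERAGE_FRACTION,
    median_confidence_threshold: float = DEFAULT_MEDIAN_CONFIDENCE,
    expected: TemplateSequence | None = None,
) -> tuple[ConsensusResult, ConsensusResult, bool, TemplateSequence]:
    """Two consensus passes: against the draft, and against its reverse
    complement (mapped back to the draft frame).

    Indel left-alignment is frame-dependent, so a variant adjacent to a
    homopolymer can have its support diluted in one frame but not the other;
    disagreement between the passes flags a possible variant template.

    When ``expected`` is given, the draft is first oriented to the expected
    reference and reconciled against it at full read depth (see
    reconcile_draft); the pass-1 alignments are reused when reconciliation
    leaves the draft unchanged. Returns (forward pass, reverse pass,
    agreement flag, draft actually used).
    """

    def align_all(target: TemplateSequence):
        return [align_read(r, target, band_width=band_width) for r in reads]

    if expected is not None:
        draft = orient_draft(draft, expected)
    alignments = align_all(draft)
    pileup = build_pileup(alignments, draft)
    if expected is not None:
        reconciled = reconcile_draft(
            draft, expected, pileup, coverage_fraction, band_width
        )
        if reconciled.sequence != draft.sequence:
            draft = reconciled
            pileup = build_pileup(align_all(draft), draft)

    forward = consensus_from_pileup(
        pileup,
        ratio_threshold=ratio_threshold,
        coverage_fraction=coverage_fraction,
        median_confidence_threshold=median_confidence_threshold,
        pass_label="forward_draft",
    )

    rc_draft = TemplateSequence(
        name="draft_rc", sequence=reverse_complement(draft.sequence)
    )
    rc_pileup = build_pileup(align_all(rc_draft), rc_draft)
    reverse = consensus_from_pileup(
        rc_pileup,
        ratio_threshold=ratio_threshold,
        coverage_fraction=coverage_fraction,
        median_confidence_threshold=median_confidence_threshold,
        pass_label="reverse_draft",
    )
    reverse = reverse_complement_consensus(reverse, draft.length)
    return forward, reverse, forward.sequence == reverse.sequence, draft
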