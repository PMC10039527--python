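"""Synthetic plasmid templates and nanopore-like reads.

The generator emulates duplex-grade reads of a linearized plasmid: every
read is a full-template-length copy (in either orientation) corrupted by a
configurable error model. The model captures the error structure that
matters to the consensus pipeline — a small dispersed substitution/indel
load, run-length undercalling of homopolymers, optional strand-specific
systematic miscalls, and ragged read ends — without attempting raw-signal
realism.

All operations are deterministic given an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import decode, encode
from .seqio import SequencedRead, TemplateSequence

_BASES = "ACGT"


@dataclass(frozen=True)
class MutationSpec:
    """One template edit: SNV, single-base insertion or single-base deletion.

    ``position`` is 1-based on the template. An SNV replaces ``ref_base``
    with ``alt_base`` at ``position``; a deletion removes ``ref_base`` at
    ``position``; an insertion places ``alt_base`` immediately after
    ``position``.
    """

    kind: str  # "SNV" | "insertion" | "deletion"
    position: int
    ref_base: str = ""
    alt_base: str = ""

    def __post_init__(self):
        if self.kind not in ("SNV", "insertion", "deletion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.kind == "SNV" and (
            not self.ref_base or not self.alt_base or self.ref_base == self.alt_base
        ):
            raise ValueError("SNV requires ref_base != alt_base")
        if self.kind == "deletion" and not self.ref_base:
            raise ValueError("deletion requires ref_base")
        if self.kind == "insertion" and not self.alt_base:
            raise ValueError("insertion requires alt_base")

    @property
    def label(self) -> str:
        if self.kind == "SNV":
            return f"{self.ref_base}{self.position}{self.alt_base}"
        if self.kind == "deletion":
            return f"{self.position}del{self.ref_base}"
        return f"{self.position}ins{self.alt_base}"


@dataclass
class ErrorModel:
    """Read corruption model.

    Rates are per base (substitution, deletion) or per junction (insertion).
    ``homopolymer_undercall`` maps a true run length to a probability
    distribution over reported run lengths; runs whose length is not listed
    (and at least ``min_homopolymer``) fall back to a binomial loss model in
    which each base beyond ``min_homopolymer - 1`` is dropped independently
    with probability ``hp_loss_per_base``. ``strand_bias_sites`` lists
    (1-based template position, strand, wrong base, miscall probability)
    systematic errors applied only to reads of the designated strand, in
    template frame. ``end_raggedness`` is the maximum number of bases
    truncated (uniformly) from each read end.

    ``quality_profile`` is "constant" (every base gets ``base_quality``) or
    "flag_errors" (bases altered by the model get ``error_quality``); the
    latter lets the per-read-minimum quality filter single out errored reads
    when a test wants that coupling.
    """

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    homopolymer_undercall: dict[int, dict[int, float]] = field(default_factory=dict)
    hp_loss_per_base: float = 0.0
    min_homopolymer: int = 5
    strand_bias_sites: list[tuple[int, str, str, float]] = field(default_factory=list)
    end_raggedness: int = 0
    quality_profile: str = "constant"
    base_quality: int = 20
    error_quality: int = 10

    def __post_init__(self):
        for name in ("substitution_rate", "insertion_rate", "deletion_rate",
                     "hp_loss_per_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for run_len, dist in self.homopolymer_undercall.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"undercall distribution for run length {run_len} sums to {total}"
                )
            if any(rep < 1 for rep in dist):
                raise ValueError("reported run lengths must be >= 1")
        for pos, strand, base, prob in self.strand_bias_sites:
            if strand not in ("forward", "reverse"):
                raise ValueError(f"bad strand {strand!r} in strand_bias_sites")
            if base not in _BASES or not 0.0 <= prob <= 1.0:
                raise ValueError("bad strand bias site")
        if self.quality_profile not in ("constant", "flag_errors"):
            raise ValueError(f"unknown quality profile {self.quality_profile!r}")

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls()

    @classmethod
    def duplex(cls, **overrides) -> "ErrorModel":
        """Duplex-grade residual error regime.

        Dispersed substitutions at 0.05% per base with a light indel load,
        plus homopolymer run-length undercalling (8% loss per base beyond
        the minimum tracked run length) — most residual error sits in
        homopolymers, as in duplex-called nanopore data.
        """
        params = dict(
            substitution_rate=5e-4,
            insertion_rate=2e-4,
            deletion_rate=1e-4,
            hp_loss_per_base=0.08,
            end_raggedness=5,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def simplex(cls, **overrides) -> "ErrorModel":
        """Single-pass nanopore regime: ~5% total error, heavy on indels."""
        params = dict(
            substitution_rate=0.025,
            insertion_rate=0.008,
            deletion_rate=0.012,
            hp_loss_per_base=0.15,
            end_raggedness=25,
        )
        params.update(overrides)
        return cls(**params)


def find_homopolymer_runs(sequence: str, min_length: int = 2):
    """Maximal single-base runs of at least min_length as (start, base, length)."""
    runs = []
    start = 0
    for i in range(1, len(sequence) + 1):
        if i == len(sequence) or sequence[i] != sequence[start]:
            if i - start >= min_length:
                runs.append((start, sequence[start], i - start))
            start = i
    return runs


def make_reference(
    length: int,
    seed: int,
    homopolymer_runs: list[tuple[int, str, int]] | None = None,
) -> TemplateSequence:
    """Uniform-random template with requested homopolymer runs embedded.

    ``homopolymer_runs`` is a list of (0-based start, base, run length); runs
    must fit inside the template without overlapping each other. The bases
    flanking each embedded run are forced to differ from the run base so the
    realized run has exactly the requested length.
    """
    if length < 100:
        raise ValueError("template length must be >= 100")
    runs = sorted(homopolymer_runs or [])
    prev_end = -1
    for start, base, run_len in runs:
        if base not in _BASES or run_len < 1:
            raise ValueError(f"bad homopolymer run ({start}, {base!r}, {run_len})")
        if start <= prev_end:
            raise ValueError("homopolymer runs overlap")
        if start < 1 or start + run_len >= length:
            raise ValueError("homopolymer run does not fit inside the template")
        prev_end = start + run_len
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    for start, base, run_len in runs:
        b = _BASES.index(base)
        codes[start : start + run_len] = b
        for flank in (start - 1, start + run_len):
            if 0 <= flank < length and codes[flank] == b:
                codes[flank] = (b + 1 + rng.integers(0, 3)) % 4
    return TemplateSequence(name=f"synthetic_{length}bp_seed{seed}",
                            sequence=decode(codes))


def apply_mutations(
    template: TemplateSequence, mutations: list[MutationSpec]
) -> TemplateSequence:
    """Apply edits right-to-left so earlier 1-based positions stay valid."""
    seq = list(template.sequence)
    for mut in sorted(mutations, key=lambda m: m.position, reverse=True):
        i = mut.position - 1
        if i >= len(seq):
            raise ValueError(f"mutation {mut.label}: position beyond template end")
        if mut.kind in ("SNV", "deletion") and seq[i] != mut.ref_base:
            raise ValueError(
                f"mutation {mut.label}: template has {seq[i]!r} at position "
                f"{mut.position}, expected {mut.ref_base!r}"
            )
        if mut.kind == "SNV":
            seq[i] = mut.alt_base
        elif mut.kind == "deletion":
            del seq[i]
        else:
            seq.insert(i + 1, mut.alt_base)
    return TemplateSequence(name=template.name + ".variant", sequence="".join(seq))


def _sample_run_length(rng, model: ErrorModel, run_len: int) -> int:
    dist = model.homopolymer_undercall.get(run_len)
    if dist is not None:
        reps = np.fromiter(dist.keys(), dtype=np.int64)
        probs = np.fromiter(dist.values(), dtype=np.float64)
        return int(rng.choice(reps, p=probs / probs.sum()))
    if model.hp_loss_per_base > 0.0:
        at_risk = run_len - (model.min_homopolymer - 1)
        return run_len - int(rng.binomial(at_risk, model.hp_loss_per_base))
    return run_len


def _corrupt(codes: np.ndarray, rng, model: ErrorModel, runs, strand: str):
    """Return (corrupted codes, error flag array) for one read, template frame."""
    seq = codes.copy()
    flagged = np.zeros(len(seq), dtype=bool)

    for pos, site_strand, wrong, prob in model.strand_bias_sites:
        if site_strand == strand and rng.random() < prob:
            seq[pos - 1] = _BASES.index(wrong)
            flagged[pos - 1] = True

    if runs and (model.hp_loss_per_base > 0.0 or model.homopolymer_undercall):
        parts = []
        flag_parts = []
        prev = 0
        for start, base, run_len in runs:
            reported = _sample_run_length(rng, model, run_len)
            parts.append(seq[prev:start])
            flag_parts.append(flagged[prev:start])
            parts.append(np.full(reported, _BASES.index(base), dtype=np.uint8))
            flag_parts.append(np.full(reported, reported != run_len, dtype=bool))
            prev = start + run_len
        parts.append(seq[prev:])
        flag_parts.append(flagged[prev:])
        seq = np.concatenate(parts)
        flagged = np.concatenate(flag_parts)

    if model.substitution_rate > 0.0:
        mask = rng.random(len(seq)) < model.substitution_rate
        if mask.any():
            idx = np.nonzero(mask)[0]
            seq[idx] = (seq[idx] + rng.integers(1, 4, size=len(idx))) % 4
            flagged[idx] = True
    if model.insertion_rate > 0.0:
        mask = rng.random(len(seq) + 1) < model.insertion_rate
        if mask.any():
            idx = np.nonzero(mask)[0]
            seq = np.insert(seq, idx, rng.integers(0, 4, size=len(idx)).astype(np.uint8))
            flagged = np.insert(flagged, idx, True)
    if model.deletion_rate > 0.0:
        mask = rng.random(len(seq)) < model.deletion_rate
        if mask.any():
            keep = ~mask
            seq = seq[keep]
            flagged = flagged[keep]

    return seq, flagged


def simulate_reads(
    template: TemplateSequence,
    n_reads: int,
    error_model: ErrorModel | None = None,
    fraction_reverse: float = 0.5,
    seed: int = 0,
    id_prefix: str = "read",
) -> list[SequencedRead]:
    """Full-template-length reads in both orientations under the error model.

    Exactly round(n_reads * fraction_reverse) reads are reverse-strand, at
    randomized positions in the output. The true orientation is recorded as
    a "/fwd" or "/rev" read-id suffix for test introspection only — the
    pipeline itself never consults it.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0.0 <= fraction_reverse <= 1.0:
        raise ValueError("fraction_reverse must be in [0, 1]")
    model = error_model or ErrorModel.error_free()
    rng = np.random.default_rng(seed)
    codes = encode(template.sequence)
    runs = find_homopolymer_runs(template.sequence, model.min_homopolymer)

    n_rev = int(round(n_reads * fraction_reverse))
    is_reverse = np.zeros(n_reads, dtype=bool)
    is_reverse[:n_rev] = True
    rng.shuffle(is_reverse)

    reads = []
    for i in range(n_reads):
        strand = "reverse" if is_reverse[i] else "forward"
        seq, flagged = _corrupt(codes, rng, model, runs, strand)
        if strand == "reverse":
            seq = (3 - seq)[::-1]
            flagged = flagged[::-1]
        if model.end_raggedness > 0:
            lo = int(rng.integers(0, model.end_raggedness + 1))
            hi = int(rng.integers(0, model.end_raggedness + 1))
            end = len(seq) - hi if hi else len(seq)
            seq = seq[lo:end]
            flagged = flagged[lo:end]
        quals = np.full(len(seq), model.base_quality, dtype=np.int16)
        if model.quality_profile == "flag_errors":
            quals[flagged] = model.error_quality
        suffix = "rev" if strand == "reverse" else "fwd"
        reads.append(
            SequencedRead(
                read_id=f"{id_prefix}{i:06d}/{suffix}",
                sequence=decode(np.ascontiguousarray(seq)),
                qualities=quals,
            )
        )
    return reads


def mixture_counts(proportions: list[float], n_reads: int) -> list[int]:
    """Exact per-template read counts by largest-remainder rounding."""
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {sum(proportions)}, expected 1")
    raw = [p * n_reads for p in proportions]
    counts = [int(np.floor(x)) for x in raw]
    short = n_reads - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def simulate_mixture(
    templates: list[tuple[TemplateSequence, float]],
    n_reads: int,
    error_model: ErrorModel | None = None,
    seed: int = 0,
    fraction_reverse: float = 0.5,
) -> list[SequencedRead]:
    """Reads from a mixture of templates at exact-count proportions.

    Counts follow largest-remainder rounding so they always conserve
    ``n_reads``. Output order is shuffled; each read carries its source
    template name in a hidden ``_source`` attribute for test introspection.
    """
    counts = mixture_counts([p for _, p in templates], n_reads)
    rng = np.random.default_rng(seed)
    reads: list[SequencedRead] = []
    for t_idx, ((template, _), count) in enumerate(zip(templates, counts)):
        if count == 0:
            continue
        sub = simulate_reads(
            template,
            count,
            error_model,
            fraction_reverse=fraction_reverse,
            seed=int(rng.integers(0, 2**31 - 1)),
            id_prefix=f"t{t_idx}_read",
        )
        for r in sub:
            r._source = template.name
        reads.extend(sub)
    perm = rng.permutation(len(reads))
    return [reads[i] for i in perm]


def non_homopolymer_sites(
    template: TemplateSequence,
    n_sites: int,
    margin: int = 100,
    min_spacing: int = 50,
) -> list[int]:
    """1-based positions in clear context for placing point mutations.

    A clear site is a base that differs from both neighbors (so an edit
    there is not absorbed into a homopolymer run and indels left-align
    unambiguously), at least ``margin`` bases from the template ends and
    ``min_spacing`` bases from the previously chosen site.
    """
    s = template.sequence
    out: list[int] = []
    last = -min_spacing
    for p in range(margin, len(s) - margin):
        if s[p - 1] != s[p] != s[p + 1] and s[p - 1] != s[p + 1]:
            if (p + 1) - last >= min_spacing:
                out.append(p + 1)
                last = p + 1
                if len(out) == n_sites:
                    return out
    raise ValueError(
        f"only {len(out)} clear sites found, {n_sites} requested"
    )


def design_mutations(
    template: TemplateSequence, kinds: Sequence[str]
) -> list[MutationSpec]:
    """Place one mutation of each requested kind at spread-out clear sites.

    SNV alt bases and inserted bases are chosen to differ from every
    adjacent template base, so each edit stays a single, unambiguous
    alignment column.
    """
    positions = non_homopolymer_sites(template, len(kinds))
    s = template.sequence
    muts = []
    for kind, pos in zip(kinds, positions):
        i = pos - 1
        if kind == "SNV":
            alt = next(b for b in _BASES if b not in (s[i - 1], s[i], s[i + 1]))
            muts.append(MutationSpec("SNV", pos, ref_base=s[i], alt_base=alt))
        elif kind == "insertion":
            alt = next(b for b in _BASES if b not in (s[i], s[i + 1]))
            muts.append(MutationSpec("insertion", pos, alt_base=alt))
        elif kind == "deletion":
            muts.append(MutationSpec("deletion", pos, ref_base=s[i]))
        else:
            raise ValueError(f"unknown mutation kind {kind!r}")
    return muts


def simulate_junk_reads(
    template: TemplateSequence, n_reads: int, seed: int = 0
) -> list[SequencedRead]:
    """Reads that should fail the quality or length filters.

    Cycles through three aberrant classes: short fragments, near-duplications
    (concatenated template, as from chained molecules), and full-length reads
    carrying one sub-threshold quality base (q = 11).
    """
    rng = np.random.default_rng(seed)
    codes = encode(template.sequence)
    L = len(codes)
    reads = []
    for i in range(n_reads):
        kind = i % 3
        if kind == 0:
            n = int(rng.integers(100, max(101, L - 300)))
            start = int(rng.integers(0, L - n + 1))
            seq = codes[start : start + n]
            quals = np.full(len(seq), 20, dtype=np.int16)
        elif kind == 1:
            seq = np.concatenate([codes, codes[: int(rng.integers(300, L))]])
            quals = np.full(len(seq), 20, dtype=np.int16)
        else:
            seq = codes
            quals = np.full(len(seq), 20, dtype=np.int16)
            quals[int(rng.integers(0, L))] = 11
        reads.append(
            SequencedRead(
                read_id=f"junk{i:06d}",
                sequence=decode(np.ascontiguousarray(seq)),
                qualities=quals,
            )
        )
    return reads
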