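"""Pairwise alignment of full-length reads against a reference or draft.

Reads from a linearized plasmid are colinear, full-template-length copies of
the reference (in either orientation), so a banded global aligner with affine
gap costs and free end gaps is sufficient and fast — no seed-and-extend
heuristics are needed. Each read is aligned in both orientations and the
higher-scoring one is kept; indels are normalized to their leftmost
equivalent placement inside homopolymer runs, the convention assumed by the
downstream pileup.

Orientation screening and band sizing use edlib's unit-cost edit distance,
which is cheap even for unrelated sequences; the reported alignment itself
always comes from the affine-gap dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import edlib
import numpy as np
from numba import njit

# Op codes shared with the pileup module.
OP_MATCH = 0
OP_MISMATCH = 1
OP_INSERTION = 2
OP_DELETION = 3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

NEG_INF = np.int32(-(2**30))


class BandError(ValueError):
    """Raised when the requested band cannot cover the two sequences."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; N maps to N."""
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


def encode(sequence: str) -> np.ndarray:
    """Encode A,C,G,T,N as 0..4 (uint8)."""
    arr = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass
class PairwiseAlignment:
    """Read-versus-reference placement as ordered columnar edit operations.

    ``ops``/``ref_pos``/``read_pos`` are parallel arrays over alignment
    columns. For match/mismatch/deletion columns ``ref_pos`` is the 0-based
    consumed reference base; for insertion columns it is the junction index
    (number of reference bases consumed before the inserted read base).
    ``read_pos`` is the consumed read base, or -1 for deletion columns; for
    reverse-strand alignments it indexes the reverse-complemented read.
    """

    read_id: str
    strand: str  # "forward" | "reverse"
    ops: np.ndarray
    ref_pos: np.ndarray
    read_pos: np.ndarray
    match_count: int
    aligned_span: tuple[int, int]  # reference, 0-based half-open
    score: int
    read_length: int
    multi_alignment: bool = False
    # encoded read in reference orientation (reverse-complemented for
    # reverse-strand alignments); read_pos indexes into this array
    read_codes: np.ndarray | None = None

    @property
    def operations(self) -> Iterator[tuple[str, int, int]]:
        """Yield (op name, reference position/junction, read position)."""
        names = ("match", "mismatch", "insertion", "deletion")
        for o, rp, qp in zip(self.ops, self.ref_pos, self.read_pos):
            yield (names[o], int(rp), int(qp))


@njit(cache=True)
def _banded_gotoh(read, ref, match, mismatch, gap_open, gap_extend, cmin, cmax):
    """Banded Gotoh DP with free end gaps on both sequences.

    States: M (diagonal), X (read base against reference gap = insertion),
    Y (reference base against read gap = deletion). A gap of length k costs
    gap_open + k*gap_extend. Leading/trailing gaps on either sequence are
    free: any (0, j) or (i, 0) cell is a zero-score start, and the best score
    is taken over the last row and last column. Scores are kept in two
    rolling rows; the full matrix stores only packed 1-byte predecessor
    pointers (M: bits 0-1, X: bits 2-3, Y: bits 4-5), which is all the
    traceback needs.

    Returns (score, end_i, end_j, end_state, ops, refpos, readpos, ncols).
    """
    n = read.shape[0]
    m = ref.shape[0]
    K = cmax - cmin + 1

    Mp = np.full(K, NEG_INF, dtype=np.int32)
    Xp = np.full(K, NEG_INF, dtype=np.int32)
    Yp = np.full(K, NEG_INF, dtype=np.int32)
    Mc = np.full(K, NEG_INF, dtype=np.int32)
    Xc = np.full(K, NEG_INF, dtype=np.int32)
    Yc = np.full(K, NEG_INF, dtype=np.int32)
    ptr = np.zeros((n + 1, K), dtype=np.uint8)

    go_ge = gap_open + gap_extend
    best_score = NEG_INF
    end_i = -1
    end_k = -1
    end_state = np.uint8(0)

    for i in range(1, n + 1):
        klo = 0 if i + cmin >= 0 else -(i + cmin)
        khi = K if i + cmax <= m else m - i - cmin + 1
        rb = read[i - 1]
        for k in range(K):
            Mc[k] = NEG_INF
            Xc[k] = NEG_INF
            Yc[k] = NEG_INF
        prow = ptr[i]
        first_row = i == 1
        for k in range(klo, khi):
            j = i + cmin + k
            p = np.uint8(0)
            # --- M: consume read[i-1] and ref[j-1]; predecessor (i-1,j-1) = k
            if j >= 1:
                if first_row or j == 1:
                    best = np.int32(0)
                    pm = np.uint8(3)
                else:
                    best = NEG_INF
                    pm = np.uint8(3)
                v = Mp[k]
                if v > best:
                    best = v
                    pm = np.uint8(0)
                v = Xp[k]
                if v > best:
                    best = v
                    pm = np.uint8(1)
                v = Yp[k]
                if v > best:
                    best = v
                    pm = np.uint8(2)
                if best > NEG_INF:
                    Mc[k] = best + (match if rb == ref[j - 1] else mismatch)
                    p = pm
            # --- X: consume read[i-1], gap in ref; predecessor (i-1, j) = k+1
            if k + 1 < K:
                best = Mp[k + 1] + go_ge
                px = np.uint8(0)
                v = Xp[k + 1] + gap_extend
                if v > best:
                    best = v
                    px = np.uint8(1)
                v = Yp[k + 1] + go_ge
                if v > best:
                    best = v
                    px = np.uint8(2)
                if best > NEG_INF // 2:
                    Xc[k] = best
                    p |= px << 2
            # --- Y: consume ref[j-1], gap in read; predecessor (i, j-1) = k-1
            if j >= 1 and k >= 1:
                best = Mc[k - 1] + go_ge
                py = np.uint8(0)
                v = Xc[k - 1] + go_ge
                if v > best:
                    best = v
                    py = np.uint8(1)
                v = Yc[k - 1] + gap_extend
                if v > best:
                    best = v
                    py = np.uint8(2)
                if best > NEG_INF // 2:
                    Yc[k] = best
                    p |= py << 4
            prow[k] = p
            if j == m and i < n:  # trailing read gap free
                if Mc[k] > best_score:
                    best_score = Mc[k]
                    end_i = i
                    end_k = k
                    end_state = np.uint8(0)
                if Xc[k] > best_score:
                    best_score = Xc[k]
                    end_i = i
                    end_k = k
                    end_state = np.uint8(1)
                if Yc[k] > best_score:
                    best_score = Yc[k]
                    end_i = i
                    end_k = k
                    end_state = np.uint8(2)
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp

    # last row (i = n): trailing reference gap free
    for k in range(K):
        j = n + cmin + k
        if 0 <= j <= m:
            if Mp[k] > best_score:
                best_score = Mp[k]
                end_i = n
                end_k = k
                end_state = np.uint8(0)
            if Xp[k] > best_score:
                best_score = Xp[k]
                end_i = n
                end_k = k
                end_state = np.uint8(1)
            if Yp[k] > best_score:
                best_score = Yp[k]
                end_i = n
                end_k = k
                end_state = np.uint8(2)

    ops = np.empty(n + m, dtype=np.int8)
    refpos = np.empty(n + m, dtype=np.int32)
    readpos = np.empty(n + m, dtype=np.int32)
    ncols = 0
    if end_i < 0 or best_score <= NEG_INF // 2:
        return NEG_INF, -1, -1, np.uint8(0), ops, refpos, readpos, 0

    i = end_i
    k = end_k
    st = int(end_state)
    while True:
        j = i + cmin + k
        p = ptr[i, k]
        if st == 0:
            rb = read[i - 1]
            ops[ncols] = 0 if rb == ref[j - 1] else 1
            refpos[ncols] = j - 1
            readpos[ncols] = i - 1
            ncols += 1
            nxt = int(p & 0x3)
            i -= 1
            if nxt == 3:
                break
            st = nxt
        elif st == 1:
            ops[ncols] = 2
            refpos[ncols] = j  # junction index
            readpos[ncols] = i - 1
            ncols += 1
            st = int((p >> 2) & 0x3)
            i -= 1
            k += 1
        else:
            ops[ncols] = 3
            refpos[ncols] = j - 1
            readpos[ncols] = -1
            ncols += 1
            st = int((p >> 4) & 0x3)
            k -= 1
        if i == 0:
            break
        j = i + cmin + k
        if j == 0:
            break

    # reverse in place
    for a in range(ncols // 2):
        b = ncols - 1 - a
        ops[a], ops[b] = ops[b], ops[a]
        refpos[a], refpos[b] = refpos[b], refpos[a]
        readpos[a], readpos[b] = readpos[b], readpos[a]
    end_j = end_i + cmin + end_k
    return best_score, end_i, end_j, end_state, ops, refpos, readpos, ncols


@njit(cache=True)
def _left_normalize(ops, refpos, readpos, read, ref, ncols):
    """Shift indel blocks to their leftmost equivalent placement.

    A deletion block removing ref[p:p+L] may move to p-1 when
    ref[p-1] == ref[p+L-1] and the preceding column consumes ref[p-1]
    (the swapped column keeps its op type because the bases are equal);
    symmetrically for insertion blocks on the read. Score is unchanged
    because block lengths are preserved.
    """
    c = 0
    while c < ncols:
        if ops[c] != 2 and ops[c] != 3:
            c += 1
            continue
        kind = ops[c]
        start = c
        end = c
        while end + 1 < ncols and ops[end + 1] == kind:
            end += 1
        L = end - start + 1
        while start > 0 and (ops[start - 1] == 0 or ops[start - 1] == 1):
            if kind == 3:
                p = refpos[start]
                if p == 0 or ref[p - 1] != ref[p + L - 1]:
                    break
                # swap: preceding M column now pairs ref[p+L-1] with its read base
                rdb = readpos[start - 1]
                # deletion block now occupies columns start-1 .. end-1
                for t in range(start - 1, end):
                    ops[t] = 3
                    readpos[t] = -1
                    refpos[t] = p - 1 + (t - (start - 1))
                ops[end] = 0 if read[rdb] == ref[p + L - 1] else 1
                refpos[end] = p + L - 1
                readpos[end] = rdb
                start -= 1
                end -= 1
            else:
                q = readpos[start]
                j = refpos[start]
                if q == 0 or j == 0 or read[q - 1] != read[q + L - 1]:
                    break
                rfb = refpos[start - 1]
                for t in range(start - 1, end):
                    ops[t] = 2
                    refpos[t] = j - 1
                    readpos[t] = q - 1 + (t - (start - 1))
                ops[end] = 0 if read[q + L - 1] == ref[rfb] else 1
                refpos[end] = rfb
                readpos[end] = q + L - 1
                start -= 1
                end -= 1
        c = end + 1
    return ops, refpos, readpos


DEFAULT_SCORING = (2, -4, -4, -2)


def _edlib_distance(query: str, target: str, k: int = -1) -> int:
    """Unit-cost NW edit distance; -1 if it exceeds the cutoff k."""
    res = edlib.align(query, target, mode="NW", task="distance", k=k)
    return int(res["editDistance"])


def _screen_orientation(read_seq: str, rc_seq: str, ref_seq: str):
    """Pick the read orientation with the smaller edit distance to ref.

    Distances are computed with staged cutoffs so dissimilar pairs stay
    cheap. Returns (strand, oriented sequence, distance); when both
    orientations exceed every cutoff (an unrelated sequence) the forward
    orientation is kept and the last cutoff is reported as the distance.
    """
    k = 64
    kmax = min(2048, max(len(read_seq), len(ref_seq)))
    while True:
        d_fwd = _edlib_distance(read_seq, ref_seq, k)
        d_rev = _edlib_distance(rc_seq, ref_seq, k)
        if d_fwd >= 0 and (d_rev < 0 or d_fwd <= d_rev):
            return "forward", read_seq, d_fwd
        if d_rev >= 0:
            return "reverse", rc_seq, d_rev
        if k >= kmax:
            # unrelated either way; orientation is immaterial for such reads
            return "forward", read_seq, k
        k = min(k * 8, kmax)


def align_encoded(
    read_codes: np.ndarray,
    ref_codes: np.ndarray,
    band_half: int,
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
):
    """Run the banded DP on encoded sequences; returns the raw kernel output."""
    n = len(read_codes)
    m = len(ref_codes)
    cmin = min(0, m - n) - band_half
    cmax = max(0, m - n) + band_half
    match, mismatch, gap_open, gap_extend = scoring
    return _banded_gotoh(
        read_codes,
        ref_codes,
        np.int32(match),
        np.int32(mismatch),
        np.int32(gap_open),
        np.int32(gap_extend),
        cmin,
        cmax,
    )


def align_read(
    read,
    reference,
    band_width: int = 600,
    scoring: tuple[int, int, int, int] = DEFAULT_SCORING,
) -> PairwiseAlignment:
    """Align a read to the reference in the better of the two orientations.

    ``read`` is a SequencedRead (or any object with ``read_id`` and
    ``sequence``); ``reference`` a TemplateSequence or plain string. Both
    orientations are screened with edlib's unit-cost edit distance, which
    also sizes the band adaptively (capped at ``band_width``); the affine-gap
    banded DP is then run on the winning orientation. Ties prefer forward.
    """
    ref_seq = getattr(reference, "sequence", reference)
    read_seq = getattr(read, "sequence", read)
    read_id = getattr(read, "read_id", "")
    if not read_seq or not ref_seq:
        raise ValueError("read and reference must be non-empty")

    rc_seq = reverse_complement(read_seq)
    strand, seq, dist = _screen_orientation(read_seq, rc_seq, ref_seq)
    ref_codes = encode(ref_seq)
    read_codes = encode(seq)

    if dist == 0:
        # identical sequences: the alignment is all matches, skip the DP
        n = len(seq)
        ops = np.zeros(n, dtype=np.int8)
        pos = np.arange(n, dtype=np.int32)
        return PairwiseAlignment(
            read_id=read_id,
            strand=strand,
            ops=ops,
            ref_pos=pos,
            read_pos=pos.copy(),
            match_count=n,
            aligned_span=(0, n),
            score=scoring[0] * n,
            read_length=len(read_seq),
            read_codes=read_codes,
        )

    band_half = min(max(band_width // 2, 8), max(16, dist + 16))
    score, _ei, _ej, _es, ops, refpos, readpos, ncols = align_encoded(
        read_codes, ref_codes, band_half, scoring
    )
    if ncols == 0:
        raise BandError(
            f"band of width {band_width} too narrow to align read "
            f"{read_id!r}; retry with a wider band"
        )
    ops, refpos, readpos = _left_normalize(
        ops, refpos, readpos, read_codes, ref_codes, ncols
    )
    ops = ops[:ncols].copy()
    refpos = refpos[:ncols].copy()
    readpos = readpos[:ncols].copy()

    consumed = refpos[ops != OP_INSERTION]
    span = (int(consumed.min()), int(consumed.max()) + 1) if consumed.size else (0, 0)
    return PairwiseAlignment(
        read_id=read_id,
        strand=strand,
        ops=ops,
        ref_pos=refpos,
        read_pos=readpos,
        match_count=int((ops == OP_MATCH).sum()),
        aligned_span=span,
        score=int(score),
        read_length=len(read_seq),
        read_codes=read_codes,
    )
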