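"""Reading and writing the pipeline's external formats.

FASTA (references in, consensus out), FASTQ (reads; Phred+33), PAF
(optional pre-computed alignments), the per-position TSV report and the JSON
run summary. References are validated strictly: a plasmid reference must be
plain uppercase A/C/G/T — ambiguity codes are rejected because every
downstream threshold assumes an unambiguous expected sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .pileup import ConsensusResult

_REF_ALPHABET = set("ACGT")
_READ_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class TemplateSequence:
    """A linearized plasmid reference: name plus uppercase A/C/G/T text."""

    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"reference {self.name!r}: empty sequence")
        bad = set(self.sequence) - _REF_ALPHABET
        if bad:
            raise ValueError(
                f"reference {self.name!r}: non-ACGT characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SequencedRead:
    """A basecalled read: id, A/C/G/T/N text, per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality scores "
                f"for {len(self.sequence)} bases"
            )
        if len(self.qualities) and self.qualities.min() < 0:
            raise ValueError(f"read {self.read_id!r}: negative quality score")
        bad = set(self.sequence) - _READ_ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id!r}: bad characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def min_quality(self) -> int:
        return int(self.qualities.min()) if len(self.qualities) else 0


def read_fasta(path) -> list[TemplateSequence]:
    """Read a FASTA file into validated, uppercased TemplateSequences."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {i} ({rec.id!r}) has no sequence")
        try:
            out.append(TemplateSequence(name=rec.id, sequence=seq))
        except ValueError as e:
            raise FormatError(f"{path}: record {i}: {e}") from e
    return out


def read_fastq(path) -> list[SequencedRead]:
    """Read a 4-line-record FASTQ (Phred+33) into SequencedReads."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = np.array(
                rec.letter_annotations["phred_quality"], dtype=np.int16
            )
            out.append(
                SequencedRead(
                    read_id=rec.id, sequence=str(rec.seq).upper(), qualities=quals
                )
            )
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
    return out


def write_fastq(reads: Iterable[SequencedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_fasta(templates: Iterable[TemplateSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in templates:
            fh.write(f">{t.name}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")


@dataclass
class PafRecord:
    """One PAF line: the fields the pipeline consumes.

    ``match_count`` is column 10 ("number of residue matches"), the quantity
    used as "aligned bases" by read qualification. Reads appearing on more
    than one line are flagged multi-alignment.
    """

    read_id: str
    read_length: int
    strand: str  # "forward" | "reverse"
    match_count: int
    multi_alignment: bool = False


def read_paf(path) -> list[PafRecord]:
    """Parse a PAF file (>=12 mandatory tab-separated columns per line)."""
    records: list[PafRecord] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}: line {lineno}: {len(cols)} columns, expected >= 12"
                )
            if cols[4] not in "+-":
                raise FormatError(f"{path}: line {lineno}: bad strand {cols[4]!r}")
            rec = PafRecord(
                read_id=cols[0],
                read_length=int(cols[1]),
                strand="forward" if cols[4] == "+" else "reverse",
                match_count=int(cols[9]),
            )
            if rec.read_id in seen:
                records[seen[rec.read_id]].multi_alignment = True
                rec.multi_alignment = True
            else:
                seen[rec.read_id] = len(records)
            records.append(rec)
    return records


def write_pair_list(pairs: Sequence[tuple[str, str]], path) -> None:
    """Two-column text file of (forward read id, reverse read id)."""
    with open(path, "w") as fh:
        for fwd, rev in pairs:
            fh.write(f"{fwd}\t{rev}\n")


def write_consensus_fasta(consensus: "ConsensusResult", path, name="consensus") -> None:
    if not consensus.sequence:
        raise ValueError("empty consensus: nothing to write")
    with open(path, "w") as fh:
        fh.write(f">{name} median_confidence={consensus.median_confidence:.4f}\n")
        seq = consensus.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


_REPORT_COLUMNS = [
    "column",
    "kind",
    "A",
    "C",
    "G",
    "T",
    "gap_or_pass",
    "insertions",
    "top_base",
    "top_count",
    "second_base",
    "second_count",
    "confidence_pct",
    "signal_noise",
    "status",
]


def write_position_report(consensus: "ConsensusResult", path) -> None:
    """One TSV row per pileup column (2L+1 rows for a draft of length L).

    Base columns use 1-based indices, between-columns are labeled "i/i+1",
    and the terminal columns "5'" and "3'". ``gap_or_pass`` holds the
    deletion count at base columns and the pass-through count at
    between/terminal columns; ``insertions`` lists per-offset counts as
    offset:base=count, comma-separated.
    """
    if not consensus.calls:
        raise ValueError("empty consensus: nothing to report")
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for call in consensus.calls:
            ins = ",".join(
                f"{off}:{base}={cnt}" for off, base, cnt in call.insertion_counts
            )
            sn = "inf" if call.signal_noise == float("inf") else f"{call.signal_noise:.2f}"
            row = [
                call.column_id,
                call.kind,
                *(str(call.counts.get(b, 0)) for b in "ACGT"),
                str(call.gap_or_pass),
                ins,
                call.top_base or ".",
                str(call.top_count),
                call.second_base or ".",
                str(call.second_count),
                f"{call.confidence:.2f}" if call.confidence is not None else ".",
                sn if call.signal_noise is not None else ".",
                call.status,
            ]
            fh.write("\t".join(row) + "\n")


def write_run_summary(summary: dict, path) -> None:
    """JSON run summary: resolved config, stage counters, QC verdict."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
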