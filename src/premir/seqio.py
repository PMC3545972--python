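"""Sequence I/O, sliding windows, and low-complexity / gap screening.

Genomes and CDS files are cut into fixed-length windows (default 90 nt,
9-nt step) — the unit of classification throughout the package.  Windows
containing assembly gaps (N) or simple repeats are discarded before any
folding is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "SequenceWindow",
    "read_fasta",
    "write_fasta",
    "split_windows",
    "iter_windows",
    "complexity_report",
    "complexity_filter",
    "gap_filter",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T/U, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-length fragment of a source sequence.

    Coordinates are 0-based, half-open, always on the forward strand of
    the source; for ``strand == '-'`` the stored ``seq`` is the reverse
    complement of ``source[start:end]``.
    """

    source_id: str
    start: int
    end: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("window coordinates do not match sequence length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def id(self) -> str:
        return f"{self.source_id}:{self.start}-{self.end}({self.strand})"

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving the T/U convention of the input."""
    rc = seq.translate(_COMPLEMENT)[::-1]
    if "U" in seq.upper() and "T" not in seq.upper():
        rc = rc.replace("T", "U").replace("t", "u")
    return rc


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercase :class:`SequenceRecord` objects.

    Both T and U are accepted and preserved as read.  Raises
    ``ValueError`` for an empty file or duplicate identifiers.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def split_windows(
    record: SequenceRecord, window_len: int = 90, step: int = 9
) -> Iterator[SequenceWindow]:
    """Tile ``record`` with forward-strand windows at starts 0, step, 2*step, ...

    Only full-length windows are emitted; a trailing partial window is
    dropped rather than padded, because downstream length-normalised
    features assume a fixed window length.
    """
    if window_len <= 0 or step <= 0:
        raise ValueError("window_len and step must be positive")
    L = len(record.seq)
    for start in range(0, L - window_len + 1, step):
        yield SequenceWindow(
            record.id, start, start + window_len, "+", record.seq[start : start + window_len]
        )


def iter_windows(
    record: SequenceRecord,
    window_len: int = 90,
    step: int = 9,
    strands: str = "+",
) -> Iterator[SequenceWindow]:
    """Windows on one or both strands (``strands`` in {"+", "-", "both"}).

    Minus-strand windows keep forward coordinates; their ``seq`` is the
    reverse complement of the forward-strand slice.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"invalid strands {strands!r}")
    for w in split_windows(record, window_len, step):
        if strands in ("+", "both"):
            yield w
        if strands in ("-", "both"):
            yield SequenceWindow(
                w.source_id, w.start, w.end, "-", reverse_complement(w.seq)
            )


# Simple-repeat screens.  The thresholds follow the worked examples
# (AAAAAAAA; AG x 7; ATG x 4): a unit count at or above the threshold fails.
_MONO_RE = re.compile(r"(.)\1{7,}")  # >= 8 identical nucleotides
_DI_RE = re.compile(r"(..)\1{6,}")  # >= 7 tandem dinucleotide units
_TRI_RE = re.compile(r"(...)\1{3,}")  # >= 4 tandem trinucleotide units


def complexity_report(seq: str) -> list[str]:
    """Names of every repeat rule the sequence violates (may be several)."""
    s = seq.upper().replace("U", "T")
    fired = []
    if _MONO_RE.search(s):
        fired.append("mono>=8")
    if _DI_RE.search(s):
        fired.append("di>=7")
    if _TRI_RE.search(s):
        fired.append("tri>=4")
    return fired


def complexity_filter(seq: str) -> bool:
    """True if the sequence is free of mono/di/tri-nucleotide simple repeats."""
    return not complexity_report(seq)


def gap_filter(seq: str) -> bool:
    """True iff the sequence is pure A/C/G/T/U (no N, no ambiguity codes)."""
    return all(c in "ACGTU" for c in seq.upper())
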