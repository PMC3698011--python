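"""FASTQ parsing and quality-score <-> integer conversion.

Quality scores are stored in FASTQ as printable ASCII, one character per
base, with the integer score equal to the character's ASCII code (the scale
offset — 33 for Sanger/Phred+33, 64 for Phred+64/Solexa+64 — is included in
the stored value, so ``'!'`` is 33 and ``'I'`` is 73 on the Phred+33 scale).
The codec operates on these raw integer codes, never on offset-subtracted
Phred values.

The reader is deliberately strict: four lines per record, no line wrapping,
all reads the same length.  Those are preconditions of the downstream
model (one covariance matrix per position), so violations are rejected with
a line number rather than silently tolerated.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FastqRecord",
    "QualityBlock",
    "FastqFormatError",
    "SCALE_RANGES",
    "read_fastq",
    "write_fastq_sorted",
    "decode_qualities",
    "encode_qualities",
]

#: Default (qmin, qmax) alphabet bounds for the declared ASCII offset.
#: Phred+33 spans ASCII 33..73; the 64-offset scales span 64..104.
SCALE_RANGES = {33: (33, 73), 64: (64, 104)}


class FastqFormatError(ValueError):
    """Malformed FASTQ input (bad sigil, length mismatch, ragged reads...)."""


@dataclass
class FastqRecord:
    """One four-line FASTQ entry.

    ``header`` is stored without the leading ``@``; ``plus_line`` is the
    third line verbatim (including the leading ``+`` and any repeated
    description), so writing a record back reproduces the input bytes.
    """

    header: str
    sequence: str
    plus_line: str = "+"
    quality_ascii: str = ""

    def __post_init__(self) -> None:
        if not self.header:
            raise FastqFormatError("FASTQ header must be non-empty")
        if not self.plus_line.startswith("+"):
            raise FastqFormatError(
                f"record {self.header!r}: third line must start with '+'"
            )
        if len(self.sequence) != len(self.quality_ascii):
            raise FastqFormatError(
                f"record {self.header!r}: sequence length "
                f"{len(self.sequence)} != quality length {len(self.quality_ascii)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QualityBlock:
    """Integer quality scores of N equal-length reads as an (N, n) matrix.

    ``values[i, j]`` is the raw ASCII code of read i at position j.
    ``n_mask[i, j]`` is True where the called base is 'N' (unknown); the
    decoder later forces those positions to ``qmin``.
    """

    values: np.ndarray
    offset: int
    qmin: int
    qmax: int
    n_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be an (N, n) matrix")
        if self.n_mask is None:
            self.n_mask = np.zeros(self.values.shape, dtype=bool)
        self.n_mask = np.asarray(self.n_mask, dtype=bool)
        if self.n_mask.shape != self.values.shape:
            raise ValueError("n_mask shape must match values shape")
        if self.values.size and (
            self.values.min() < self.qmin or self.values.max() > self.qmax
        ):
            raise ValueError(
                f"quality values outside declared alphabet [{self.qmin}, {self.qmax}]"
            )

    @property
    def n_reads(self) -> int:
        return self.values.shape[0]

    @property
    def read_length(self) -> int:
        return self.values.shape[1]


def _open_maybe_gzip(source, mode: str):
    """Open a path as text, transparently handling gzip; pass streams through."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if "r" in mode:
            with open(path, "rb") as probe:
                magic = probe.read(2)
            if magic == b"\x1f\x8b":
                return gzip.open(path, mode + "t"), True
        elif path.suffix == ".gz":
            return gzip.open(path, mode + "t"), True
        return open(path, mode + "t" if mode in ("r", "w") else mode), True
    if isinstance(source, io.TextIOBase):
        return source, False
    # binary stream
    return io.TextIOWrapper(source), False


def read_fastq(source) -> list[FastqRecord]:
    """Parse a 4-line-per-record FASTQ file (path, ``.gz`` path, or stream).

    All reads must share one length; ragged input is rejected because the
    codec models one Gaussian per position across reads.
    """
    stream, owned = _open_maybe_gzip(source, "r")
    try:
        records: list[FastqRecord] = []
        lines = [line.rstrip("\n").rstrip("\r") for line in stream]
    finally:
        if owned:
            stream.close()

    if lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise FastqFormatError(
            f"truncated FASTQ: {len(lines)} lines is not a multiple of 4"
        )

    expected_len: int | None = None
    for i in range(0, len(lines), 4):
        lineno = i + 1
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or len(head) < 2:
            raise FastqFormatError(f"line {lineno}: expected '@header', got {head!r}")
        if not plus.startswith("+"):
            raise FastqFormatError(f"line {lineno + 2}: expected '+' line, got {plus!r}")
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"line {lineno}: sequence/quality length mismatch "
                f"({len(seq)} vs {len(qual)})"
            )
        if expected_len is None:
            expected_len = len(seq)
        elif len(seq) != expected_len:
            raise FastqFormatError(
                f"line {lineno}: read length {len(seq)} differs from first "
                f"read's length {expected_len}; fixed-length input required"
            )
        records.append(FastqRecord(head[1:], seq, plus, qual))
    return records


def write_fastq_sorted(records: Iterable[FastqRecord], dest) -> None:
    """Write records ordered by bytewise-lexicographic header.

    The deterministic comparator guarantees that paired-end mates, which
    share header sets, end up in the same order in both output files.
    """
    ordered = sorted(records, key=lambda r: r.header.encode())
    stream, owned = _open_maybe_gzip(dest, "w")
    try:
        for rec in ordered:
            stream.write(f"@{rec.header}\n{rec.sequence}\n{rec.plus_line}\n{rec.quality_ascii}\n")
    finally:
        if owned:
            stream.close()


def decode_qualities(
    records: Sequence[FastqRecord],
    offset: int,
    qmin: int | None = None,
    qmax: int | None = None,
) -> QualityBlock:
    """Convert ASCII quality strings to an integer :class:`QualityBlock`.

    ``qmin``/``qmax`` default to the declared scale's range (e.g. [33, 73]
    for Phred+33).  Out-of-range characters are errors, not clamped: a
    character below the declared offset almost always means the wrong scale
    was declared, which silent clamping would hide.
    """
    if qmin is None or qmax is None:
        if offset not in SCALE_RANGES:
            raise ValueError(f"no default range for offset {offset}; pass qmin/qmax")
        d_min, d_max = SCALE_RANGES[offset]
        qmin = d_min if qmin is None else qmin
        qmax = d_max if qmax is None else qmax

    if not records:
        return QualityBlock(np.zeros((0, 0), dtype=np.int64), offset, qmin, qmax)

    n = len(records[0])
    values = np.zeros((len(records), n), dtype=np.int64)
    n_mask = np.zeros((len(records), n), dtype=bool)
    for i, rec in enumerate(records):
        if len(rec) != n:
            raise ValueError(f"record {rec.header!r}: length {len(rec)} != {n}")
        row = np.frombuffer(rec.quality_ascii.encode("ascii"), dtype=np.uint8)
        bad = np.nonzero((row < qmin) | (row > qmax))[0]
        if bad.size:
            j = int(bad[0])
            raise ValueError(
                f"record {rec.header!r}, position {j}: quality character "
                f"{rec.quality_ascii[j]!r} (={int(row[j])}) outside [{qmin}, {qmax}] "
                f"for declared offset {offset}"
            )
        values[i] = row
        seq = np.frombuffer(rec.sequence.upper().encode("ascii"), dtype=np.uint8)
        n_mask[i] = seq == ord("N")
    return QualityBlock(values, offset, qmin, qmax, n_mask)


def encode_qualities(block: QualityBlock) -> list[str]:
    """Inverse of :func:`decode_qualities`: integer rows back to ASCII strings."""
    if block.values.size and (
        block.values.min() < block.qmin or block.values.max() > block.qmax
    ):
        bad = np.argwhere((block.values < block.qmin) | (block.values > block.qmax))[0]
        raise ValueError(
            f"value {int(block.values[tuple(bad)])} at read {bad[0]}, position "
            f"{bad[1]} outside [{block.qmin}, {block.qmax}]"
        )
    return [
        row.astype(np.uint8).tobytes().decode("ascii") for row in block.values
    ]
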