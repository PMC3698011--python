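"""Distortion and storage accounting.

The fidelity metric is the mean squared error between original and
reconstructed quality scores: per read, D(i) = (1/n) sum_j (Q_ij - Qhat_ij)^2,
and overall D = (1/N) sum_i D(i).  Because the codec reorders its output,
reads are matched by header before comparing.

Unit conventions, chosen to match how sizes are conventionally reported:
storage projections use GB = 10^9 bytes (decimal, as disk vendors and
sequencing consortia do); side-information overheads use KB = 1024 bytes
(binary, as file-size listings do).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .codec import CompressedContainer, effective_rate
from .fastq_io import FastqRecord, decode_qualities

__all__ = [
    "DistortionReport",
    "mse",
    "rate_overhead",
    "storage_projection",
    "format_report",
]

GB = 10**9
KB = 1024


@dataclass
class DistortionReport:
    """MSE plus the rate/size bookkeeping of one compression run."""

    mse: float
    per_read_mse: np.ndarray
    rate_requested: float | None = None
    rate_effective: float | None = None
    payload_bytes: int | None = None
    overhead_bytes: int | None = None


def _match_by_header(
    original: Sequence[FastqRecord], reconstructed: Sequence[FastqRecord]
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Pair reads by header; duplicate headers pair up in sorted order."""
    a = sorted(original, key=lambda r: r.header.encode())
    b = sorted(reconstructed, key=lambda r: r.header.encode())
    if len(a) != len(b):
        raise ValueError(f"read count mismatch: {len(a)} vs {len(b)}")
    for ra, rb in zip(a, b):
        if ra.header != rb.header:
            raise ValueError(
                f"header sets differ: {ra.header!r} has no counterpart"
            )
    return a, b


def mse(
    original: Sequence[FastqRecord],
    reconstructed: Sequence[FastqRecord],
    offset: int = 33,
    qmin: int | None = None,
    qmax: int | None = None,
    container: CompressedContainer | None = None,
) -> DistortionReport:
    """Average per-read MSE between two header-matched sets of reads.

    When the container of the run is supplied, the report also carries the
    requested and effective rates and the payload/overhead split.
    """
    a, b = _match_by_header(original, reconstructed)
    qa = decode_qualities(a, offset, qmin, qmax).values.astype(np.float64)
    qb = decode_qualities(b, offset, qmin, qmax).values.astype(np.float64)
    if qa.shape != qb.shape:
        raise ValueError(f"dimension mismatch: {qa.shape} vs {qb.shape}")
    per_read = ((qa - qb) ** 2).mean(axis=1)
    report = DistortionReport(mse=float(per_read.mean()), per_read_mse=per_read)
    if container is not None:
        report.rate_requested = container.rate
        report.rate_effective = effective_rate(container)
        report.payload_bytes = container.payload_bytes
        report.overhead_bytes = container.overhead_bytes
    return report


def rate_overhead(overhead_bytes: float, n: int, n_reads: int) -> float:
    """Rate increase (bits per quality score) caused by side information.

    delta_R = R' - R = 8 * overhead_bytes / (n * N).
    """
    if overhead_bytes < 0 or n <= 0 or n_reads <= 0:
        raise ValueError("overhead, read length and read count must be positive")
    return 8.0 * overhead_bytes / (n * n_reads)


def storage_projection(total_quality_scores: float, rate: float) -> float:
    """Bytes needed to store that many quality scores at ``rate`` bits each.

    Side-information overhead is excluded: at dataset scales worth
    projecting, it is orders of magnitude below the payload.
    """
    if total_quality_scores < 0 or rate < 0:
        raise ValueError("inputs must be nonnegative")
    return total_quality_scores * rate / 8.0


def format_report(report: DistortionReport) -> str:
    """Plain-text/TSV rendering of a distortion report."""
    lines = [f"mse\t{report.mse:.6g}"]
    if report.rate_requested is not None:
        lines.append(f"rate_requested\t{report.rate_requested:.6g}")
    if report.rate_effective is not None:
        lines.append(f"rate_effective\t{report.rate_effective:.6g}")
    if report.payload_bytes is not None:
        lines.append(f"payload_bytes\t{report.payload_bytes}")
    if report.overhead_bytes is not None:
        lines.append(f"overhead_bytes\t{report.overhead_bytes}")
    return "\n".join(lines)
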