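"""End-to-end encoder/decoder and the binary container format.

Encoding pipeline, per input FASTQ file:

1. parse reads, decode qualities to an integer (N, n) block;
2. k-means cluster the quality vectors (deterministic constant-profile
   initialization);
3. per cluster: empirical mean/covariance, eigendecomposition
   Sigma = V diag(s) V^T, reverse-water-filling bit allocation for the
   requested rate R (solved once per cluster — the allocation is shared by
   every read in it);
4. per read: transform q' = V^T(q - mu), normalize each component by
   sqrt(s_j), realize the fractional allocation as integers by seeded
   randomized rounding, quantize each component with the Lloyd-Max codebook
   of its bit depth, and pack the indices MSB-first into one bitstream.

The container (``.qc``) stores the side information the decoder needs — per
cluster: read count, mu, V, s, rho — plus the rounding seed and the packed
payload.  Headers, nucleotide sequences and '+' lines travel in a plain-text
companion stub (``.qcs``) in the same cluster-grouped read order; its own
compression is deliberately out of scope here, and it is excluded from the
effective-rate accounting, which concerns quality bits only.

Decoding replays the same pseudorandom draws from the stored seed to
recover each read's integer bit depths, unpacks and dequantizes the
indices, rescales by sqrt(s_j), inverts the transform with
round(V q' + mu) clamped to the alphabet, and forces positions whose base
is 'N' to qmin (an unknown base deserves the least reliable score).  Read
order is not preserved: output is sorted by header, which makes paired-end
files come out in matching order.
"""

from __future__ import annotations

import gzip
import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .clustering import kmeans
from .fastq_io import (
    FastqRecord,
    QualityBlock,
    decode_qualities,
    encode_qualities,
    read_fastq,
    write_fastq_sorted,
)
from .model_stats import SpectralModel, compute_statistics, round_half_away, spectral_decompose
from .prng import SplitMix64
from .quantizer import get_codebook
from .rate_allocator import realize_allocations, solve_allocation

__all__ = [
    "ClusterBlock",
    "CompressedContainer",
    "SequenceStub",
    "ContainerFormatError",
    "compress",
    "decompress",
    "effective_rate",
    "write_container",
    "read_container",
    "compress_file",
    "decompress_file",
]

MAGIC = b"QCMP"
VERSION = 1
#: Floor for the normalization divisor sqrt(s_j); components this close to
#: deterministic never receive bits, so the floor only guards arithmetic.
_NORM_FLOOR = 1e-12


class ContainerFormatError(ValueError):
    """Corrupt, truncated, or incompatible container data."""


@dataclass
class ClusterBlock:
    """Per-cluster side information stored in the container."""

    count: int
    mu: np.ndarray
    V: np.ndarray
    s: np.ndarray
    rho: np.ndarray


@dataclass
class CompressedContainer:
    """Parsed form of a ``.qc`` file: side information plus packed payload."""

    n: int
    n_reads: int
    offset: int
    qmin: int
    qmax: int
    rate: float
    seed: int
    max_bits: int
    clusters: list[ClusterBlock]
    payload: bytes = b""

    def to_bytes(self) -> bytes:
        out = io.BytesIO()
        out.write(MAGIC)
        out.write(struct.pack("<B", VERSION))
        out.write(
            struct.pack(
                "<IQBBBBdQH",
                self.n,
                self.n_reads,
                self.offset,
                self.qmin,
                self.qmax,
                self.max_bits,
                self.rate,
                self.seed,
                len(self.clusters),
            )
        )
        for c in self.clusters:
            out.write(struct.pack("<Q", c.count))
            out.write(np.asarray(c.mu, dtype="<f8").tobytes())
            out.write(np.asarray(c.V, dtype="<f8").tobytes())
            out.write(np.asarray(c.s, dtype="<f8").tobytes())
            out.write(np.asarray(c.rho, dtype="<f8").tobytes())
        out.write(struct.pack("<Q", len(self.payload)))
        out.write(self.payload)
        return out.getvalue()

    @classmethod
    def from_bytes(cls, data: bytes) -> "CompressedContainer":
        buf = io.BytesIO(data)

        def take(nbytes: int) -> bytes:
            chunk = buf.read(nbytes)
            if len(chunk) != nbytes:
                raise ContainerFormatError(
                    f"truncated container: wanted {nbytes} bytes, got {len(chunk)}"
                )
            return chunk

        if take(4) != MAGIC:
            raise ContainerFormatError("bad magic: not a quality-codec container")
        (version,) = struct.unpack("<B", take(1))
        if version != VERSION:
            raise ContainerFormatError(f"unsupported container version {version}")
        n, n_reads, offset, qmin, qmax, max_bits, rate, seed, k = struct.unpack(
            "<IQBBBBdQH", take(struct.calcsize("<IQBBBBdQH"))
        )
        clusters = []
        for _ in range(k):
            (count,) = struct.unpack("<Q", take(8))
            mu = np.frombuffer(take(8 * n), dtype="<f8").copy()
            V = np.frombuffer(take(8 * n * n), dtype="<f8").reshape(n, n).copy()
            s = np.frombuffer(take(8 * n), dtype="<f8").copy()
            rho = np.frombuffer(take(8 * n), dtype="<f8").copy()
            clusters.append(ClusterBlock(count, mu, V, s, rho))
        if sum(c.count for c in clusters) != n_reads:
            raise ContainerFormatError("cluster counts do not sum to the read count")
        (payload_len,) = struct.unpack("<Q", take(8))
        payload = take(payload_len)
        if buf.read(1):
            raise ContainerFormatError("trailing bytes after payload")
        return cls(n, n_reads, offset, qmin, qmax, rate, seed, max_bits, clusters, payload)

    @property
    def payload_bytes(self) -> int:
        return len(self.payload)

    @property
    def overhead_bytes(self) -> int:
        """Everything in the serialized container except the payload."""
        return len(self.to_bytes()) - len(self.payload)


@dataclass
class SequenceStub:
    """Non-quality lines of each read, in cluster-grouped payload order."""

    headers: list[str]
    sequences: list[str]
    plus_lines: list[str]

    def __post_init__(self) -> None:
        if not (len(self.headers) == len(self.sequences) == len(self.plus_lines)):
            raise ValueError("stub field lengths disagree")

    def __len__(self) -> int:
        return len(self.headers)

    def write(self, dest) -> None:
        opener = gzip.open if str(dest).endswith(".gz") else open
        with opener(dest, "wt") as fh:
            for h, s, p in zip(self.headers, self.sequences, self.plus_lines):
                fh.write(f"@{h}\n{s}\n{p}\n")

    @classmethod
    def read(cls, source) -> "SequenceStub":
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as fh:
            lines = [line.rstrip("\n") for line in fh]
        if lines and lines[-1] == "":
            lines.pop()
        if len(lines) % 3 != 0:
            raise ContainerFormatError("stub is not 3 lines per record")
        headers, seqs, pluses = [], [], []
        for i in range(0, len(lines), 3):
            head, seq, plus = lines[i : i + 3]
            if not head.startswith("@") or not plus.startswith("+"):
                raise ContainerFormatError(f"malformed stub record at line {i + 1}")
            headers.append(head[1:])
            seqs.append(seq)
            pluses.append(plus)
        return cls(headers, seqs, pluses)


def _cluster_model(rows: np.ndarray, n: int) -> SpectralModel:
    """Spectral model of one cluster, degrading gracefully below 2 reads."""
    if rows.shape[0] >= 2:
        return spectral_decompose(compute_statistics(rows))
    mu = rows[0].astype(np.float64) if rows.shape[0] == 1 else np.zeros(n)
    return SpectralModel(mu=mu, V=np.eye(n), s=np.zeros(n))


def _pack_indices(values: np.ndarray, nbits: np.ndarray) -> bytes:
    """Concatenate each value in exactly its bit width, MSB-first."""
    active = nbits > 0
    values = values[active].astype(np.int64)
    nbits = nbits[active].astype(np.int64)
    total = int(nbits.sum())
    if total == 0:
        return b""
    offsets = np.cumsum(nbits) - nbits
    group_bits = np.repeat(nbits, nbits)
    within = np.arange(total) - np.repeat(offsets, nbits)
    shift = group_bits - 1 - within
    bits = (np.repeat(values, nbits) >> shift) & 1
    return np.packbits(bits.astype(np.uint8)).tobytes()


def _unpack_indices(payload: bytes, nbits: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_pack_indices`; returns one index per active slot."""
    active = nbits > 0
    widths = nbits[active].astype(np.int64)
    total = int(widths.sum())
    expected_bytes = (total + 7) // 8
    if len(payload) != expected_bytes:
        raise ContainerFormatError(
            f"payload is {len(payload)} bytes but the allocation implies {expected_bytes}"
        )
    if total == 0:
        return np.zeros(0, dtype=np.int64)
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8))[:total].astype(np.int64)
    offsets = np.cumsum(widths) - widths
    group_bits = np.repeat(widths, widths)
    within = np.arange(total) - np.repeat(offsets, widths)
    shift = group_bits - 1 - within
    return np.add.reduceat(bits << shift, offsets)


def compress(
    source,
    rate: float,
    clusters: int = 3,
    seed: int = 0,
    offset: int = 33,
    qmin: int | None = None,
    qmax: int | None = None,
    max_bits: int = 15,
    kmeans_max_iter: int = 100,
) -> tuple[CompressedContainer, SequenceStub]:
    """Compress a FASTQ file (or a list of records) at ``rate`` bits/score.

    Returns the container and the companion stub.  ``seed`` drives the
    randomized rounding and is stored in the container so the decoder can
    replay it.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if rate > max_bits:
        raise ValueError(f"rate {rate} exceeds the per-position cap of {max_bits} bits")
    if clusters < 1:
        raise ValueError("need at least one cluster")

    records: Sequence[FastqRecord]
    if isinstance(source, (str, Path)) or hasattr(source, "read"):
        records = read_fastq(source)
    else:
        records = list(source)
    if not records:
        raise ValueError("no reads to compress")

    block = decode_qualities(records, offset, qmin, qmax)
    n_reads, n = block.values.shape
    k = min(clusters, n_reads)
    state = kmeans(block.values, k, kmeans_max_iter, qmin=block.qmin, qmax=block.qmax)
    order = np.argsort(state.labels, kind="stable")  # cluster-grouped, file order kept

    prng = SplitMix64(seed)
    cluster_blocks: list[ClusterBlock] = []
    all_values: list[np.ndarray] = []
    all_nbits: list[np.ndarray] = []
    for c in range(k):
        members = order[state.labels[order] == c]
        rows = block.values[members].astype(np.float64)
        count = rows.shape[0]
        model = _cluster_model(rows, n)
        alloc = solve_allocation(model.s, n, rate, max_bits)
        cluster_blocks.append(
            ClusterBlock(count, model.mu, model.V, model.s, alloc.rho)
        )
        if count == 0:
            continue
        rho_int = realize_allocations(alloc.rho, count, prng)
        coeffs = (rows - model.mu) @ model.V
        divisor = np.maximum(np.sqrt(model.s), _NORM_FLOOR)
        normalized = coeffs / divisor
        indices = np.zeros_like(rho_int)
        for b in np.unique(rho_int):
            if b == 0:
                continue
            cb = get_codebook(int(b))
            mask = rho_int == b
            indices[mask] = np.searchsorted(cb.thresholds, normalized[mask], side="right")
        all_values.append(indices.ravel())
        all_nbits.append(rho_int.ravel())

    if all_values:
        payload = _pack_indices(np.concatenate(all_values), np.concatenate(all_nbits))
    else:
        payload = b""

    container = CompressedContainer(
        n=n,
        n_reads=n_reads,
        offset=block.offset,
        qmin=block.qmin,
        qmax=block.qmax,
        rate=float(rate),
        seed=int(seed) % (1 << 64),
        max_bits=max_bits,
        clusters=cluster_blocks,
        payload=payload,
    )
    stub = SequenceStub(
        headers=[records[i].header for i in order],
        sequences=[records[i].sequence for i in order],
        plus_lines=[records[i].plus_line for i in order],
    )
    return container, stub


def decompress(container: CompressedContainer, stub: SequenceStub) -> list[FastqRecord]:
    """Reconstruct FASTQ records (header-sorted) from container + stub."""
    if len(stub) != container.n_reads:
        raise ContainerFormatError(
            f"stub has {len(stub)} reads but container declares {container.n_reads}"
        )
    n = container.n
    prng = SplitMix64(container.seed)

    # replay the rounding draws in the exact encoding order
    per_cluster_rho_int: list[np.ndarray] = []
    nbits_parts: list[np.ndarray] = []
    for c in container.clusters:
        if c.count == 0:
            per_cluster_rho_int.append(np.zeros((0, n), dtype=np.int64))
            continue
        rho_int = realize_allocations(c.rho, c.count, prng)
        per_cluster_rho_int.append(rho_int)
        nbits_parts.append(rho_int.ravel())
    nbits = np.concatenate(nbits_parts) if nbits_parts else np.zeros(0, dtype=np.int64)
    indices_flat = _unpack_indices(container.payload, nbits)

    reconstructed = np.zeros((container.n_reads, n), dtype=np.int64)
    row0 = 0
    taken = 0
    for c, rho_int in zip(container.clusters, per_cluster_rho_int):
        if c.count == 0:
            continue
        active = rho_int > 0
        n_active = int(active.sum())
        indices = np.zeros_like(rho_int)
        indices[active] = indices_flat[taken : taken + n_active]
        taken += n_active

        coeffs = np.zeros(rho_int.shape, dtype=np.float64)
        for b in np.unique(rho_int):
            if b == 0:
                continue
            cb = get_codebook(int(b))
            mask = rho_int == b
            bad = indices[mask] >= cb.representatives.shape[0]
            if bad.any():
                raise ContainerFormatError("quantizer index out of range in payload")
            coeffs[mask] = cb.representatives[indices[mask]]
        coeffs *= np.sqrt(c.s)[None, :]
        rows = round_half_away(coeffs @ c.V.T + c.mu[None, :])
        reconstructed[row0 : row0 + c.count] = np.clip(
            rows, container.qmin, container.qmax
        ).astype(np.int64)
        row0 += c.count

    # unknown bases get the least reliable score
    seq_codes = np.frombuffer(
        "".join(s.upper() for s in stub.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(container.n_reads, n)
    reconstructed[seq_codes == ord("N")] = container.qmin

    qual_block = QualityBlock(
        reconstructed, container.offset, container.qmin, container.qmax
    )
    quality_strings = encode_qualities(qual_block)
    out = [
        FastqRecord(h, s, p, q)
        for h, s, p, q in zip(stub.headers, stub.sequences, stub.plus_lines, quality_strings)
    ]
    out.sort(key=lambda r: r.header.encode())
    return out


def effective_rate(container: CompressedContainer) -> float:
    """Actual bits per quality score, side information included.

    R' = (payload bits + side-information bits) / (n * N); everything in the
    serialized container other than the payload counts as side information.
    """
    total_bits = len(container.to_bytes()) * 8
    return total_bits / (container.n * container.n_reads)


def write_container(container: CompressedContainer, path) -> None:
    Path(path).write_bytes(container.to_bytes())


def read_container(path) -> CompressedContainer:
    return CompressedContainer.from_bytes(Path(path).read_bytes())


def compress_file(
    fastq_path,
    out_prefix,
    rate: float,
    clusters: int = 3,
    seed: int = 0,
    offset: int = 33,
    qmin: int | None = None,
    qmax: int | None = None,
    max_bits: int = 15,
) -> tuple[Path, Path]:
    """Compress ``fastq_path`` to ``<out_prefix>.qc`` + ``<out_prefix>.qcs``."""
    container, stub = compress(
        fastq_path, rate, clusters, seed, offset, qmin, qmax, max_bits
    )
    qc = Path(f"{out_prefix}.qc")
    qcs = Path(f"{out_prefix}.qcs")
    write_container(container, qc)
    stub.write(qcs)
    return qc, qcs


def decompress_file(container_path, stub_path, out_fastq) -> None:
    """Decode a container/stub pair into a header-sorted FASTQ file."""
    container = read_container(container_path)
    stub = SequenceStub.read(stub_path)
    records = decompress(container, stub)
    write_fastq_sorted(records, out_fastq)
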