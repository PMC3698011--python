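"""Synthetic FASTQ with the statistical structure the codec assumes.

Quality vectors are drawn from a mixture of multivariate Gaussians — one
component per "read population" — each with a length-n mean profile, a
per-position standard-deviation profile, and AR(1) within-read correlation
(Cov[j,k] = sigma_j sigma_k rho^|j-k|), then rounded and clamped into the
quality alphabet.  Nucleotides are uniform over ACGT with a configurable
fraction replaced by 'N'.  Everything is deterministic under the seed.

The default single component mimics a short-read Illumina profile on the
Phred+33 scale: mean quality declining from ~70 at the 5' end to ~50 at the
3' end, noise growing from sd 2 to sd 6 along the read, and lag-1
correlation 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fastq_io import FastqRecord, write_fastq_sorted

__all__ = [
    "MixtureComponent",
    "GeneratorSpec",
    "default_spec",
    "two_blob_spec",
    "generate_records",
    "generate_fastq",
]


@dataclass
class MixtureComponent:
    """One Gaussian read population.

    ``mean`` and ``std`` may be scalars or length-n profiles; ``ar1`` is the
    lag-1 correlation coefficient in [0, 1).
    """

    weight: float
    mean: np.ndarray | float
    std: np.ndarray | float = 3.0
    ar1: float = 0.8

    def covariance(self, n: int) -> np.ndarray:
        std = np.broadcast_to(np.asarray(self.std, dtype=np.float64), (n,))
        if np.any(std < 0):
            raise ValueError("standard deviations must be nonnegative")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must lie in [0, 1)")
        lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        return np.outer(std, std) * self.ar1**lags

    def mean_profile(self, n: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.mean, dtype=np.float64), (n,)).copy()


@dataclass
class GeneratorSpec:
    """Full description of a synthetic FASTQ file."""

    n_reads: int
    read_length: int
    components: list[MixtureComponent]
    offset: int = 33
    qmin: int = 33
    qmax: int = 73
    n_base_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads < 1 or self.read_length < 1:
            raise ValueError("need at least one read and one position")
        if not self.components:
            raise ValueError("need at least one mixture component")
        weights = np.array([c.weight for c in self.components], dtype=np.float64)
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be nonnegative and sum to 1")
        if not 0.0 <= self.n_base_fraction <= 1.0:
            raise ValueError("n_base_fraction must lie in [0, 1]")
        for c in self.components:
            mu = np.round(c.mean_profile(self.read_length))
            if mu.min() < self.qmin or mu.max() > self.qmax:
                raise ValueError(
                    "rounded mean profile leaves the quality alphabet "
                    f"[{self.qmin}, {self.qmax}]"
                )
            c.covariance(self.read_length)  # raises on invalid std/ar1


def default_spec(n_reads: int = 5000, read_length: int = 50, seed: int = 0) -> GeneratorSpec:
    """Single Illumina-like population: 70 -> 50 mean decay, sd 2 -> 6, AR(1) 0.8."""
    t = np.linspace(0.0, 1.0, read_length)
    return GeneratorSpec(
        n_reads=n_reads,
        read_length=read_length,
        components=[
            MixtureComponent(weight=1.0, mean=70.0 - 20.0 * t, std=2.0 + 4.0 * t, ar1=0.8)
        ],
        n_base_fraction=0.005,
        seed=seed,
    )


def two_blob_spec(
    n_reads: int = 3000, read_length: int = 50, seed: int = 0
) -> GeneratorSpec:
    """Two well-separated populations (constant means 35 and 70, sd 2)."""
    return GeneratorSpec(
        n_reads=n_reads,
        read_length=read_length,
        components=[
            MixtureComponent(weight=0.5, mean=35.0, std=2.0, ar1=0.5),
            MixtureComponent(weight=0.5, mean=70.0, std=2.0, ar1=0.5),
        ],
        seed=seed,
    )


def _component_root(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root (eigh-based; tolerates singular cov)."""
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, 0.0)
    return vecs * np.sqrt(vals)


def generate_records(spec: GeneratorSpec) -> tuple[list[FastqRecord], np.ndarray]:
    """Draw the reads; returns (records, component labels).

    Headers are ``SYN.<index>`` with zero-padded indices so lexicographic
    and numeric order agree.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_reads, n = spec.n_reads, spec.read_length
    weights = np.array([c.weight for c in spec.components])
    labels = rng.choice(len(spec.components), size=n_reads, p=weights)

    qualities = np.zeros((n_reads, n), dtype=np.int64)
    for ci, comp in enumerate(spec.components):
        members = np.nonzero(labels == ci)[0]
        if not members.size:
            continue
        root = _component_root(comp.covariance(n))
        z = rng.standard_normal((members.size, n))
        raw = comp.mean_profile(n) + z @ root.T
        rounded = np.sign(raw) * np.floor(np.abs(raw) + 0.5)
        qualities[members] = np.clip(rounded, spec.qmin, spec.qmax).astype(np.int64)

    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=(n_reads, n))
    if spec.n_base_fraction > 0:
        bases[rng.random((n_reads, n)) < spec.n_base_fraction] = ord("N")

    width = len(str(n_reads - 1))
    records = []
    for i in range(n_reads):
        records.append(
            FastqRecord(
                header=f"SYN.{i:0{width}d}",
                sequence=bases[i].tobytes().decode("ascii"),
                plus_line="+",
                quality_ascii=qualities[i].astype(np.uint8).tobytes().decode("ascii"),
            )
        )
    return records, labels


def generate_fastq(spec: GeneratorSpec, path) -> list[FastqRecord]:
    """Write a synthetic FASTQ file (header-sorted) and return its records."""
    records, _ = generate_records(spec)
    write_fastq_sorted(records, path)
    return records
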