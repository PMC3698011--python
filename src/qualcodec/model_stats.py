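"""Gaussian modeling of quality vectors and SVD decorrelation.

Each cluster of reads is modeled as draws from a multivariate normal
N(mu, Sigma) over read positions; Sigma is the maximum-likelihood sample
covariance.  Because Sigma is symmetric positive semidefinite its SVD
coincides with its eigendecomposition, Sigma = V diag(s) V^T, and the
Karhunen-Loeve transform q' = V^T (q - mu) yields components that are
uncorrelated — independent under the Gaussian model — with variances s_j.
The decoder inverts with round(V q' + mu).

Sign and order of the factors are pinned down by an explicit convention
(descending s; largest-magnitude entry of each column of V positive) so
that the factors stored in the compressed container are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClusterStatistics",
    "SpectralModel",
    "compute_statistics",
    "spectral_decompose",
    "decorrelate",
    "recorrelate",
    "round_half_away",
]

_SYM_TOL = 1e-9
_PSD_TOL = 1e-8


@dataclass
class ClusterStatistics:
    """Empirical mean, ML covariance, and read count of one cluster."""

    mu: np.ndarray
    sigma: np.ndarray
    count: int


@dataclass
class SpectralModel:
    """Eigenfactors of a cluster covariance: Sigma = V diag(s) V^T.

    ``V`` is orthogonal, ``s`` nonnegative and sorted non-increasing.
    """

    mu: np.ndarray
    V: np.ndarray
    s: np.ndarray


def compute_statistics(rows) -> ClusterStatistics:
    """Empirical mean and maximum-likelihood covariance of an (N, n) block.

    The covariance denominator is N (not N-1): the model calls for the
    empirical second moment, and at the read counts this codec targets the
    difference is far below sampling noise.
    """
    rows = np.asarray(rows, dtype=np.float64)
    if rows.ndim != 2:
        raise ValueError("expected an (N, n) matrix of quality vectors")
    count = rows.shape[0]
    if count < 2:
        raise ValueError(f"need at least 2 reads to estimate a covariance, got {count}")
    mu = rows.mean(axis=0)
    centered = rows - mu
    sigma = centered.T @ centered / count
    sigma = (sigma + sigma.T) / 2.0  # exact symmetry for eigh
    return ClusterStatistics(mu=mu, sigma=sigma, count=count)


def spectral_decompose(stats: ClusterStatistics) -> SpectralModel:
    """Eigendecompose Sigma with a deterministic sign/order convention.

    Eigenvalues are sorted non-increasing (stable, so equal eigenvalues
    keep LAPACK's order); each eigenvector column is flipped so its
    largest-magnitude entry (lowest index on ties) is positive.  Small
    negative eigenvalues from round-off are clamped to zero; anything below
    -1e-8 times the spectral radius is treated as a genuinely indefinite
    matrix and rejected.
    """
    sigma = np.asarray(stats.sigma, dtype=np.float64)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("sigma must be square")
    if np.abs(sigma - sigma.T).max(initial=0.0) > _SYM_TOL:
        raise ValueError("sigma is not symmetric within tolerance")
    eigvals, eigvecs = np.linalg.eigh(sigma)
    smax = float(np.abs(eigvals).max(initial=0.0))
    if eigvals.min(initial=0.0) < -_PSD_TOL * max(smax, 1.0):
        raise ValueError(
            f"sigma is not positive semidefinite (min eigenvalue {eigvals.min():g})"
        )
    eigvals = np.maximum(eigvals, 0.0)
    order = np.argsort(-eigvals, kind="stable")
    s = eigvals[order]
    V = eigvecs[:, order]
    # sign convention: dominant entry of each column positive, first on ties
    lead = np.argmax(np.abs(V), axis=0)
    flip = V[lead, np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    return SpectralModel(mu=np.asarray(stats.mu, dtype=np.float64), V=V, s=s)


def decorrelate(q_vector, model: SpectralModel) -> np.ndarray:
    """Karhunen-Loeve transform of one read: q' = V^T (q - mu)."""
    q = np.asarray(q_vector, dtype=np.float64)
    if q.shape != model.mu.shape:
        raise ValueError(f"dimension mismatch: read has {q.shape}, model {model.mu.shape}")
    return model.V.T @ (q - model.mu)


def round_half_away(x) -> np.ndarray:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3), elementwise."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def recorrelate(qprime, model: SpectralModel, qmin: int, qmax: int) -> np.ndarray:
    """Invert the transform to integer qualities: round(V q' + mu), clamped.

    Rounding is half-away-from-zero; results are clamped into the declared
    alphabet [qmin, qmax] so the reconstruction always re-encodes to valid
    FASTQ characters.
    """
    qp = np.asarray(qprime, dtype=np.float64)
    if qp.shape != model.mu.shape:
        raise ValueError(f"dimension mismatch: coeffs have {qp.shape}, model {model.mu.shape}")
    q = round_half_away(model.V @ qp + model.mu)
    return np.clip(q, qmin, qmax).astype(np.int64)
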