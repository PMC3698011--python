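"""k-means clustering of read quality profiles.

Reads with very different quality behavior (e.g. a failed tile, or decaying
tails) are poorly described by a single Gaussian; pre-clustering lets each
cluster carry its own mean/covariance.  The variant here is the classical
Lloyd k-means with two codec-specific choices:

* initialization is deterministic — k *constant* profiles equally spaced
  between the alphabet bounds (for [33, 73] and k=3: all-33s, all-53s,
  all-73s), so the same input always clusters identically;
* assignment minimizes per-position MSE, (1/n) sum_j (Q_j - V_j)^2, the
  same distortion the codec optimizes.

Iteration stops when no read changes cluster or after ``max_iter`` sweeps.
Empty clusters keep their previous mean rather than being reseeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClusterState", "init_means", "assign", "kmeans"]


@dataclass
class ClusterState:
    """Cluster means (k, n) and per-read labels (N,) in [0, k)."""

    means: np.ndarray
    labels: np.ndarray
    n_iter: int = 0


def init_means(k: int, qmin: int, qmax: int, n: int) -> np.ndarray:
    """Constant mean profiles equally spaced over [qmin, qmax].

    For k >= 2 the constants are qmin + t*(qmax-qmin)/(k-1); for k = 1 the
    midpoint is used (the single-cluster assignment is unaffected by the
    start point, but a defined value keeps the procedure deterministic).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k == 1:
        levels = np.array([(qmin + qmax) / 2.0])
    else:
        levels = qmin + np.arange(k) * (qmax - qmin) / (k - 1)
    return np.tile(levels[:, None], (1, n)).astype(np.float64)


def _sq_distances(block: np.ndarray, means: np.ndarray) -> np.ndarray:
    """(N, k) matrix of per-position mean squared distances."""
    # ||q - m||^2 = ||q||^2 - 2 q.m + ||m||^2, averaged over n
    n = block.shape[1]
    q2 = np.einsum("ij,ij->i", block, block)[:, None]
    m2 = np.einsum("ij,ij->i", means, means)[None, :]
    cross = block @ means.T
    return (q2 - 2.0 * cross + m2) / n


def assign(q_vector, means) -> int:
    """Index of the mean minimizing per-position MSE; ties -> lowest index."""
    q = np.asarray(q_vector, dtype=np.float64)
    means = np.asarray(means, dtype=np.float64)
    if q.shape[0] != means.shape[1]:
        raise ValueError("dimension mismatch between read and cluster means")
    d = ((means - q) ** 2).mean(axis=1)
    return int(np.argmin(d))


def kmeans(
    block,
    k: int,
    max_iter: int = 100,
    qmin: int | None = None,
    qmax: int | None = None,
    initial_means=None,
) -> ClusterState:
    """Cluster an (N, n) quality matrix into k groups.

    ``qmin``/``qmax`` set the spread of the constant initial means; they
    default to the observed min/max of the block (the codec passes the
    declared alphabet bounds instead).  ``initial_means`` overrides the
    constant-profile initialization entirely (e.g. to resume from a known
    fixed point).
    """
    values = np.asarray(block, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("expected an (N, n) matrix")
    n_reads, n = values.shape
    if n_reads < k:
        raise ValueError(f"cannot form {k} clusters from {n_reads} reads")
    if initial_means is not None:
        means = np.array(initial_means, dtype=np.float64)
        if means.shape != (k, n):
            raise ValueError(f"initial_means must have shape ({k}, {n})")
    else:
        if qmin is None:
            qmin = int(np.floor(values.min()))
        if qmax is None:
            qmax = int(np.ceil(values.max()))
        means = init_means(k, qmin, qmax, n)

    labels = np.full(n_reads, -1, dtype=np.int64)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_labels = np.argmin(_sq_distances(values, means), axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = values[labels == c]
            if members.shape[0]:  # empty clusters retain their previous mean
                means[c] = members.mean(axis=0)
    return ClusterState(means=means, labels=labels, n_iter=n_iter)
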