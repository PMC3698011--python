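"""Lloyd-Max scalar quantizers for the standard Gaussian.

Each decorrelated, unit-normalized coefficient is quantized with the
MSE-optimal b-bit scalar quantizer for N(0,1).  Optimality means two fixed-
point conditions hold simultaneously: every representative is the
conditional mean of its decision region, and every threshold is the
midpoint of its neighboring representatives.  The codebooks depend only on
b, so they are built once (closed-form Gaussian tail expressions, no
sampling) and cached.

For b = 1 the fixed point is available in closed form: threshold 0 and
representatives +-sqrt(2/pi) ~= +-0.7979.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.stats import norm

__all__ = [
    "Codebook",
    "lloyd_max",
    "get_codebook",
    "quantize",
    "dequantize",
    "codebook_distortion",
]

_DEFAULT_TOL = 1e-10
_DEFAULT_MAX_ITER = 200

_CACHE: dict[int, "Codebook"] = {}


@dataclass(frozen=True)
class Codebook:
    """b-bit scalar quantizer: 2^b - 1 thresholds, 2^b representatives."""

    bits: int
    thresholds: np.ndarray
    representatives: np.ndarray


def _interval_mass(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """P(a < X <= b) for N(0,1), accurate deep into either tail.

    Far in the positive tail cdf(b) - cdf(a) cancels catastrophically (both
    are ~1); the survival function keeps full relative precision there.
    """
    return np.where(a >= 0, norm.sf(a) - norm.sf(b), norm.cdf(b) - norm.cdf(a))


def _conditional_means(thresholds: np.ndarray) -> np.ndarray:
    """E[X | a < X <= b] for N(0,1) over the regions cut by ``thresholds``."""
    edges = np.concatenate(([-np.inf], thresholds, [np.inf]))
    a, b = edges[:-1], edges[1:]
    num = norm.pdf(a) - norm.pdf(b)  # pdf(+-inf) = 0
    den = _interval_mass(a, b)
    return num / den


def _lloyd_residual_and_jacobian(reps: np.ndarray):
    """Residual F(r) = condmean(midpoints(r)) - r and its tridiagonal Jacobian.

    Region i is (a_i, b_i] with a_i = (r_{i-1}+r_i)/2, b_i = (r_i+r_{i+1})/2
    (outermost edges at +-inf).  With num = phi(a)-phi(b), den = Phi(b)-Phi(a):

        d(num/den)/da = phi(a) (num - a den) / den^2
        d(num/den)/db = phi(b) (b den - num) / den^2

    and each threshold moves half as fast as its adjacent representatives,
    so the Jacobian of F couples only neighbors.
    """
    m = reps.shape[0]
    edges = np.concatenate(([-np.inf], 0.5 * (reps[:-1] + reps[1:]), [np.inf]))
    a, b = edges[:-1], edges[1:]
    pdf_a = norm.pdf(a)  # phi(+-inf) = 0 kills the infinite-edge terms
    pdf_b = norm.pdf(b)
    num = pdf_a - pdf_b
    den = _interval_mass(a, b)
    cm = num / den
    F = cm - reps

    with np.errstate(invalid="ignore"):
        dcm_da = np.where(np.isfinite(a), pdf_a * (num - a * den) / den**2, 0.0)
        dcm_db = np.where(np.isfinite(b), pdf_b * (b * den - num) / den**2, 0.0)
    lower = 0.5 * dcm_da[1:]  # dF_i/dr_{i-1}
    diag = 0.5 * (dcm_da + dcm_db) - 1.0
    upper = 0.5 * dcm_db[:-1]  # dF_i/dr_{i+1}
    banded = np.zeros((3, m))
    banded[0, 1:] = upper
    banded[1] = diag
    banded[2, :-1] = lower
    return F, banded


def lloyd_max(bits: int, tol: float = _DEFAULT_TOL, max_iter: int = _DEFAULT_MAX_ITER) -> Codebook:
    """Construct the MSE-optimal b-bit quantizer for N(0,1).

    Solves the Lloyd fixed point (conditional-mean representatives, midpoint
    thresholds) by Newton iteration on the residual system from
    quantile-spaced starting representatives; the residual couples only
    neighboring levels, so each step is a tridiagonal solve.  Newton is used
    instead of plain Lloyd sweeps because the sweep map's contraction factor
    approaches 1 as the level count grows, while Newton reaches the same
    fixed point quadratically.  Convergence requires both the residual and
    the last step below ``tol``; the optimum's symmetry is enforced each
    step to cancel round-off.
    """
    if bits < 0:
        raise ValueError("bits must be nonnegative")
    if bits == 0:
        return Codebook(0, np.empty(0), np.zeros(1))
    m = 1 << bits
    reps = norm.ppf((2 * np.arange(m) + 1) / (2 * m))
    for _ in range(max_iter):
        F, banded = _lloyd_residual_and_jacobian(reps)
        step = solve_banded((1, 1), banded, -F)
        new_reps = reps + step
        new_reps = 0.5 * (new_reps - new_reps[::-1])
        if np.any(np.diff(new_reps) <= 0):  # safeguard: fall back to a Lloyd sweep
            new_reps = _conditional_means(0.5 * (reps[:-1] + reps[1:]))
            new_reps = 0.5 * (new_reps - new_reps[::-1])
        reps = new_reps
        # converged when both optimality conditions hold within tol (the
        # residual IS the representative movement a Lloyd sweep would make)
        if np.abs(_lloyd_residual_and_jacobian(reps)[0]).max() < tol:
            thresholds = 0.5 * (reps[:-1] + reps[1:])
            return Codebook(bits, thresholds, reps)
    raise RuntimeError(
        f"Lloyd-Max did not converge for {bits} bits within {max_iter} iterations"
    )


def get_codebook(bits: int) -> Codebook:
    """Cached accessor: codebooks are computed once per bit depth."""
    cb = _CACHE.get(bits)
    if cb is None:
        cb = lloyd_max(bits)
        _CACHE[bits] = cb
    return cb


def quantize(x, codebook: Codebook):
    """Map value(s) to decision-region indices.

    A value exactly on a threshold belongs to the upper region; the
    outermost regions are unbounded, so any finite input saturates rather
    than escaping.
    """
    idx = np.searchsorted(codebook.thresholds, x, side="right")
    return int(idx) if np.isscalar(x) else idx


def dequantize(index, codebook: Codebook):
    """Region index back to its representative value."""
    idx = np.asarray(index)
    if idx.size and (idx.min() < 0 or idx.max() >= codebook.representatives.shape[0]):
        raise ValueError(
            f"index out of range for a {codebook.bits}-bit codebook"
        )
    out = codebook.representatives[idx]
    return float(out) if np.isscalar(index) else out


def codebook_distortion(codebook: Codebook) -> float:
    """E[(X - Q(X))^2] for X ~ N(0,1), by closed-form Gaussian integrals.

    Per region (a, b] with representative r:
    integral (x-r)^2 phi(x) dx = (1+r^2)(Phi(b)-Phi(a)) + (a-2r)phi(a) - (b-2r)phi(b).
    """
    edges = np.concatenate(([-np.inf], codebook.thresholds, [np.inf]))
    a, b = edges[:-1], edges[1:]
    r = codebook.representatives
    mass = norm.cdf(b) - norm.cdf(a)
    a_f = np.where(np.isfinite(a), a, 0.0)  # phi(+-inf)=0 zeroes these terms anyway
    b_f = np.where(np.isfinite(b), b, 0.0)
    term_a = (a_f - 2 * r) * norm.pdf(a)
    term_b = (b_f - 2 * r) * norm.pdf(b)
    return float(np.sum((1 + r**2) * mass + term_a - term_b))
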