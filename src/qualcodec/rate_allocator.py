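"""Rate-distortion bit allocation by reverse water-filling.

Given decorrelated component variances s_1..s_n and a budget of n*R bits
per read, the MSE-optimal allocation solves

    min (1/n) sum_j s_j * 2^(-2 rho_j)   s.t.  sum_j rho_j <= n*R, rho_j >= 0.

The KKT solution is reverse water-filling: components with variance above a
water level theta get rho_j = 0.5*log2(s_j/theta), the rest get nothing.
theta is found by bisection on the monotone budget residual; a per-position
cap ``max_bits`` bounds codebook sizes.

The fractional rho are realized per read as integers by randomized
rounding — floor(rho_j)+1 with probability frac(rho_j) — so that the
*average* bits spent per position across reads equals rho_j.  Encoder and
decoder replay identical draws from the shared :class:`~qualcodec.prng.SplitMix64`
stream, consumed in read order and position order within each read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prng import SplitMix64

__all__ = [
    "BitAllocation",
    "solve_allocation",
    "expected_distortion",
    "randomize_rounding",
    "realize_allocations",
]

_BUDGET_TOL = 1e-12
_MAX_BISECT = 500


@dataclass
class BitAllocation:
    """Fractional per-position bit budget and the water level that produced it."""

    rho: np.ndarray
    budget: float
    water_level: float
    max_bits: int


def solve_allocation(s, n: int, R: float, max_bits: int = 15) -> BitAllocation:
    """Minimize (1/n) sum s_j 2^(-2 rho_j) subject to sum rho_j <= n*R.

    Positions with s_j = 0 contribute nothing to the objective and receive
    rho_j = 0.  When the budget exceeds what the caps allow, every
    positive-variance position saturates at ``max_bits``.
    """
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 1 or s.shape[0] != n:
        raise ValueError(f"s must be a length-{n} vector")
    if np.any(s < 0):
        raise ValueError("variances must be nonnegative")
    if R < 0:
        raise ValueError("rate must be nonnegative")
    if max_bits < 0:
        raise ValueError("max_bits must be nonnegative")

    budget = float(n * R)
    rho = np.zeros(n, dtype=np.float64)
    positive = s > 0
    if budget == 0.0 or not positive.any() or max_bits == 0:
        theta = float(s.max(initial=0.0))
        return BitAllocation(rho=rho, budget=budget, water_level=theta, max_bits=max_bits)

    sp = s[positive]

    def spent(theta: float) -> float:
        with np.errstate(divide="ignore"):
            r = 0.5 * np.log2(sp / theta)
        return float(np.clip(r, 0.0, max_bits).sum())

    lo = float(sp.min()) * 4.0 ** (-max_bits)  # everything capped
    hi = float(sp.max())  # nothing allocated
    if budget >= spent(lo):
        rho[positive] = max_bits
        return BitAllocation(rho=rho, budget=budget, water_level=lo, max_bits=max_bits)

    for _ in range(_MAX_BISECT):
        theta = 0.5 * (lo + hi)
        resid = spent(theta) - budget
        if abs(resid) <= _BUDGET_TOL:
            break
        if resid > 0:
            lo = theta
        else:
            hi = theta
    rho[positive] = np.clip(0.5 * np.log2(sp / theta), 0.0, max_bits)
    return BitAllocation(rho=rho, budget=budget, water_level=float(theta), max_bits=max_bits)


def expected_distortion(s, rho, n: int) -> float:
    """Model distortion (1/n) sum s_j 2^(-2 rho_j) of an allocation."""
    s = np.asarray(s, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    if s.shape != rho.shape:
        raise ValueError("s and rho must have equal length")
    return float(np.sum(s * 4.0 ** (-rho)) / n)


def randomize_rounding(rho, prng: SplitMix64) -> np.ndarray:
    """Integer realization of one read's fractional allocation.

    Consumes exactly len(rho) draws in position order so the decoder, which
    replays the same stream, recovers the identical integers.  Integer
    entries map to themselves (their draw is consumed but cannot change the
    outcome).
    """
    rho = np.asarray(rho, dtype=np.float64)
    if np.any(rho < 0):
        raise ValueError("rho must be nonnegative")
    base = np.floor(rho)
    frac = rho - base
    u = prng.uniforms(rho.shape[0])
    return (base + (u < frac)).astype(np.int64)


def realize_allocations(rho, n_reads: int, prng: SplitMix64) -> np.ndarray:
    """Vectorized :func:`randomize_rounding` for ``n_reads`` consecutive reads.

    Equivalent to stacking n_reads calls to randomize_rounding; draw order
    is read-major then position, matching the decoder's replay.
    """
    rho = np.asarray(rho, dtype=np.float64)
    base = np.floor(rho)
    frac = rho - base
    u = prng.uniforms(n_reads * rho.shape[0]).reshape(n_reads, rho.shape[0])
    return (base[None, :] + (u < frac[None, :])).astype(np.int64)
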