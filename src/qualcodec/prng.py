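"""Counter-based splitmix64 generator shared by encoder and decoder.

The randomized rounding of fractional bit budgets must be replayed
bit-exactly at decode time on any platform, so the generator is part of the
container-format contract and is specified here in full rather than
delegated to a library whose stream might change between versions.

Draw i (1-based) is ``mix64(seed + i * GOLDEN)`` with the splitmix64
finalizer; uniforms are the top 53 bits scaled by 2^-53.  Being
counter-based, any run of draws can be produced vectorized.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SplitMix64"]

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def _mix64(z: np.ndarray) -> np.ndarray:
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


class SplitMix64:
    """Deterministic uniform stream over [0, 1) from a 64-bit seed."""

    def __init__(self, seed: int) -> None:
        self._seed = np.uint64(seed % (1 << 64))
        self._counter = 0

    @property
    def counter(self) -> int:
        """Number of draws consumed so far."""
        return self._counter

    def uniforms(self, count: int) -> np.ndarray:
        """Next ``count`` uniforms in stream order, as float64 in [0, 1)."""
        if count < 0:
            raise ValueError("count must be >= 0")
        with np.errstate(over="ignore"):
            idx = np.arange(
                self._counter + 1, self._counter + count + 1, dtype=np.uint64
            )
            z = _mix64(self._seed + idx * _GOLDEN)
        self._counter += count
        return (z >> np.uint64(11)).astype(np.float64) * 2.0**-53
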