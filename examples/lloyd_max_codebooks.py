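"""Build Lloyd-Max quantizers for the unit Gaussian and show their levels.

Each b-bit codebook is the MSE-optimal scalar quantizer for N(0,1):
representatives are conditional means of their decision regions, thresholds
the midpoints between neighbors.  The distortion column is E(X-Q(X))^2 —
the residual variance left after spending b bits on one coefficient.
"""

import numpy as np

from qualcodec.quantizer import codebook_distortion, lloyd_max

for bits in range(4):
    cb = lloyd_max(bits)
    reps = np.array2string(cb.representatives, precision=4)
    print(f"b={bits}: D={codebook_distortion(cb):.4f}  representatives={reps}")

print()
print("The 1-bit levels are +-sqrt(2/pi) =", f"{np.sqrt(2/np.pi):.4f};")
print("a coefficient of -0.344 encodes to region 0 and decodes to the")
print("lower representative, losing (0.7979-0.344)^2 =",
      f"{(np.sqrt(2/np.pi)-0.344)**2:.3f}", "in squared error.")
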