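# Methods

## Problem setting

A FASTQ file with N reads of common length n carries N·n quality scores,
integers on a declared ASCII scale (Phred+33: raw codes 33–73; the
+64 scales: 64–104). `qualcodec` compresses these scores — and only
these — under a user-chosen budget of R bits per score, minimizing the mean
squared error

D = (1/N) Σᵢ D(i),  D(i) = (1/n) Σⱼ (Qᵢ(j) − Q̂ᵢ(j))².

MSE is a deliberate choice of a *mathematical* distortion: it makes the
codec independent of any particular downstream consumer (aligner, variant
caller, trimmer) and lets rate-distortion theory give an exact optimal bit
allocation.

## Model and assumptions

Quality vectors are modeled i.i.d. across reads as multivariate Gaussian
N(μ_Q, Σ_Q), with moments estimated from the file itself. Assumptions, and
what breaks when they fail:

- **Within-read correlation only.** Σ_Q is n×n; correlation across reads
  (tiles, cycles) is ignored. Clustering (below) recovers part of it.
- **Gaussianity.** Real quality scores are integers on a bounded alphabet,
  often skewed. The Gaussian is used because it is the *worst case* for
  compression at fixed covariance: a code designed for it does no worse on
  the true source. The cost is at high rates — near-lossless operation is
  wasteful compared to entropy coding the discrete alphabet directly, and
  this codec is intended for the low-rate regime (R ≲ 1).
- **Fixed read length.** A precondition, enforced by the reader.

The alphabet bounds are user-declared, not sniffed: auto-detection from
observed characters is unreliable on small or unusually clean files, and a
mis-declared scale surfaces immediately as an out-of-range error.

## Pipeline

1. **Clustering** (`clustering`). Lloyd k-means with MSE assignment.
   Initialization is k *constant* profiles equally spaced over
   [qmin, qmax] (for [33,73], k=3: all-33s / all-53s / all-73s), making the
   whole encoder deterministic. Iteration stops when no read is
   reassigned or after `max_iter` (default 100) sweeps. Empty clusters
   keep their previous mean rather than being reseeded. For k=1 the
   (irrelevant) initial mean is the alphabet midpoint, fixed for
   determinism.
2. **Statistics** (`model_stats`). Per cluster, μ_Q and the
   maximum-likelihood covariance (denominator N — the model asks for the
   empirical second moment; at thousands of reads the N−1 distinction is
   far below sampling noise). Degenerate clusters (0 or 1 reads) fall back
   to a zero covariance and identity factors.
3. **Decorrelation.** Σ_Q is symmetric PSD, so its SVD coincides with its
   eigendecomposition; it is computed with a symmetric eigensolver and made
   deterministic by convention: eigenvalues sorted non-increasing (stable
   on ties), each eigenvector's largest-magnitude entry (lowest index on
   ties) positive. Determinism matters because V, s are written into the
   container and the decoder must use exactly the encoder's factors.
   Eigenvalues in [−10⁻⁸·s_max, 0) are clamped to zero; anything lower is
   rejected as genuinely indefinite.
4. **Allocation** (`rate_allocator`). Reverse water-filling:
   ρⱼ = clip(½ log₂(s_jj/θ), 0, max_bits), with θ bisected until the
   budget residual |Σρⱼ − nR| < 10⁻¹² (bracket: [min₊ s · 4^(−max_bits),
   max s]). Zero-variance components get ρⱼ = 0 — bits spent there buy
   nothing. `max_bits` (default 15) caps codebook sizes; at the cap the
   remaining budget is simply left unused, which can only happen when
   nR > max_bits × (number of positive-variance components).
5. **Randomized rounding.** The shared fractional ρ is realized per read:
   ρ′ⱼ = ⌊ρⱼ⌋ + 1 with probability frac(ρⱼ), else ⌊ρⱼ⌋, so E[ρ′ⱼ] = ρⱼ and
   the *average* rate across reads meets the budget. Redrawing per read
   (not once per file) is what makes that average converge. Draws come
   from a splitmix64 stream — part of the file-format contract, specified
   below — consumed in payload read order, n draws per read (one per
   position, including integer positions, which keeps encoder/decoder
   indexing trivial and bit-exact).
6. **Quantization** (`quantizer`). Each component is normalized by
   √s_jj (divisor floored at 10⁻¹² purely to guard arithmetic; such
   components never receive bits) and quantized with the Lloyd-Max
   codebook for N(0,1) at ρ′ⱼ bits. Values exactly on a threshold go to
   the upper region; out-of-range values saturate into the outermost
   region (no escape coding). Indices are packed MSB-first, each in
   exactly ρ′ⱼ bits, positions in order within a read, reads concatenated
   in cluster order, final byte zero-padded.
7. **Decoding.** Replay ρ′ from the stored seed, unpack, map indices to
   representatives, multiply by √s_jj, emit round(V Q̂′ + μ_Q) with
   half-away-from-zero rounding, clamp into [qmin, qmax] (the model is
   unbounded; clamping keeps output FASTQ valid), and set every position
   whose stub base is 'N' to qmin — an unknown base call should not carry
   a confident score. Output records are sorted bytewise by header; read
   order is deliberately not preserved, and the shared comparator makes
   paired-end files decompress in matching order.

## Lloyd-Max construction

The b-bit codebook for N(0,1) satisfies two conditions simultaneously:
representatives are conditional means of their regions
(rᵢ = (φ(aᵢ)−φ(bᵢ))/(Φ(bᵢ)−Φ(aᵢ))), thresholds are midpoints of adjacent
representatives. For b=1 the solution is closed-form: threshold 0, levels
±√(2/π) ≈ ±0.7979, distortion 1 − 2/π.

The classical approach iterates the two conditions as a fixed-point sweep,
but that map's contraction factor approaches 1 as the level count grows —
at 8 bits it needs tens of thousands of sweeps for a 10⁻¹⁰ tolerance and at
10+ bits it effectively stalls. The codebooks here are instead computed by
Newton iteration on the residual F(r) = condmean(midpoints(r)) − r, whose
Jacobian is tridiagonal (each region touches only neighboring levels), from
quantile-spaced starting points. Convergence is certified by
max|F| < 10⁻¹⁰ — the residual *is* the movement a Lloyd sweep would make —
within a 200-iteration cap; a monotonicity safeguard falls back to one
plain sweep if a Newton step ever crosses levels (not observed in
practice). Interval masses use the Gaussian survival function on the
positive side, because Φ(b)−Φ(a) cancels catastrophically beyond ~6σ, which
is reached at 10+ bits. All depths 0–15 build in under 0.3 s total and are
cached on first use.

## Container format (`.qc`)

Little-endian throughout; all reals IEEE-754 float64.

| field | type |
|---|---|
| magic `QCMP`, version | 4 bytes + uint8 |
| n, N | uint32, uint64 |
| offset, qmin, qmax, max_bits | uint8 ×4 |
| R, seed | float64, uint64 |
| k | uint16 |
| per cluster: count; μ; V (row-major); s; ρ | uint64; n + n² + n + n float64 |
| payload length, payload | uint64 + bytes |

Storing μ, V, s (not Σ) removes any decoder-side eigendecomposition — and
with it all sign/order ambiguity — at an overhead of ≈ 8(n² + 3n) bytes per
cluster, shared by all reads in the cluster. The stub (`.qcs`) is
plain text, three lines per record, in payload order; compressing it is out
of scope (this codec is one component of a whole-file scheme), and it is
excluded from effective-rate accounting, which concerns quality bits only:
R′ = (container bytes × 8)/(n·N).

**PRNG contract.** Draw i (1-based) is
`mix64(seed + i·0x9E3779B97F4A7C15) mod 2⁶⁴` where mix64 is the splitmix64
finalizer (`z ^= z>>30; z *= 0xBF58476D1CE4E5B9; z ^= z>>27;
z *= 0x94D049BB133111EB; z ^= z>>31`); uniforms are the top 53 bits ×
2⁻⁵³. Counter-based, hence platform-independent and vectorizable; any
change to it is a format version change.

## Synthetic data

The generator draws quality vectors from a mixture of multivariate
Gaussians with per-component mean profile, standard-deviation profile, and
AR(1) within-read correlation (Cov[j,k] = σⱼσₖ·ρ^|j−k|), rounded
half-away-from-zero and clamped to the alphabet; bases are uniform ACGT
with a configurable fraction replaced by 'N'. Defaults model a short-read
Illumina lane on Phred+33: mean falling 70 → 50 along the read, sd rising
2 → 6, AR(1) coefficient 0.8, 0.5% 'N' bases. The AR(1) family was chosen
because within-read correlation is precisely the structure the codec's
premise rests on.

What it does *not* emulate: non-Gaussian marginals (real scores are often
skewed or bimodal at single positions), dependence of quality on the called
base, inter-read correlation, platform-specific artifacts. Consequences:
tests on this generator validate the machinery (transforms, allocation,
bit-exactness, rate monotonicity, clustering gains) under the codec's own
model; they do not measure the MSE one would obtain on any particular
instrument's data, which depends on how far that data departs from
Gaussianity. Rounding/clamping already makes the generator's marginals
only approximately Gaussian, which is the mild, realistic mismatch the
tolerance of the statistical tests accounts for (rounding alone adds
≈ 1/12 to each diagonal covariance entry).

Test problem sizes (5000×50 for the rate sweep, 20 000×20 for parameter
recovery, 2000–3000 reads for clustering) were chosen as the smallest at
which sampling noise is comfortably below the tested effects; the whole
suite runs in a few seconds.

## Unit conventions

Storage projections use GB = 10⁹ bytes (decimal, as sequencing consortia
and disk vendors report); side-information overheads use KB = 1024 bytes
(binary, as file listings report). Each is stated where used.

## Known limitations

- Uncompetitive near lossless rates: the real-line Gaussian model ignores
  the finite alphabet, so above R ≈ 2 a good lossless entropy coder can
  win. The design point is R ≤ ~1.
- The stub and container carry no checksums; corruption is detected only
  structurally (magic, counts, payload length).
- Quality scales without a built-in default range (e.g. Solexa's −5 floor)
  require explicit qmin/qmax.
- k-means cost is O(N·k·n) per sweep in memory; the whole block is held as
  float64. Files of tens of millions of reads fit (the model state is
  tiny), but the quality matrix itself must fit in RAM.
- R′ accounting counts the container only; an implementation that carried
  extra per-read state would report higher — comparisons of R′ across
  tools must use the same definition.
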