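# Methods

## The compression model

A dynamic CT acquisition is `I(x, t)`, `t = 0..n−1`, 16-bit signed stored
values. Per voxel the codec keeps the temporal minimum
`C(x) = min_t I(x, t)` and the non-negative deltas
`Δ(x, t) = I(x, t) − C(x)`, packed at the voxel's own width
`B(x) = ⌈log₂(range + 1)⌉ ∈ [0, 16]`. The transform is exactly invertible
for any 16-bit input; compression gains come entirely from `B(x) < 16`,
i.e. from small temporal variation. No spatial prediction, entropy coding
or lossy step is involved, and no inter-voxel state: every voxel
compresses independently, which makes the output bit-identical under any
chunked or parallel execution order.

Any base between the temporal min and max would work; the minimum is used
so deltas are unsigned and the arithmetic stays a single add. `B = 0` is
legal: a temporally constant voxel stores no delta bits at all and reads
return `C` directly.

The width formula is evaluated in exact integer arithmetic
(`(max − min).bit_length()`, table-driven in the vectorised path) — never
through floating-point logarithms.

## Storage layout and random access

Delta records are concatenated voxel-major, time-ascending, with no
padding between records, into a stream of 32-bit words, LSB-first: stream
bit `b` is bit `b mod 32` of word `b div 32`, and values are
little-endian-in-bits. Record starts are the exclusive prefix sum
`O[j] = Σ_{i<j} n·B[i]`, kept as a materialised array for O(1) access
although it is fully derivable from `B`. Since `B ≤ 16 < 32`, any single
delta spans at most two words, so `read_bits` is a constant number of
shift/mask operations; an optional access log on the stream records the
word indices a read touches, which the tests use to verify the two-word
bound. Offsets are 64-bit: at full clinical scale (≈2 × 10⁹ stream bits)
32-bit bit-offsets would overflow, so 32 bits is kept only as a reporting
convention (below), not as the addressing type.

Voxels are linearised C-order, `j = (z·Y + y)·X + x`, x fastest; this is
fixed so the container format is bit-exact across writers.

## Size accounting

`compression_stats` counts the four arrays only:
`16m + (offset-entry bits)·m + 8m + 32·⌈bits(D)/32⌉` versus `16·m·n`
uncompressed, with the offset entry width defaulting to 32 bits for
comparability with implementations that store 32-bit offsets
(`offset_bits=64` reports this package's native convention; the two
differ by exactly `32m` bits). A temporally constant image costs
16 + 32 + 8 = 56 bits per voxel, hence ratio 384/56 ≈ 6.86 at n = 24,
and an image of full-range voxels has ratio < 1 — the codec is built for
CTP-like redundancy, not adversarial inputs.

## Compressed-domain masking

The double threshold `lo ≤ I(x, t) ≤ hi` (default 0–15 HU, the first
stage of CTP noise-reduction filtering) is evaluated from the compressed
arrays. Every intensity of voxel `j` lies in `[C[j], C[j] + 2^B[j] − 1]`;
a bound inside the window sets all `n` mask entries, a disjoint bound
clears them, and only undecided voxels have their delta records decoded
(vectorised per width group). Thresholds are inclusive on both ends —
fixed here because "double threshold 0–15" does not specify strictness —
and are applied to stored intensity values; DICOM rescale slope/intercept
is deliberately not applied (see I/O). The per-time-step mask is the
primary output because it exercises the `(x, t)` access machinery;
`all_timesteps` / `any_timestep` reductions are provided since filters
differ in whether they aggregate over time. The pruned fraction is
reported but never asserted against a threshold: it is a property of the
data, not of the algorithm.

## The synthetic phantom

The generator emulates the statistical structure the codec exploits, not
anatomy: concentric in-plane geometry (air background −1000 HU, a skull
ring at 1000 HU, a brain disc, two CSF regions at ~8 HU, three vessel
discs), identical across slices. Each tissue class follows
`baseline + gamma-variate bolus + N(0, σ)`, rounded and clipped to int16.
The gamma-variate

`A·((t−t0)/(αβ))^α · exp(α − (t−t0)/β)` for `t > t0`, else 0

is the standard parametric bolus shape; it is normalised so the peak is
exactly `A` at `t = t0 + αβ`, which gives the class amplitudes direct HU
meaning. Defaults: brain baseline 30 HU with 25 HU enhancement (temporal
range ≈ tens of HU → ~5–6 bits with the default σ = 2 HU noise), vessels
46 HU baseline with 145 HU amplitude (range ≈ 145 HU → 8 bits), CSF
baseline 8 HU so the clinical 0–15 HU window selects real structure.
These were chosen once to land in the bit-width regime of clinical CTP
brain data — the bulk of head voxels at ≤ 8 bits — and are not fitted to
any measured dataset.

The default acquisition schedule is one consistent reading of the
clinical whole-brain CTP protocol: 14 scans 2.5 s apart from t = 0, five
more 5 s apart, then five late scans 30 s apart — 24 strictly increasing
times (gap multiset {2.5×13, 5×5, 30×5}). The codec never uses the times
numerically; they only shape phantom curves and travel as metadata.

Motion is modelled as integer in-plane shifts of whole frames with air
fill — interpolation would break integer semantics and the codec only
cares that shifted frames widen temporal ranges along tissue boundaries
(the skull-edge effect seen in clinical width maps). Noise is additive
Gaussian; real CT noise is spatially correlated and intensity-dependent,
but only the temporal range distribution matters here.

What passing tests on phantoms do and do not show: they demonstrate
exactness (losslessness, random-access agreement, mask equivalence) on
data with realistic temporal-range statistics, and qualitative size
behaviour (ratios near ~2.2–2.4, most widths ≤ 8 bits). They do not
certify compression ratios on patient data, which depend on scanner
noise, slice thickness and true patient motion.

## Container and I/O choices

The `.dicopp` container is fully little-endian with an 8-byte magic, a
version, flags, geometry, declared payload lengths and a CRC-32 over the
payload; `C`, `B`, `D` are always stored, `O` only behind a flag (default
off: it is reconstructed by one prefix sum on load, and at 64 bits per
entry it would dominate the overhead). Bad magic, unsupported version,
truncation, checksum mismatch and geometry/length inconsistencies raise
distinct typed errors; persisted offsets are cross-checked against the
prefix sum on load.

Input adapters produce `(t, z, y, x)` int16 arrays from DICOM series
directories (slices grouped by temporal position index, falling back to
acquisition time, falling back to equal instance-number blocks; sorted by
slice position), 4D NIfTI, or a minimal raw headered format. Stored pixel
values are used verbatim: rescale slope/intercept is metadata, because
losslessness must be defined on the stored bits, and mask thresholds are
therefore in stored-value units.

## Numerical and testing notes

- Bulk pack/unpack routes go through a flat bit array and
  `numpy.packbits`/`unpackbits` (little bit order); the scalar
  `read_bits`/`write_bits` path is the independent two-word shift/mask
  implementation, and the tests cross-check the two against a bit-by-bit
  boolean oracle.
- Deltas never exceed 65535, so all delta arithmetic fits uint32;
  reconstruction adds in int32 before the final int16 cast.
- Property tests (hypothesis, derandomised) cover round trips at widths
  0–32 and losslessness over random shapes with n ∈ {1, 2, 24} including
  the int16 extremes; structural invariants (offset identity, stream
  length, width bound) are asserted on every compressed object the suite
  creates.
- Test problem sizes: exhaustive random-access checks up to 4×8×8×8,
  sampled checks (10⁴ positions) on a 24×32×128×128 phantom, 50 seeded
  phantoms for mask equivalence; the acceptance script uses a
  24×16×128×128 phantom with three one/two-voxel motion events. These
  sizes keep the full suite around ten seconds while every guarantee is
  exact, not statistical.

## Known limitations

- Spatial redundancy is deliberately unexploited; ratios are bounded by
  temporal range statistics (~2.2 on CTP-like data).
- The phantom's geometry is identical across slices and its noise model
  is simplistic; it is a codec testbed, not a perfusion simulator.
- DICOM reading covers common single-frame CT series layouts only;
  multi-frame (enhanced CT) objects and DICOM writing are out of scope.
- The 32-bit offset reporting convention cannot address a full clinical
  dataset; it exists purely for size comparability.
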