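# Methods

## Problem and model

Salt-and-pepper (impulsive) noise drives individual 8-bit pixel entries to
the dynamic-range extremes 0 or 255, typically through transmission or
acquisition errors.  At high densities (50–90% of entries corrupted) the
difficulty is not deciding *that* a pixel is corrupted but finding any clean
information near it to repair it with: a plain median over a small window is
itself dominated by impulses.  This package implements a repair strategy that
reconstructs the corrupted pixel's entire neighbourhood before estimating the
pixel, in three stages, preceded by a detection stage.  Each colour plane is
processed independently; grayscale images are promoted to three identical
planes on load, so impulses can strike any plane of any image.

### Detection (two-round directional thresholding)

Local variation around position (x, y) is measured as V_ij = |K_i ⊗ I_j|,
the absolute response of plane I_j (j = R, G, B) to sixteen integer, zero-sum
directional second-derivative kernels rotated in steps of π/8.  In round one
(K1–K8, probing the adjacent ring) the rule is: if

    M1(x, y) = min_{i=1..8, j=1..3} V_ij(x, y) > T,

i.e. even the calmest of the 24 measurements shows variation above the
threshold T, the location is suspicious; the (kernel, channel) argmin
selects the channel whose value is then required to be an extreme (0 or 255)
for the location to be flagged.  Otherwise round two repeats the test with
K9–K16, whose supports skip the eight immediately adjacent pixels — a pair
of connected equal-valued impulses cancels a ring-1 probe but not a ring-2
probe.  Channel flags, which the restorer consumes, are derived as "flagged
location AND that channel's value is extreme".  Argmin ties break by lowest
kernel index, then lowest channel index, for determinism.

The exact kernel coefficients are configurable (plain-text override file);
the defaults are three-point stencils (+2 at the centre, −1 at ±v) along
axis/diagonal directions and knight-move directions for the π/8 family, with
doubled offsets in round two.  Responses are computed in wide signed integer
arithmetic before the absolute value.

**Threshold default.**  T = 0.  With integer kernels any genuine variation
produces a response ≥ 1, and detection misses occur only where some probe
pair cancels exactly (response 0); raising T can therefore only lose recall,
so T = 0 maximises F1 on the synthetic fixture suite.  T is exposed on the
CLI (`--threshold`).

**A structural property worth knowing.**  Because M1 minimises over channels
as well as directions, an impulse confined to a single plane of a locally
clean image is invisible: the clean planes contribute a zero response.  The
detector is therefore evaluated (and is effective) on *whole-pixel*
impulses — the coupled injection mode — and in the sparse regime (a few
percent density) where every corrupted site is locally isolated; there its
recall exceeds 99% with zero false positives on smooth extreme-free images.
As density grows, the probability that both probes of some direction land on
equal-valued impulses grows as (d/2)² per direction, and recall degrades
(≈97% at 10% coupled density).  For this reason the benchmark harness can
bypass detection and restore from the injection truth mask, which is also
how the replacement engine — the actual contribution — is evaluated.

### Restoration (nested filtering, then morphological completion)

For each flagged entry, with default windows sw1 = 7 and sw2 = 5:

1. **Main window.**  A sw1×sw1 workspace is copied out around the pixel; its
   48 non-centre positions are each *clean* or *noisy* per the mask.  The
   centre is the pixel under repair: it never contributes a value.
2. **Nested (secondary) filtering.**  Every noisy neighbour is estimated as
   the median of the non-noisy pixels inside its own sw2×sw2 window, read
   from the **original** plane.  Estimates never feed other estimates, and
   repairs of other centres are never read: every pixel's repair depends
   only on original data, so results are order-independent and
   parallelisable.  Neighbours whose secondary window contains no clean
   pixel remain unrestored.
3. **Dilation fill.**  Remaining gaps are filled by scanning the workspace
   left-to-right, top-to-bottom: a gap whose 4-connex structuring-element
   probe intersects the useful set (clean + stage-1 + stage-2 values) takes
   the maximum or minimum of those candidates — alternating, starting with
   the maximum, toggling after every successful fill — and joins the useful
   set immediately.  The alternation avoids flooding a region with a single
   repeated value.  Passes repeat until a fixpoint; since the window is
   4-connected, one non-empty useful set suffices to fill everything, and
   isolated corners that a single pass would miss are caught by iteration.
4. **Replacement.**  The pixel takes the lower median of the useful
   neighbour values (degenerate positions excluded).

Replacements are written to a separate output buffer; unflagged entries are
never modified.

**Degenerate pixels.**  A flagged pixel whose entire combined reach — every
position within Chebyshev distance Ms = ⌊sw1/2⌋ + ⌊sw2/2⌋ = 5 — is corrupted
has no information to draw on.  Policy: keep the original value and count it
in the report.  At d = 0.9 such configurations occur with probability
≈ 0.9^120 ≈ 3·10⁻⁶ per interior pixel (more near mirrored corners), i.e. an
expected handful per 256×256 plane; at d ≤ 0.7 they are vanishingly rare.
This is an intrinsic property of fixed windows at extreme densities; window
growth is deliberately out of scope.

### Numerical conventions

- **Medians** use the lower-of-two convention for even counts, everywhere:
  the replacement is always an intensity actually observed (or estimated) in
  the neighbourhood, never an invented average.
- **Mirror padding** reflects without repeating the border pixel
  ([a,b,c] → [b,a,b,c,b]); size Ms = 5 for the default windows.  Detection
  and restoration share this single convention; all coordinates are 0-based,
  row-major.
- **Alternation state** is per-workspace, reset to "maximum" for every
  flagged pixel.
- Intensities are carried as int64 inside the pipeline; outputs are uint8.

### Metrics

PSNR = 10·log₁₀(255²/MSE) with MSE the mean of the three per-channel MSEs,
computed in double precision; identical images report +∞ by convention.
NCD is the summed Euclidean luminance/chrominance error divided by the
summed luminance/chrominance magnitude of the original; the colour space is
analog ITU-R BT.601 YUV (Y = 0.299R + 0.587G + 0.114B and the standard U, V
rows).  Digital YCbCr with offsets would shift NCD slightly; BT.601 analog
is fixed and recorded in `nfmo.metrics.BT601_YUV`.  An all-black original
makes NCD undefined and raises an error rather than returning 0/0.

## Noise model

Corruption is per (location, channel) with probability d; a hit becomes 255
with probability `salt_fraction` (default 0.5), else 0.  The coupled mode
(`per_channel=False`) corrupts all three channels of a hit location together
with independent polarities.  The generator is
`numpy.random.Generator(PCG64)`, recorded in the spec object, so a
(seed, density) pair regenerates bit-identical noise across runs.

## Synthetic fixtures

The fixture families emulate, one trait at a time, what the method's real
inputs (fundus photographs, MRI slices, chest X-rays exported as 8-bit
rasters) look like: flat regions (`constant`), smooth ramps (`gradient`),
organ-like plateaus (`piecewise-constant`), periodic anatomy
(`repeated-texture`), and a bright structured disc on a near-black ground
(`dark-background-disc`).  Clean fixture intensities stay inside 8..247:
well-exposed clean tissue rarely saturates, and keeping clean data off
{0, 255} makes injected impulses the only extremes.  What passing tests on
these fixtures do **not** show: performance on real anatomical texture
(vessel trees, trabecular bone), on clean images that genuinely contain
saturated pixels, or on non-impulsive noise (Gaussian, Rician, quantum
mottle — explicitly out of scope).

The worked-example fixture (`make_worked_example`) reproduces the structure
of a high-density neighbourhood: 3 clean values among 48, clustered so that
nested filtering restores a strict subset (12 positions, by secondary-window
reach) and the dilation completes the remaining 33.

## Problem sizes used in the test suite

Oracle-equivalence checks run ~100 random 24×24 fixtures against a literal
loop-everything reference; the benchmark sweeps run 256×256 fixtures across
densities {0.1, 0.3, 0.5, 0.7, 0.9} with three seeds per density, restoring
from the truth mask.  These sizes match the scale of the medical images the
method targets (256×256) while keeping the full suite fast.

## Known limitations

- Detection shares the min-over-channels blindness described above; it is
  not a general single-plane impulse detector.
- At d = 0.9 a few flagged pixels per 256×256 plane are degenerate and kept
  unchanged (see above); the benchmark reports their count per run.
- Fixed windows: no adaptive growth, no vector (joint-channel) medians.
- The default kernel coefficients are a documented stand-in with the
  required structural properties; published coefficient sets can be
  substituted via the override file without touching code.
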