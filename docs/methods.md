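# Methods

This note records the models, conventions, parameter choices and numerical
details behind `subpix`, and what the synthetic benchmarks do and do not show
about real data.

## Coordinate and intensity conventions

Pixel *(x, y)* has its center at integer coordinates and spans
[x−½, x+½) × [y−½, y+½); *x* is the column index, *y* the row index, origin
top-left, arrays indexed `img[y, x]`. Images travel in memory as floats in
[0, 1]; on disk as 8/16-bit grayscale PNG/TIFF. Thresholds live on the [0, 1]
scale with the 0–255 integer representation reported alongside (a value *v*
maps to bin `round(255 v)`). "Above threshold" is always strict (`I > t`).

## Scene simulation

A particle is a bivariate Gaussian with zero correlation, integrated exactly
over each pixel square (product of erf differences). The ¼ prefactor is kept
so that an isolated still particle integrates to exactly its `flux` over an
unbounded grid; since a composed scene is rescaled by its global maximum
anyway, this only makes per-particle flux meaningful, it does not change any
downstream result. A particle moving with constant velocity **v** over the
unit exposure has center μ(t) = μ + v(t − ½); the time integral is evaluated
by midpoint quadrature with `time_steps = 64` nodes by default. Halving the
step changes no pixel by more than 1e−4 of the flux for speeds up to
15 px/exposure (tested), which is far below every noise level studied.

Noise is applied to the rescaled [0, 1] image in a fixed order: additive
white Gaussian noise (standard normal scaled by 1/SNR, then clipped to
[0, 1]), then salt-and-pepper (each pixel independently forced to 1 with
p_salt, to 0 with p_pepper), then optional quantization (round-half-up).
The order of the two noise stages is a convention of this package; AWGN and
salt-and-pepper draw from independent streams spawned from one scene seed,
so every simulated image is bit-reproducible.

**Benchmark layout.** The many-particle experiments place one particle per
20 × 20 px cell, jittered uniformly within the central pixel of the cell
(sub-pixel offsets uniform in [−0.5, 0.5]). This guarantees ≥ 19 px
center-to-center separation, matching the "mostly disjunct" particle images
of the target application, and makes 10,000 particles a 2000 × 2000 px
image. Pair scenes for the separation study put two particles at a fixed
center distance and a uniformly random orientation in each cell.

What the simulator does *not* model: shot noise and dark current, PSF
aberrations and Airy side lobes, the Gaussian laser-sheet intensity profile,
particle-size dispersion, and frame-to-frame motion. Passing benchmarks
therefore demonstrate algorithmic correctness and noise robustness under the
stated noise model, not end-to-end camera fidelity.

## Preprocessing

The Hann kernel weight at Euclidean radius r from the center is
w(r) = ½[1 − cos(2π(r − (N−1)/2)/(N−1))] for r ≤ (N−1)/2, else 0. The kernel
is normalized to unit sum so filtering preserves mean intensity and leaves
thresholds on the same scale; filtering is correlation with reflect padding
(the kernel is symmetric, so correlation equals convolution).

Otsu's threshold maximizes the between-class variance over the fixed 256-bin
histogram; ties break to the lowest bin. It is implemented with the classic
cumulative-moment recurrences and is verified in the tests against an
exhaustive search over all 255 splits and against scikit-image. Intermodes
thresholding smooths the histogram with a 3-bin running average (ends
reflected) until exactly two strict local maxima remain (plateaus collapse to
their leftmost bin; iteration cap 10,000) and returns the mean of the two
mode positions. Only the threshold value feeds detection — positions are
always computed from gray values, never from a binarized image.

## Blob detection

Above-threshold pixels are partitioned under the transitive relation
"center distance ≤ r" (sparse-graph connected components, verified against a
brute-force closure oracle). The inclusive predicate is deliberate: with it,
r = 1 reproduces 4-connected labeling (the classic simply connected moment
method) and r = 1.5 connects across corners and single-pixel gaps. A strict
`< r` reading would leave r = 1 with no connections at all, contradicting the
classic method it is meant to recover.

Constraint filtering keeps blobs with at least `m_p` pixels, extents
x_d, y_d (maximum coordinate differences; 0 for a single pixel) of at least
`m_x`, `m_y`, density |P|/(x_d·y_d) ≥ `m_d` (taken as +∞ when the envelope is
degenerate) and mean intensity ≥ `m_bd`. All minima default to 0.

The stadium streak model treats a moving particle image as a disk of radius ρ
swept along a segment of length l: A = πρ² + 2ρl and l_m = l + 2ρ, inverted
through the quadratic (π/4 − 1)l² + (1 − π/2)l_m·l + (π/4)l_m² − A = 0
(lower root, clamped to [0, l_m]; a negative discriminant is flagged and
returns 0). The effective area A is, by default, the above-threshold pixel
count ("binary" mode); an "intensity" mode divides the summed intensity by a
caller-supplied plateau level. The source material's definition of A
(a moment divided by the intensity sum) is self-cancelling as printed, so
both readings are exposed and neither is claimed to be the original intent.
l_m is the maximum pairwise pixel-center distance. The orientation angle uses
the two-argument arctangent α = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂) ∈ (−90°, 90°],
avoiding the quadrant ambiguity of a plain arctan; rotationally degenerate
blobs raise an "undefined orientation" error instead of returning noise.

## PSF refinement

Tiles: the half-size δ of a detection's square tile is half the Chebyshev
distance max(|Δx|, |Δy|) to its nearest neighbouring detection, capped at
`delta_max = 15` px (the cap also sizes a lone particle's tile and bounds
per-fit cost). Bounds are the floor/ceil expansion of center ± δ clipped to
the image; a pixel claimed by two expanded rectangles belongs to the
Chebyshev-nearer owner (ties to the lower index), so tiles never overlap.

The model is the radially symmetric generalized Gaussian
amp · p^{1−1/p}/(2σΓ(1/p)) · exp(−r^p/(pσ^p)) plus constant background b,
evaluated at pixel centers (p = 2 is exactly the normal profile). Fitting
pixel-center samples to pixel-integrated data inflates the fitted width to
roughly √(σ² + 1/12) — a shape effect the free exponent partly absorbs — but
leaves the fitted *center* unbiased by symmetry, which is the quantity of
interest. An explicit amplitude is fitted by default: rescaled scenes give
every particle an arbitrary flux, so a fixed-normalization profile cannot
match the data; `fit_amp=False` freezes it for callers who prefer the fixed
form. Fits run on the original, unfiltered image.

Optimization: L-BFGS-B over (x, y, σ, p, b[, amp]) with bounds
σ ∈ [0.1, 10] px, p ∈ [0.5, 10], b ∈ [0, 1], center within the tile,
amp ∈ (0, 10·amp₀]; tight tolerances (ftol 1e−14, gtol 1e−10, ≤ 200
iterations) because the default stopping rule can stall on the very shallow
objectives of low-noise tiles. Gradients are symmetric difference quotients
with step 1e−6·max(1, |θ|), one-sided at an active bound. Initialization:
center from the moment method, σ from the blob's second central moments,
p = 2, b = tile median, amplitude matching the brightest blob pixel above
that background (peak matching; initializing from total flux instead
overshoots the peak several-fold and occasionally strands the optimizer in a
p→0.5 local basin). A fit that fails, or does not improve the residual,
returns the moment-method center flagged unconverged — refinement never
loses a particle.

## Pipeline presets

Stage order: gamma → Hann filter → threshold selection → blob extraction and
filtering → base-corrected centroid (all on the preprocessed image) → PSF
refinement (original image). `alg01`–`alg05` and `alg08`–`alg12` are moment-
method variants; `alg06`/`alg07` add the PSF fit. Manual-threshold presets
require the user's threshold; the benchmark experiments in this repository
use 0.1 on the [0, 1] scale for SNR = 100 scenes — ten noise standard
deviations above the background, and safely below the dimmest σ = 1
particle's peak pixel (≥ 0.79 of the global maximum across sub-pixel
placements). The separation experiments use the fixed high threshold
130/255 ≈ 0.51.

`alg09` ("search radius r > 1") defaults to r = 2.5. At 20% pepper noise a
single-pixel-wide band of dead pixels across a blob leaves a minimum crossing
distance of 2, so r = 1.5 — enough for corner connectivity — still splits
about 3% of particles, and the fragments overlap genuine small blobs in size,
which no pixel-count constraint can undo. r = 2.5 bridges those bands while
remaining far below the ≥ 19 px particle spacing; combined with m_p = 4 (to
reject rare isolated above-threshold pixels) it detects all 10,000 particles
of the pepper benchmark exactly, across seeds. The pepper experiments
therefore run alg09 with r = 2.5, m_p = 4 and alg08 with r = 1, m_p = 4.

## Evaluation

Matching is mutual nearest neighbour within `max_radius` (default 2 px;
1.5 px in the pair experiments where two truths sit 3–10 px apart): a truth
point and a detection pair iff each is the other's nearest neighbour. This
rule is this package's own operationalization; on well-separated scenes it
coincides with optimal assignment (tested against the Hungarian algorithm).
"All correctly detected" means no misses and no spurious detections. RMSE is
computed over matched pair distances and is interpretable as a position
standard deviation because matched errors at high SNR are zero-mean (tested).

Velocity-error propagation uses the factor 2 (not √2) in
Δv = 2·Δx·(mm/px)/dt, matching the printed reference arithmetic it
reproduces; the thermal-speed scale is the 1-D √(k_B T/m) with
m = ρ(π/6)d³ and room temperature fixed at 293 K.

## Problem sizes

The test suite runs scenes of 100–800 particles (about 45 s in total); the
acceptance script uses 2,000 particles for the fitted-pipeline RMSE, the
full 10,000 for the pepper count, 40–60 pairs × 2–3 replicate seeds per
distance for the separation experiments. These sizes give sampling error
well inside the margins being tested (e.g. RMSE standard error ≲ 3% at
n = 2,000) at interactive runtimes.

## Known limitations

- The intensity-mode streak area needs a caller-supplied plateau level; no
  automatic estimate is provided.
- Streak lengths recovered from thresholded blobs carry a threshold-dependent
  bias of a few pixels at σ = 1 (the above-threshold region is not exactly
  the half-max stadium); angles are accurate to ≲ 1° for l ≥ 5 px.
- No multi-frame linking: the package localizes within single frames.
- Simultaneous global fitting of all particles is out of scope (unreliable
  and 100–700× more expensive in the underlying study); fits are local per
  tile.
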