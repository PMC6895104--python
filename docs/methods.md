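# Methods

This note documents the models, numerical choices and limitations behind
`ardic`. It complements the README, which describes what the package
computes; here is *how*, and why the defaults are what they are.

## Displacement measurement (PIV engine)

Displacement between a reference and a current frame is estimated by
window cross-correlation on a regular grid. Windows are mean-subtracted
and variance-normalised, correlated via zero-padded FFT, and the circular
correlation map is divided by the linear-overlap taper `((w−|Δy|)(w−|Δx|)/w²)`
so partial overlap does not pull the peak toward zero lag. The integer
peak is searched inside the pass's search radius; sub-pixel position
comes from a nine-point least-squares Gaussian fit (a paraboloid fitted
to the log-correlation over the 3×3 neighbourhood), falling back to
per-axis three-point Gaussian and then parabolic fits where the
neighbourhood admits no Gaussian model.

The default schedule is (window, search, spacing) = (64, 16, 32) →
(32, 8, 24) → (32, 8, 24) px: a coarse pass whose field seeds a finer
pass as integer window offsets, with the final pass iterated once on its
own output so every window is re-interrogated near its true offset. The
24 px final vector spacing matches the standard vector block whose area,
at the reference optics of 0.9616 µm/px, is 532.6 µm². All schedule
values are configurable; windows may not increase across passes and
spacing may not exceed the window.

Vector quality is the ratio of the primary correlation peak to the
secondary peak (excluding the 5×5 neighbourhood of the primary, which
belongs to the primary's own lobe). The validity cutoff of 1.5 was set
from simulation: across 1000 uncorrelated pure-noise window pairs more
than 95% fall below 1.5, while genuine matches on synthetic speckle sit
above ≈2. Between passes a normalised-median test (3×3 neighbourhood,
threshold 2.0, ε = 0.1 px) replaces outliers with the median of valid
neighbours; the test is only applied to vectors with a complete
8-neighbour set, because asymmetric border neighbourhoods bias the median
in steep-gradient fields and misfire the test. A vector with no valid
neighbours stays invalid — nothing is fabricated. Replaced vectors are
flagged (`replaced`); they are interpolations, not measurements.

Measured accuracy under the study conditions: uniform shifts are
recovered with ≈0.02–0.03 px RMS error per vector (worst single vector
up to ≈0.1 px — the familiar random error of non-deforming window
correlation); the sinusoidal benchmark (amplitude 2 px, wavelength
256 px) is recovered with ≈0.08 px RMSE. Window deformation (affine
shape functions) is deliberately out of scope; it is the main route to
improving the steep-gradient error.

## Adaptive reference selection

Each analysed frame is scored by the Frobenius norm of its displacement
matrix over valid vectors (invalid vectors are excluded; the norm is in
px, conversion to µm is presentation only). A frame whose norm falls
below `t_adapt` becomes the reference for *subsequent* frames; its own
field is still reported against the previous reference, so every frame's
measurement is well defined. Displacements are reported relative to the
active reference, not chained across references — each new reference is a
rest state near zero absolute displacement. A chained-accumulation mode
(`ARConfig.accumulate`) exists for genuinely drifting tissue.

`estimate_tadapt` measures the norm between two caller-designated rest
frames and rounds it *up* to the next multiple of the refinement step
(ceiling; never below one step). Rounding up is the conservative choice:
a threshold below the true noise floor silently disables re-referencing.

Refinement raises the threshold in `refine_step` (default 0.1) increments
until the baseline of the norm series stops drifting. "Baseline" is made
operational as per-cycle minima: local minima of the norm series
separated by at least half the dominant period (found from the FFT of the
detrended series), with the drift defined as the least-squares slope of
those minima versus cycle index. The default tolerance is 0.1 norm units
per cycle. These definitions (minima spacing, slope criterion, tolerance)
are package choices; the underlying criterion — raise the threshold until
the baseline no longer grows — is the method itself.

## Kinematics and strain

Velocity is the backward difference of displacement,
`v = (d_t − d_{t−1}) · pixel_size / Δt`, in µm/s. When the reference
switched between the two frames, `d_{t−1}` is first re-expressed against
the new reference by subtracting the new reference's recorded field (the
switch frame is near rest, so the correction is small);
`velocity_series` resolves this automatically from the recorded
reference indices.

Strain is the infinitesimal (small-deformation) tensor: observed tissue
strains are ≲10%, so the linear components suffice and no finite-strain
measure is used. Gradients are central differences on the vector grid
(one-sided at borders); the shear component carries the tensorial ½
factor, ε_xy = ½(∂u/∂y + ∂v/∂x). Principal strains use the closed form
ε₁,₂ = (ε_xx+ε_yy)/2 ± √(((ε_xx−ε_yy)/2)² + ε_xy²) with
θ_p = ½·atan2(2ε_xy, ε_xx−ε_yy); the trace ε₁+ε₂ = ε_xx+ε_yy is conserved
to rounding. Optional Gaussian pre-smoothing of (u, v) (σ in grid cells,
off by default) tames the noise amplification of differentiation.

## Contraction metrics

A grid point contracts when its displacement magnitude exceeds the
average in-vivo single-sarcomere shortening, 0.14 µm; the 0.56 µm
alternate threshold is exactly four sarcomeres. Coverage uses valid grid
points as the denominator — border windows carry no measurement.

The BPM signal is the spatial mean of |d| (µm) over grid points that
exceed the threshold at least once in the video; with no such points the
rate is reported as absent, never 0. The FFT estimator mean-detrends,
applies a Hann window, zero-pads ≥8×, and takes the peak in
(0.2 Hz, 0.95·Nyquist); the guard band below Nyquist prevents an aliased
harmonic that folds onto exactly fps/2 (as happens for 75 BPM sampled at
5 FPS) from tying with the fundamental. An estimate is flagged
unreliable when the peak power is less than 50× the median band power —
white-noise signals measure ≈10 on this statistic, clean pulse trains
≥10⁴. The peak counter requires maxima above mean + 0.5 σ separated by
≥0.33 s (≈180 BPM refractory, above the ~150 BPM ceiling that 5 FPS
sampling supports).

Contraction volume is CV = Σ_masked |d|_µm · block_area / 532.6 µm²; with
the default 24 px grid the areas cancel and CV reduces to the plain sum
of supra-threshold magnitudes. Frames within 1 σ below the maximum CV are
"high CV". The high/low comparison uses Welch's unequal-variance t-test
on per-frame maxima of speed, tensile ε₁ and compressive ε₂ — the test is
a pragmatic choice, reported with means ± SEM and group sizes.

## Contraction trees

Per frame, supra-threshold grid masks are labelled with 8-connectivity;
components below 4840 µm² (ten vector units at the reference scale) are
dropped. Cycles are maximal runs of frames with any surviving region.
Within a cycle, nodes are processed in ascending area order; a node's
parent is the smallest region in the nearest later frame whose member set
contains the node's centroid (centroid rounded to the nearest grid cell;
the forward frame-by-frame search tolerates brief mask dropouts). Nodes
with no containing region in any later frame of the cycle are roots;
depth runs root-down, so the earliest small regions are the deepest
leaves. Lineage therefore runs forward in time toward the merged
peak-contraction region.

Origins are leaves of multi-node trees, ranked by depth (deeper = leads
the contraction longer = stronger origin) with ties broken by total area
along the leaf-to-root path. Because one physical origin produces one
leaf per cycle, leaves are consolidated across cycles by centroid
proximity (≤1.5 grid cells) before ranking. The ASC map assigns each
grid point the maximum depth of any covering node (a summing mode is
available); the ASTC tables expose every node (position, time, area,
depth, cycle, origin/singleton flags) and edge, and inter-origin
propagation delays are differences of per-cycle leaf onset times,
quantised to the frame period.

## Synthetic fixtures

The generator emulates the reference acquisition: 5 FPS, 0.9616 µm/px,
speckle-textured frames warped by analytic displacement fields (bicubic
spline sampling at x − d(x); a spectral variant upsamples by FFT first).
Speckle is ~12 Gaussian blobs of σ = 1 px per 100 px², additive and
clipped to [0, 1] — dense, sharp texture chosen for correlation quality.

A beating origin superposes a Gaussian translation bump (peak `A`,
default 3 px ≈ 2.9 µm — the bulk tug of the contracting patch, which
makes the displacement maximum blob-like as in real recordings) and a
radial inward pull (peak `A/2` on the ring r = σ) whose negative
divergence yields compressive strain at the centre with tensile lobes
outside. The temporal envelope is a raised cosine clipped at zero,
`max(0, cos(2πft+φ))²`, so genuine rest frames separate beats; an
envelope below 1% of its peak defines "rest". The default beat rate is
1.25 Hz (75 BPM) with σ = 64 px on a 256² frame — contraction zones in
real monolayers span a large fraction of the field of view, and a wide
pulse also keeps window-averaging attenuation of the peak below 5%.
Origin-lineage fixtures instead use 0.4–0.5 Hz and σ = 20 px: at 5 FPS a
1.25 Hz beat occupies a single frame and every region would be a
singleton, whereas the slower rate gives the multi-frame growth that
depth analysis needs; origin centres are placed between vector-grid
points because a radial pulse centred exactly on a grid point leaves a
one-cell hole in its supra-threshold mask.

Inter-cycle drift models the minor frame shifts left after each
contraction cycle: continuous (px/frame) or stepped per cycle. The
threshold-refinement fixture uses a per-cycle step graded linearly across
x and sized so the measured rest-to-rest Frobenius norm is ≈1.45 — the
latent displacement the adaptive threshold must clear. The grading, the
baseline offset of three cycles, and the calibration constant
`UNIFORM_SHIFT_RESPONSE = 1.0105` (the PIV response to such a step,
measured once during development) exist so every vector samples a
different sub-pixel phase and the estimator's phase-dependent biases
average out, keeping the floor stable at ≈1.43–1.48 across textures.
With an initial threshold of 1.3 and step 0.1 the refinement then
reproducibly runs 1.3 → 1.4 → 1.5: below the floor no rest frame ever
re-references and the baseline drifts at the fixture's drift rate; at
1.5 every cycle re-references and the baseline is flat.

What the fixtures do *not* model: photorealistic cell texture,
out-of-plane motion, illumination drift, non-rigid texture decorrelation
between cycles, and beat-to-beat rate variability. Passing tests
demonstrate correctness of the measurement and analysis chain under
known ground truth, not robustness to those real-data effects.

## Degenerate inputs and edge behaviour

Constant windows yield flagged invalid vectors, not exceptions; an
all-invalid field has no Frobenius norm and raises. A flat displacement
signal reports BPM as absent. Stacks need ≥2 frames, and a frame rate
must come from the file or the caller — there is no silent default.
Writers use fixed column orders and a fixed float format, so identical
inputs produce byte-identical CSV output.

## Known limitations

* No window deformation: strain gradients steeper than ≈0.05 px/px at
  the final window inflate the random error; the unresolvable bands of
  the benchmark pair are flagged rather than measured.
* Single global reference: regionally independent references (useful for
  tissues whose parts rest at different times) are not implemented.
* The normalised-median validator assumes locally flat flow; on very
  low-noise data it can replace a legitimately curved vector with its
  neighbourhood median (replacements are always flagged).
* Video containers (AVI/MP4) are read through imageio and require an
  ffmpeg backend; multi-page TIFF is the native format.
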