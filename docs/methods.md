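# Methods

This note documents the models, parameter choices and numerical decisions
behind `merlin_zte`, and what the synthetic validation does and does not
establish about real data.

## Trajectory model

Spoke directions are unit vectors on the k-space sphere. The interleaved
spiral phyllotaxis is generated exactly from its closed form: azimuth
φ(i,j) = (i·k + j)·φ_G, z(i,j) = 1 − (i·N_i + j)·Δz with
Δz = 2/(N_s·N_i − 1), polar angle θ = acos z. The acos polar modulation
(linear z sweep) — rather than the square-root modulation of the original
phyllotaxis construction — makes the spoke density uniform on the sphere
for an isotropic field of view; the spherical-Voronoi diagnostic
(`voronoi_density`) verifies this: cell-area coefficient of variation
< 0.15 away from the two polar spokes, versus a clearly larger CV for the
square-root variant at equal spoke count (a unit test pins the ordering).
The Fibonacci stride k = F(s) with F(1) = F(2) = 1 is forced by the
convention that the 8th Fibonacci number is 21; with N_i = k interleaves
the union of interleaves is the sequential golden-angle set exactly (tested
to 1e-9 degrees of azimuth; the poles are excluded from the azimuth
comparison because azimuth is undefined there, and their direction vectors
are compared instead).

Acoustic noise itself is a hardware quantity and out of scope; its software
surrogate is the great-circle step between consecutive spokes
(`gradient_step_metric`). Interleaf-boundary transitions are excluded from
the silent statistic because the scanner ramps gradients between segments.

**k-space units.** Coordinates are in cycles per FOV, so the Nyquist shell
is |k| = MAT/2; image coordinates are FOV-normalized in [−0.5, 0.5) with
the center voxel at index MAT/2. This makes the translation phase ramp
dimensionless (mm inputs are divided by the FOV once, at the boundary).

**Deadtime gap.** The transmit-receive switching time removes a fixed
number of initial *samples* from every spoke (2 at ±31.25 kHz and the
simulated 30–40 µs switching time). Because WASPI runs at 0.125 gradient
scale, its k-space hole is 8× smaller in absolute units — which is exactly
why the WASPI data can calibrate the center. (An alternative reading,
"equal gap in absolute k-units", would leave WASPI *less* central coverage
and at small readout lengths no valid WASPI samples at all; it was
rejected as unphysical.)

**WASPI directions.** The pre-scan needs uniform, not smooth, coverage; a
deterministic spherical Fibonacci lattice is used (nearest-neighbor angular
spacing CV < 0.25 at 512 spokes), recorded in the container metadata.

## Simulator

The simulator is the ground-truth generator for everything downstream, so
motion is injected in k-space, exactly: for a segment at head pose
T = (R, Δ̄) (material points move p ↦ Rp + Δ̄ about the image center), the
acquired sample at nominal coordinate k̄ is S(Rᵀk̄)·exp(−i2π k̄·Δ̄/FOV),
with S the static multi-coil spectrum evaluated by a high-accuracy gridding
NUFFT (oversampling 2, kernel width 6). No image interpolation enters the
data path; `apply_rigid_image` (linear resampling) exists only to build
reference images and for the rotation-equivalence cross-check. The
correction stage applies literally the inverse operations, so
ground-truth-corrected data reproduce a static acquisition at the corrected
coordinates to ~1e-16 relative — the round-trip oracle that pins all sign
conventions. Rotations compose as R = Rz·Ry·Rx (intrinsic, centered); only
matrices cross module boundaries.

The phantom is the modified 3D Shepp-Logan ellipsoid set, lightly smoothed
(Gaussian, σ = 1 voxel) in the scenario fixtures. The smoothing emulates
the finite point-spread function of a real acquisition and keeps the
object approximately band-limited on the sampled ball: the raw piecewise-
constant phantom carries ~35% of its in-support energy beyond the radial
Nyquist ball at 64³, which would put an irreducible Gibbs floor (~0.29
NRMSE) under every image comparison and mask the quantities actually under
test. Coil sensitivities are smooth complex Gaussian profiles centered on
a ring of channel positions, normalized to unit root-sum-of-squares.

Inversion preparation affects contrast, not geometry; it enters only as
segment timing (TI delay), since the correction method is contrast-agnostic.

**Motion paradigms** (piecewise-constant per segment, changes only at
segment boundaries, first 3 segments always at the reference pose):
`static` (identity), `step_rotation` (4 abrupt axial-rotation levels drawn
uniformly and rescaled so the largest is exactly the requested amplitude,
default 20°; pure rotation), `nodding` (3 short transient sagittal
excursions with small y-translations), `continuous` (smooth oscillation
confined to the middle third, with a small x-translation component). Four
position changes over a 39-segment desk-scale scan mirrors an instructed
"move and hold" paradigm. Noise is complex Gaussian at 1% of the peak
signal magnitude, seeded.

## Reconstruction

The gridding NUFFT uses a Kaiser–Bessel kernel (Beatty shape parameter) on
an oversampled FFT grid, with the kernel's analytic transform divided out
of the image. The interpolator is a precomputed sparse CSR matrix, so the
adjoint is the exact conjugate transpose (dot-product test ~1e-11) and
multi-channel batches amortize the FFTs. Accuracy is a speed dial: width 4
at oversampling 1.25 (~1e-2 max relative error, used inside iterative
recon where the error is far below the noise and streaking floor) up to
width 8 at oversampling 2 (~1e-7, used by the simulator and the oracle
tests). Sliding-window operators are assembled by stacking per-segment
interpolator blocks rather than rebuilding them.

cgSENSE solves (AᴴWA + λI)x = AᴴWy by plain conjugate gradients; A is the
per-channel map-weighted NUFFT restricted to valid samples, W the Pipe
density weights. Gap samples are absent from the data term, never
zero-filled, so the regularized solution extrapolates the center. λ
defaults to 1e-2 × a 10-step power-iteration estimate of the largest
eigenvalue of AᴴWA, making regularization invariant to data scale and
sample count; within one pipeline the calibration (weights and λ) is
computed once per geometry class — first navigator window, and the
uncorrected full set, whose values the corrected reconstruction reuses so
the two images are directly comparable. The CG diagnostics record residual
norms and the quadratic objective; the objective decreases monotonically
(guaranteed), the residual norm in practice as well (asserted with
tolerance). Working precision is complex64 in the pipeline (memory/speed),
complex128 in oracle-grade tests.

Pipe density compensation iterates w ← w/(w ⊛ psf) with the convolution
normalized so an isolated sample has weight exactly 1 (hence a duplicated
sample converges to ½). Density estimation prefers a wider kernel than
gridding: with width 6 at oversampling 2 the fully-sampled radial weights
follow the analytic r² law to within 10% mean deviation; the narrow
reconstruction kernel yields noisier weights that are still adequate as a
data-term weighting, and both are available through the `operator`
argument. Default 40 iterations with an early stop at 1e-3 maximum
relative update (a warning, not an error, on non-convergence).

Sensitivity maps: WASPI-only gridding per channel with a Hann apodization
over the WASPI k-radius (suppresses low-resolution ringing), divided by the
root-sum-of-squares. RSS of the estimate is 1 by construction. Accuracy
against the simulator's true maps is band-limited by the WASPI k-extent
(waspi_scale · MAT/2 cycles/FOV): at the desk-scale readout lengths used in
the tests, truncation of genuine map variation dominates the error (mean
absolute error ~0.16 at 32-cube with 2-cycle WASPI radius), while the
downstream registration and reconstruction quality remain unaffected.

## Motion estimation and correction

Navigators (3 mm default) are registered to the first navigator with
SimpleITK: Mattes mutual information (32 bins, 25% regular sampling with a
fixed seed), two-level multi-resolution (shrink 2/1, smoothing 1/0),
regular-step gradient descent with physical-shift scaling, 150 iterations,
minimum step 1e-5. Each registration is initialized from the previous
window's estimate, which keeps the optimizer near the solution through
large cumulative rotations. The mask is Otsu threshold → largest connected
component → fill holes → two 3³ dilations, covering the object boundary
while excluding distant static structures (headrest stand-in test). The
registration returns the head pose directly in the package's convention —
pinned by a round-trip test against the simulator, not by documentation.

Each window's pose is assigned to its middle segment (the earlier of the
two central segments for even window lengths); segments before the first
middle keep the identity (the not-corrected start of the scan: reference
region and WASPI), segments after the last middle inherit the final
estimate. The k-space correction rotates each segment's coordinates by Rᵀ
and applies the unit phase ramp at the acquired coordinates; rotated
samples leaving the nominal Nyquist ball are kept (they carry valid
high-frequency information and the oversampled grid represents them).

**Known limitation — pose transitions.** A sliding window that straddles a
pose step reconstructs a navigator containing both poses, and registration
(any metric: MI, correlation, mean squares — all were measured) returns a
~25% blend of the two rather than snapping to the majority pose. The two
middle segments adjacent to each step therefore inherit errors of roughly a
quarter of the step size. With 20° instructed steps this puts the
whole-trace rotation RMS error near 1.1°, while the steady-state segments
(window entirely at one pose — 31 of 39 segments in the shipped scenario)
recover rotation to ≈ 0.15° RMS and translation to ≈ 0.03 mm, matching the
navigator-to-navigator precision scale reported for static in-vivo scans.
An iterative re-correction pass was prototyped and does not contract this
transition error (the error mode is oscillatory across adjacent segments,
which a window-average re-estimate cannot reduce); the pipeline is the
published single-pass estimator. Consequences for images are mild — the
final reconstruction still improves markedly (see the acceptance tests) —
but trace consumers should treat transition-adjacent estimates as
window-averaged positions, which is what they are by construction.

Trace analysis: detrending subtracts a 51-segment uniform moving average
(reflect padding) per parameter; stability statistics are mean ± SD of the
translation- and rotation-vector magnitudes; the amplitude spectrum is
|FFT|/√n per detrended parameter (Parseval-consistent), annotated with the
golden-angle frequency 1/(N_seg·segment duration) — the rate at which the
sampling pattern rotates by φ_G, where residual streaking induces a
spurious oscillation in static traces.

## Validation scope

The scenario fixtures (64³ over 192 mm, 13 interleaves × 1152 spokes, 3
segments of 384, s = 7, 8 channels, gap 2, 512 WASPI spokes, 1% noise) are
desk-scale: ~3.5× angular undersampling at full resolution, a smooth
phantom, ideal rigid motion synchronized to segment boundaries, no
relaxation/contrast evolution, no off-resonance, no gradient imperfections,
and coil maps that remain valid at all poses. Passing tests therefore
demonstrate the *self-consistency and accuracy of the estimator and
corrector under the stated model* — exact k-space motion model, known
ground truth — not performance on in-vivo data, where navigator contrast,
non-rigid anatomy, pose-dependent sensitivities and within-navigator motion
add effects this simulator deliberately excludes. Image-quality claims are
directional (corrected ≥ uncorrected against an independent static
reference, with masked mSSIM and average edge strength), never absolute
values from any external study.

AES is implemented as the mean Sobel gradient magnitude over edge voxels
found by hysteresis thresholding at 0.1/0.2 of the in-mask gradient range,
after normalizing the image by its mean in-mask intensity (making the score
scale-invariant); the exact normalization of the originally cited edge
metric is not publicly specified, so all AES uses here are directional or
regression-bound. mSSIM uses a 3D Gaussian window (σ = 1.5, 11 voxels),
K1 = 0.01, K2 = 0.03, dynamic range from the reference's 99.9th percentile.

## Degenerate inputs and tie-breaks

Flat or empty images are rejected with dedicated errors in masking and
metrics; all-zero WASPI data is a degenerate input; spherical Voronoi
requires ≥ 4 non-coplanar directions; detrending requires an odd window no
longer than the trace; spectra require ≥ 8 uniformly timed segments.
Azimuth at the poles is undefined and never compared. Identity transforms
short-circuit the k-space correction so an identity trace is a bitwise
no-op.
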