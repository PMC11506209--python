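# Methods

`thermalfree` implements a verifiable BOLD fMRI analysis chain —
patch-SVD thermal-noise denoising, the standard preprocessing stages
around it, quality control, block-design GLM activation mapping,
global-signal cerebrovascular-reactivity (rCVR) mapping, and population
receptive field (pRF) grid modeling — driven entirely by seeded
synthetic 4D phantoms with known ground truth. This note records the
models, the parameter choices that matter, and the limits of what the
phantoms can show.

## Denoising model

Both denoisers operate on local Casorati matrices: for a cubic patch of
`m` voxels and a scan of `n` time points, the patch is unfolded into an
`m x n` matrix (rows = voxels, columns = time) and its singular value
decomposition computed.

**NORDIC-style hard thresholding.** Thermal noise in magnitude MRI is
approximately Gaussian at high SNR but spatially varying (coil
geometry, acceleration). The volume is first *noise-flattened*: every
voxel timeseries is divided by a smooth per-voxel noise-SD map, making
the noise spatially identical with unit variance. Each patch is then
hard-thresholded at

    tau = scale * (sqrt(m) + sqrt(n)),

the asymptotic largest singular value of an `m x n` unit-variance
Gaussian matrix. Components below `tau` are indistinguishable from
pure noise and are zeroed; the patch is reconstructed, overlapping
reconstructions are averaged, and the flattening inverted.

* `scale` defaults to 1 (the threshold is exactly the expected
  noise-only edge) and is exposed because the proportionality constant
  is a free choice; a Monte-Carlo estimator of the expected largest
  singular value (mean over seeded draws) is provided for validation
  and agrees with the analytic edge to within ~2-3% at patch sizes of
  practical interest.
* The cubic patch edge defaults to the 11:1 spatial-to-temporal voxel
  rule, `edge = round((11 n)^(1/3))`: 14 at 250 time points, 19 at
  590, 18 at 512, 14 at 240. Nearest-integer rounding is the unique
  rule consistent with all four of those edges.
* Patch lattice: half-kernel shifts, with the final start on each axis
  clamped to `extent - kernel` so every voxel is covered without
  padding the data; overlap averaging weights each voxel by the number
  of covering patches. Clamping was preferred over reflective padding
  because it never synthesizes data at the boundary and leaves the
  single-patch case exactly equal to a plain SVD threshold (which the
  tests exploit as an oracle).

**MPPCA.** The Marchenko-Pastur baseline needs no prior noise map: per
patch, the time-demeaned eigen-spectrum is scanned from the largest
eigenvalue down, and the smallest signal count `p` is selected for
which the remaining spectrum fits under the MP right edge with the
noise variance estimated from those same eigenvalues. The edge carries
a Tracy-Widom finite-size allowance (upper-quantile scale factor 2.0 on
the fluctuation scale `(sqrt(m)+sqrt(n)) (m^-1/2 + n^-1/2)^(1/3)`);
without it the largest pure-noise eigenvalue crosses the asymptotic
edge in a substantial fraction of patches and pure-noise patches would
spuriously retain components.

**Noise-map estimation.** The per-voxel noise SD is estimated from the
data itself (no separate noise scan exists for magnitude-only data):
MPPCA-style sigma estimates on half-overlapping 5-voxel patches are
averaged per voxel and smoothed with a Gaussian of 1.5 voxels. This
assumes the true noise field is smooth at the patch scale, which is the
defining property of a g-factor map; rapidly varying noise fields are
under-resolved.

## Standard preprocessing

Stage order: dummy removal (first 10 volumes) -> optional denoising ->
3D Gaussian smoothing (FWHM 2 voxels, reflect boundary) -> global
linear detrend -> brick-wall band-pass (0.001-0.25 Hz for block-design,
0.001-0.1 Hz for resting-state).

* The detrend fits one line to the whole-brain mean timeseries and
  subtracts only the zero-mean trend component `slope*(t - t_mean)`
  from every voxel: voxel means survive (rCVR's SI needs them) and
  voxel-private slopes are deliberately not removed.
* The band-pass is an ideal frequency-domain filter: printed corner
  frequencies are honored exactly and the filter is idempotent, at the
  cost of roll-off realism. DC is removed whenever the low cut is
  positive, so the rCVR stage takes its tissue-intensity normalizer SI
  from the pre-filter volume.
* Slice-timing adjustment is a documented no-op: the phantom has no
  slice-time structure, and the stage exists only for interface parity.

## Quality control

tSNR is voxelwise temporal mean over temporal sample SD (N-1); zero-SD
voxels are flagged undefined, never zeroed. The tSNR comparison branch
evaluates maps right after dummy removal (+ denoising), before
smoothing and filtering, so the reported gain reflects the denoiser
rather than the smoothing kernel. PSC is the on/off window contrast in
percent with the on-window delayed by a configurable hemodynamic shift
(default 4 s). Spectra are single-taper periodograms of the
mean-removed series, normalized to unit total power over positive
frequencies: the periodogram keeps single-bin resolution below 0.01 Hz,
which a Welch estimator would smear. Band comparison runs paired
t-tests per frequency bin (Bonferroni across bins) and, as the actual
band decision, a paired t-test on band-summed relative power
(Bonferroni across the two bands): per-bin periodogram power has a
coefficient of variation near 1, so bin-wise significance across a few
hundred bins is unreachable at realistic subject counts while the
band-integrated comparison is well powered.

## GLM

The task regressor is the stimulation boxcar convolved with a
double-gamma HRF, difference of two gamma densities with shape =
delay/dispersion and scale = dispersion, undershoot divided by its
ratio, sampled at `t = 0, tr, ..., kernel_length - tr` and
peak-normalized to 1 so betas carry PSC units. The rodent defaults
(response delay 3.7 s, undershoot delay 4.45 s, dispersions 0.5 s,
ratio 1.5, kernel 32 s) give a combined peak near 2.7 s — earlier than
the 3.2 s mode of the response gamma alone, because the undershoot
subtraction pulls the peak forward.

Fitting is voxelwise OLS with `t = beta/SE`, residual df = N - rank(X),
two-sided p. No autocorrelation prewhitening is applied: phantom noise
is temporally white, and AR modeling of real physiological noise is out
of scope. "p < 0.001, FDR corrected" is ambiguous between
Benjamini-Hochberg at level q = 0.001 and an FDR-adjusted p map
thresholded at 0.001; both modes are exposed (they produce the same
rejection set for BH, and the ambiguity is therefore harmless here).

## rCVR

Each voxel timeseries is normalized to zero mean and L2 norm
`sqrt(N)/2` (the printed form of the normalization denominator is
typographically garbled in the source material; the implementation
adopts the reading consistent with the stated norm). The global signal
is the whole-brain mean timeseries, normalized identically, so the
regression slope alpha is dimensionless and — both sides having equal
norm — numerically a correlation. rCVR = alpha / SI with SI the
whole-brain mean intensity; the intercept beta is stored but unused.
Because alpha saturates toward 1 as the shared fluctuation dominates
the residual noise, rCVR is insensitive to denoising precisely when
physiological fluctuations are strong relative to in-band thermal noise
— which is the regime the band-passed resting-state data occupy, and
why the pipeline reproduces the observed denoising-invariance of rCVR
while still showing reduced across-voxel variance.

Depth profiles are mean +- SE of rCVR per depth bin (default 10
equal-thickness bins, pial to white, phantom-supplied labels standing
in for an atlas depth definition).

## pRF

Isotropic 2D Gaussian receptive fields (center x, y; size sigma;
degrees of visual angle). Per stimulus frame, the model response is the
aperture-weighted integral of the Gaussian divided by the Gaussian's
full integral (full-field aperture -> overlap 1); the overlap series is
convolved with an HRF and each grid model regressed against the voxel
by OLS with intercept. The winner-take-all rule keeps the model with
the highest R^2 among positive-slope fits; ties break to the smallest
grid linear index, making fits fully deterministic. The default grid is
30 x 30 centers over a 26-degree field and 30 sizes over 0.20-7.00
degrees (27,000 models); display thresholding uses R = sqrt(R^2) > 0.2.

Ring/wedge apertures default to a 101 x 101 pixel grid (41 in the test
suite), 45-degree wedge width, ring thickness 1/8 of the maximum
eccentricity — typical paradigm geometry, since aperture geometry is
not otherwise constrained. Stimulus frames are generated at the TR
(2 s), so no temporal resampling occurs.

Cluster-extent thresholding draws `n_iter` (default 1000) Gaussian null
fields, smooths them to the requested FWHM, re-standardizes, thresholds,
and labels clusters with 6-neighbor connectivity; the minimum cluster
size is the 95th percentile of the null maximum-cluster-size
distribution. For non-z statistic maps (the pRF R map) the caller
supplies the voxelwise null tail probability of the threshold — a helper
computes it for the null correlation distribution — and the Gaussian
null is cut at the matching quantile. The same connectivity and
threshold rule are used for map and null, so the correction is
internally consistent even though the reference implementation's
conventions are proprietary.

## Phantom design

The generator emulates the statistical structure the analyses assume:

    S(v,t) = B * [1 + (a/100) r(t) 1_ROI(v) + f g(v) G(t) + d (t - t_mean)]
    data   = S + sigma gf(v) * noise   (or two-channel Rician magnitude)

* `B` baseline intensity (100 arbitrary units), `a` activation PSC in
  percent, `r(t)` the HRF-convolved boxcar *calibrated so that the
  delayed on/off window contrast of the noiseless signal is exactly
  `a` percent* (the raw convolution plateau depends on the kernel sum;
  calibration makes ground-truth PSC exact by construction).
* `G(t)` a unit-SD band-limited Gaussian fluctuation shared across the
  brain (default band 0.005-0.08 Hz, spanning infra-slow and
  low-frequency oscillation ranges), with amplitude `f` as a fraction
  of baseline and per-voxel vascular gain `g(v)` composed of a linear
  depth profile and optional regional factors (the pharmacological
  pre/post analogue). The vascular gains multiply the *fluctuation
  term only*: the rCVR normalization is scale-invariant, so a gain on
  the whole signal would be invisible to alpha; gains on the
  fluctuation are exactly what a cerebrovascular-reactivity index
  measures.
* Thermal noise is white in time with SD `sigma * gf(v)` for a smooth
  g-factor-like map `gf`; Rician mode forms the magnitude of a complex
  Gaussian perturbation and agrees with the Gaussian model to <0.5% in
  voxel mean at baseline/sigma >= 20.
* Fixed seed gives bitwise-identical output.

Default study conditions, chosen once as physiologically typical and
not revisited: rodent block-design phantoms use sigma = 5 at baseline
100 (raw tSNR ~ 20, cryoprobe-free surface-coil regime) with 2% evoked
PSC; resting-state phantoms use sigma = 3 (tSNR ~ 33) with a 4%-SD
shared fluctuation, putting the band-passed fluctuation-to-noise ratio
near 3 so that rCVR sits in its saturated, denoising-insensitive
regime; drift defaults to zero in fixtures and 2e-5 of baseline per
volume where drift is wanted. The retinotopic sheet phantom maps voxel
indices smoothly onto a +-1.5-degree window of the visual field
(neighboring voxels have nearly identical receptive fields, as on a
real cortical patch, keeping the patch-local signal low-rank), with 5%
response amplitude and tSNR ~ 70 — the regime of 3T visual cortex. Its
HRF uses the canonical human double-gamma (delays 6/16 s, dispersions
1 s, ratio 6).

**What the phantoms do not emulate** — and hence what passing tests do
not show about real data: no k-space/EPI sampling, partial Fourier or
coil combination; no motion, slice-time structure, or registration
error; no spatially structured (non-smooth) noise; no temporally
autocorrelated physiological noise beyond the single shared band-limited
fluctuation; no neurovascular nonlinearity. Direction-preserving
properties (tSNR gain, activation-extent and cluster-size dominance,
rCVR invariance) are claims about this generative model, not about any
particular scanner.

## Numerical choices and scale of the shipped checks

Test problem sizes are chosen so the full suite runs in about a minute
on one core: the headline paired-arm phantom is 32 x 32 x 16 x 260,
replicate-based direction properties use 10 replicates of reduced
phantoms (24 x 24 x 12 x 130 block-design; 16 x 16 x 10 x 130
resting-state), the pRF suite uses a 10 x 10 x 10 grid with a 41-pixel
aperture raster and, where winner stability matters, the full 512-frame
paradigm. Replicate thresholds ("in >= 90% of replicates") follow the
direction-preservation criteria at these reduced counts.

Degenerate inputs are errors, not silent results: constant timeseries
(tSNR, normalization, pRF fits), empty masks and ROIs, kernels larger
than the padded volume, bands beyond Nyquist, non-divisible block
durations. Winner ties in the pRF grid, duplicate thresholds in
sweeps, and zero-variance voxels all have defined, tested behavior.

## Known limitations

* Hard-threshold denoising removes any signal component whose patch
  singular value falls below the noise edge `sigma (sqrt(m)+sqrt(n))`.
  A 2% evoked response at tSNR 20 crosses that edge only when it is
  spatially coherent over roughly a thousand voxels of a default-size
  patch; small, weak activations are attenuated. The shipped phantom
  defaults use activated regions of realistic extent, which is exactly
  the regime where evoked amplitude is preserved.
* Hard-threshold patch denoising biases voxel-unique signal toward the
  patch's dominant components. On signals whose spatial variation is
  fast at the patch scale (e.g. a retinotopic map jumping a full grid
  step between neighboring voxels) this measurably perturbs
  winner-take-all pRF parameters; the effect shrinks as the local
  signal manifold becomes low-rank, which is the realistic regime.
* The MP right-edge component test uses a fixed Tracy-Widom allowance
  rather than the exact finite-size distribution; extremely weak signal
  components near the edge are absorbed into noise by design.
* The noise-map estimator assumes smooth noise fields; the brick-wall
  filter rings for inputs with strong spectral content exactly at a
  corner frequency; the cluster-extent null assumes stationary Gaussian
  smoothness.
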