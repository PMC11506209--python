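# thermalfree

Thermal noise is the dominant noise source in high-resolution fMRI:
it is spatially varying but temporally white, which makes it separable
from hemodynamic signal by low-rank matrix methods. `thermalfree` is a
Python package for patch-based SVD denoising of 4D magnitude BOLD data
and for the analysis chain that evaluates what denoising does to
downstream physiology — temporal SNR, evoked activation, resting-state
spectra, cerebrovascular reactivity, and retinotopic population
receptive field maps. Every stage runs on seeded synthetic phantoms
with known ground truth, so the whole chain is testable without animal
or human data. It is written for fMRI methods researchers who want a
transparent, verifiable reference implementation rather than a black
box.

## The core algorithms

**NORDIC-style denoising.** For each cubic patch of `m` voxels over
`n` time points, form the Casorati matrix `Y (m x n)` of the
noise-flattened data (each voxel divided by its local noise SD) and
hard-threshold its singular values at

&tau; = &sigma;(&radic;m + &radic;n),

the largest singular value expected from an `m x n` pure-Gaussian
matrix with noise level &sigma; (= 1 after flattening). Components
below &tau; cannot be distinguished from thermal noise and are
removed; overlapping patch reconstructions at half-kernel shifts are
averaged and the flattening inverted. The patch edge follows the 11:1
spatial-to-temporal voxel rule, `edge = round((11 T)^(1/3))` — 14 for a
250-volume scan, 19 for 590, 18 for 512, 14 for 240.

**MPPCA baseline.** Per patch, the eigen-spectrum of the demeaned
Casorati matrix is compared against the Marchenko–Pastur bulk; only
components beyond the right edge (with a Tracy–Widom finite-size
allowance) are kept.

**Downstream measures.**
tSNR = voxelwise mean / SD; percent signal change from delayed on/off
block windows; GLM activation maps with a rodent double-gamma HRF
(response delay 3.7 s, undershoot delay 4.45 s) and Benjamini–Hochberg
FDR; relative cerebrovascular reactivity
rCVR = &alpha;/SI, where &alpha; is the slope of the normalized voxel
timeseries (zero mean, norm &radic;N/2) regressed on the equally
normalized global signal and SI is whole-brain mean intensity; pRF
mapping by winner-take-all grid search (30×30 centers × 30 sizes,
0.20–7.00°, 26° field) of Gaussian receptive-field predictions against
ring/wedge aperture movies, thresholded at R > 0.2 with Monte-Carlo
cluster-extent correction (1000 null fields, &alpha; = 0.05).

## Worked example

Run the paired-pipeline comparison on a seeded block-design phantom
(24×24×12 voxels, 130 volumes, 2% evoked signal change, raw tSNR ≈ 20):

```bash
$ thermalfree run --mode ofmri --seed 7 --outdir run7
      metric             arm       value
   tsnr_mean        standard   20.100944
 n_activated        standard  528.000000
psc_roi_mean        standard    1.534056
   tsnr_mean          nordic  425.470385
 n_activated          nordic 5220.000000
psc_roi_mean          nordic    1.064354
  tsnr_ratio nordic/standard   21.166687
report: run7/report.tsv
```

Reading the numbers: the standard arm's mean tSNR of 20.1 matches the
phantom's designed baseline/noise ratio (100/5); denoising raises it to
425 because this phantom contains only thermal noise, which the SVD
threshold removes almost entirely (on resting-state phantoms with
physiological fluctuations, `--mode rsfmri`, the gain saturates at the
fluctuation ceiling instead). The activated-voxel count at FDR
q = 0.001 grows from 528 to 5220 as suppressed noise uncovers the full
stimulated region, while the ROI-mean evoked amplitude stays on the
order of the designed 2% (1.5% vs 1.1% here — smoothing and patch
truncation both dilute the block plateau) rather than being inflated by
the denoiser.

The same stages are available individually (`thermalfree simulate`,
`denoise`, `preprocess`, `qc`, `rcvr`) and as library functions:

```python
import thermalfree as tf

vol, truth = tf.simulate_fmri(tf.PhantomSpec(seed=1, psc_amplitude=2.0,
                                             design=tf.BlockDesign(),
                                             activation_roi=(slice(10, 22),
                                                             slice(10, 22),
                                                             slice(4, 12))))
noise = tf.estimate_noise(vol)                 # Marchenko-Pastur sigma map
res = tf.nordic_denoise(vol, tf.PatchConfig(kernel="auto"), noise)
```

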