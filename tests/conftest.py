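"""Shared phantom fixtures.

Heavy paired-arm (standard vs NORDIC) results are session-scoped so
several tests can assert different properties of one computation.
"""
from __future__ import annotations

import numpy as np
import pytest

import thermalfree as tf
from thermalfree.preprocess import bandpass, detrend_global, drop_dummies, smooth_gaussian


OFMRI_ROI = (slice(12, 20), slice(12, 20), slice(6, 10))


def ofmri_spec(seed: int = 0, shape=(32, 32, 16, 260)) -> tf.PhantomSpec:
    """Block-design phantom: tSNR ~ 20 (baseline 100, sigma 5), 2% PSC.

    The activation ROI spans ~3/8 of each axis so the evoked component
    is spatially coherent over enough voxels per patch to sit clearly
    above the noise singular-value edge, as a real activated region is.
    """
    nx, ny, nz, _ = shape
    roi = (slice(nx * 5 // 16, nx * 11 // 16), slice(ny * 5 // 16, ny * 11 // 16),
           slice(nz // 4, nz * 3 // 4))
    return tf.PhantomSpec(shape=shape, noise_sigma=5.0, psc_amplitude=2.0,
                          design=tf.BlockDesign(), activation_roi=roi, seed=seed)


def small_ofmri_spec(seed: int = 0) -> tf.PhantomSpec:
    """Reduced block-design phantom (2 blocks, 130 volumes) for replicate loops."""
    return tf.PhantomSpec(shape=(24, 24, 12, 130), noise_sigma=5.0, psc_amplitude=2.0,
                          design=tf.BlockDesign(baseline=20, n_blocks=2, on=20, off=35),
                          activation_roi=(slice(7, 17), slice(7, 17), slice(3, 9)),
                          seed=seed)


def rs_spec(seed: int = 0, **kw) -> tf.PhantomSpec:
    """Resting-state phantom: shared low-frequency fluctuation plus noise."""
    defaults = dict(shape=(24, 24, 12, 130), noise_sigma=3.0, fluct_amp=0.04, seed=seed)
    defaults.update(kw)
    return tf.PhantomSpec(**defaults)


def run_arms(vol: tf.Volume4D, n_dummies: int = 10, band=(0.001, 0.25),
             fwhm: float = 2.0, kernel="auto"):
    """Standard and NORDIC arms of the canonical chain; returns per-arm
    dict with the post-denoise (tSNR-branch) and fully filtered volumes."""
    out = {}
    for arm in ("standard", "nordic"):
        v = drop_dummies(vol, n_dummies)
        pre = v
        if arm == "nordic":
            noise = tf.estimate_noise(v)
            v = tf.nordic_denoise(v, tf.PatchConfig(kernel=kernel), noise).volume
        tsnr_branch = v
        v = smooth_gaussian(v, fwhm)
        v = detrend_global(v)
        filt = bandpass(v, *band) if band else v
        out[arm] = {"tsnr_branch": tsnr_branch, "detrended": v,
                    "filtered": filt, "prefilter": pre}
    return out


@pytest.fixture(scope="session")
def ofmri_run():
    """One full-size block-design phantom run through both arms."""
    spec = ofmri_spec(seed=101)
    vol, truth = tf.simulate_fmri(spec)
    arms = run_arms(vol)
    return {"spec": spec, "vol": vol, "truth": truth, "arms": arms}


@pytest.fixture(scope="session")
def rs_run():
    """One resting-state phantom run through both arms (rsfMRI band)."""
    spec = rs_spec(seed=202)
    vol, truth = tf.simulate_fmri(spec)
    arms = run_arms(vol, band=(0.001, 0.1))
    return {"spec": spec, "vol": vol, "truth": truth, "arms": arms}
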