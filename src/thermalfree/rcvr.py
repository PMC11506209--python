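"""Relative cerebrovascular reactivity (rCVR) mapping from task-free BOLD.

Each voxel's normalized timeseries (zero mean, norm sqrt(N)/2) is
regressed on the equally normalized whole-brain global signal; the
slope alpha, divided by the whole-brain mean signal intensity SI, is
the rCVR index. The residual/intercept term beta is stored but never
used downstream.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Volume4D, Timeseries, _check_mask


@dataclass
class NormalizedTimeseries:
    """Zero-mean timeseries rescaled to L2 norm sqrt(N)/2."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class RCVRFit:
    alpha: np.ndarray         # GS regression slope, dimensionless
    beta: np.ndarray          # intercept; retained for completeness, unused
    si: float                 # whole-brain mean intensity (image units)
    rcvr: np.ndarray          # alpha / si
    defined: np.ndarray       # False where the voxel timeseries was constant
    mask: np.ndarray


@dataclass
class DepthProfile:
    depth_bins: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_voxels: np.ndarray


def normalize_bold(s: Timeseries | np.ndarray) -> NormalizedTimeseries:
    """DeltaBOLD/BOLD normalization: subtract the mean, rescale so the
    L2 norm is exactly sqrt(N)/2 (hence scale-invariant)."""
    values = s.values if isinstance(s, Timeseries) else np.asarray(s, dtype=float).ravel()
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    centered = values - values.mean()
    norm = np.linalg.norm(centered)
    if norm == 0:
        raise ValueError("constant timeseries cannot be normalized")
    return NormalizedTimeseries(values=centered * (np.sqrt(n) / (2.0 * norm)))


def global_signal(vol: Volume4D, mask: np.ndarray | None = None) -> NormalizedTimeseries:
    """Whole-brain mean timeseries, normalized like every voxel."""
    return normalize_bold(vol.mean_timeseries(mask))


def compute_rcvr(vol: Volume4D, mask: np.ndarray | None = None,
                 si_source: Volume4D | None = None) -> RCVRFit:
    """Fit alpha per voxel by OLS of the normalized voxel timeseries on
    the normalized global signal (with intercept); rCVR = alpha / SI.

    ``si_source`` supplies the volume whose mask-mean defines SI when
    the analysis volume has been band-passed to zero mean (SI must be a
    tissue intensity, not a filtered residual); defaults to ``vol``.
    Constant voxels are flagged undefined rather than fitted.
    """
    nt = vol.n_timepoints
    if nt < 3:
        raise ValueError("need at least 3 time points")
    mask = _check_mask(mask, vol.spatial_shape) if mask is not None else np.ones(vol.spatial_shape, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    gs = global_signal(vol, mask).values

    Y = vol.data[mask]                              # voxels x time
    centered = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    defined_flat = norms > 0
    Yn = np.zeros_like(centered)
    Yn[defined_flat] = centered[defined_flat] * (np.sqrt(nt) / (2.0 * norms[defined_flat, None]))

    # gs has zero mean, so with an intercept the slope is <y, gs>/<gs, gs>
    denom = float(gs @ gs)
    alpha_flat = (Yn @ gs) / denom
    beta_flat = Yn.mean(axis=1)                     # intercept of the fit
    alpha_flat[~defined_flat] = np.nan

    si_vol = si_source if si_source is not None else vol
    si = float(si_vol.data[mask].mean())
    if si <= 0:
        raise ValueError("SI must be positive; pass si_source with tissue intensities")

    def to_map(flat):
        out = np.full(vol.spatial_shape, np.nan)
        out[mask] = flat
        return out

    defined = np.zeros(vol.spatial_shape, bool)
    defined[mask] = defined_flat
    alpha = to_map(alpha_flat)
    return RCVRFit(alpha=alpha, beta=to_map(beta_flat), si=si,
                   rcvr=alpha / si, defined=defined, mask=mask)


def depth_profile(fit: RCVRFit, depth_labels: np.ndarray,
                  n_bins: int | None = None) -> DepthProfile:
    """Mean and SE of rCVR per cortical-depth bin (labels 1..n, pial to white)."""
    depth_labels = np.asarray(depth_labels)
    if depth_labels.shape != fit.rcvr.shape:
        raise ValueError("depth label shape mismatch")
    ids = (np.arange(1, n_bins + 1) if n_bins is not None
           else sorted(int(i) for i in np.unique(depth_labels) if i != 0))
    means, ses, counts = [], [], []
    for rid in ids:
        sel = (depth_labels == rid) & fit.defined
        vals = fit.rcvr[sel]
        if vals.size == 0:
            raise ValueError(f"depth bin {rid} is empty")
        means.append(float(vals.mean()))
        ses.append(float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0)
        counts.append(int(vals.size))
    return DepthProfile(depth_bins=np.asarray(ids), mean=np.asarray(means),
                        se=np.asarray(ses), n_voxels=np.asarray(counts))


def profile_slope(profile: DepthProfile) -> float:
    """Least-squares slope of mean rCVR against depth-bin index."""
    x = profile.depth_bins.astype(float)
    xc = x - x.mean()
    return float(xc @ (profile.mean - profile.mean.mean()) / (xc @ xc))


def compare_rcvr(pre: RCVRFit | list[RCVRFit], post: RCVRFit | list[RCVRFit],
                 labels: np.ndarray, roi_ids: list[int] | None = None) -> pd.DataFrame:
    """Per-ROI mean rCVR change (post - pre); across-subject SE when lists
    of fits are supplied."""
    pres = pre if isinstance(pre, list) else [pre]
    posts = post if isinstance(post, list) else [post]
    if len(pres) != len(posts):
        raise ValueError("pre and post subject counts differ")
    labels = np.asarray(labels)
    for f in pres + posts:
        if f.rcvr.shape != labels.shape:
            raise ValueError("geometry mismatch between fits and labels")
    ids = roi_ids if roi_ids is not None else sorted(int(i) for i in np.unique(labels) if i != 0)
    rows = []
    for rid in ids:
        roi = labels == rid
        diffs = []
        for fp, fq in zip(pres, posts):
            sel = roi & fp.defined & fq.defined
            if not sel.any():
                continue
            diffs.append(float(fq.rcvr[sel].mean() - fp.rcvr[sel].mean()))
        diffs = np.asarray(diffs)
        rows.append({
            "roi": rid,
            "n_subjects": diffs.size,
            "mean_pre": float(np.mean([fp.rcvr[roi & fp.defined].mean() for fp in pres])),
            "mean_post": float(np.mean([fq.rcvr[roi & fq.defined].mean() for fq in posts])),
            "mean_diff": float(diffs.mean()) if diffs.size else np.nan,
            "se_diff": float(diffs.std(ddof=1) / np.sqrt(diffs.size)) if diffs.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)
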