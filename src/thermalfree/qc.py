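"""Quality-control metrics: temporal SNR, percent signal change, ROI
summaries, and relative power spectra with band-wise group comparison."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Volume4D, Timeseries, _check_mask
from .phantom import psc_windows


@dataclass
class TSNRMap:
    """Voxelwise temporal mean / temporal SD; zero-SD voxels are flagged
    undefined (NaN in ``values``, False in ``defined``), never zeroed."""

    values: np.ndarray
    defined: np.ndarray
    mask: np.ndarray


@dataclass
class PowerSpectrum:
    """Relative power over positive frequencies (sums to 1)."""

    frequencies: np.ndarray
    relative_power: np.ndarray


def tsnr_map(vol: Volume4D, mask: np.ndarray | None = None) -> TSNRMap:
    """Temporal SNR: voxelwise mean divided by voxelwise sample SD (N-1)."""
    if vol.n_timepoints < 2:
        raise ValueError("need at least 2 time points for tSNR")
    mask = _check_mask(mask, vol.spatial_shape) if mask is not None else np.ones(vol.spatial_shape, bool)
    mean = vol.data.mean(axis=-1)
    sd = vol.data.std(axis=-1, ddof=1)
    defined = (sd > 0) & mask
    values = np.full(vol.spatial_shape, np.nan)
    values[defined] = mean[defined] / sd[defined]
    return TSNRMap(values=values, defined=defined, mask=mask)


def psc_map(vol: Volume4D, boxcar: np.ndarray, shift: float = 4.0) -> np.ndarray:
    """Percent signal change map from an on/off block design.

    ``100 * (mean_on - mean_off) / mean_off`` per voxel, with the on/off
    windows delayed by ``shift`` seconds to account for the hemodynamic
    rise (configurable; 0 disables the delay).
    """
    boxcar = np.asarray(boxcar).ravel()
    if boxcar.size != vol.n_timepoints:
        raise ValueError("design length does not match time points")
    if not ((boxcar > 0.5).any() and (boxcar <= 0.5).any()):
        raise ValueError("design must contain both on and off samples")
    on, off = psc_windows(boxcar, int(round(shift / vol.tr)))
    if not on.any() or not off.any():
        raise ValueError("shifted design lost its on or off samples")
    mean_on = vol.data[..., on].mean(axis=-1)
    mean_off = vol.data[..., off].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 100.0 * (mean_on - mean_off) / mean_off


def roi_summary(data: Volume4D | np.ndarray, labels: np.ndarray,
                roi_ids: list[int] | None = None) -> pd.DataFrame:
    """Per-ROI table: across-voxel mean and SD, plus (for 4D input) the
    temporal SD of the ROI-mean timeseries. Empty ROIs yield NaN rows."""
    import warnings

    is_vol = isinstance(data, Volume4D)
    spatial = data.spatial_shape if is_vol else data.shape
    labels = np.asarray(labels)
    if labels.shape != tuple(spatial):
        raise ValueError("label volume shape mismatch")
    ids = roi_ids if roi_ids is not None else sorted(int(i) for i in np.unique(labels) if i != 0)
    rows = []
    for rid in ids:
        roi = labels == rid
        if not roi.any():
            warnings.warn(f"ROI {rid} is empty", stacklevel=2)
            rows.append({"roi": rid, "n_voxels": 0, "mean": np.nan, "sd": np.nan,
                         "timeseries_sd": np.nan})
            continue
        if is_vol:
            voxel_means = data.data[roi].mean(axis=-1)
            ts = data.data[roi].mean(axis=0)
            ts_sd = float(ts.std(ddof=1)) if ts.size > 1 else np.nan
        else:
            voxel_means = data[roi]
            ts_sd = np.nan
        rows.append({"roi": rid, "n_voxels": int(roi.sum()),
                     "mean": float(voxel_means.mean()),
                     "sd": float(voxel_means.std(ddof=1)) if voxel_means.size > 1 else 0.0,
                     "timeseries_sd": ts_sd})
    return pd.DataFrame(rows)


def power_spectrum(ts: Timeseries) -> PowerSpectrum:
    """Periodogram of the mean-removed timeseries, normalized to unit total.

    The periodogram (rather than Welch) keeps single-bin frequency
    resolution, which the sub-0.01 Hz band comparison needs.
    """
    if ts.n < 8:
        raise ValueError("need at least 8 samples")
    x = ts.values - ts.values.mean()
    if np.allclose(x, 0):
        raise ValueError("constant timeseries has zero power")
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(ts.n, d=ts.tr)
    spec, freqs = spec[1:], freqs[1:]          # drop DC (zero after demeaning)
    return PowerSpectrum(frequencies=freqs, relative_power=spec / spec.sum())


def band_power_compare(group_a: list[PowerSpectrum], group_b: list[PowerSpectrum],
                       low_band: tuple[float, float] = (0.0, 0.01),
                       high_band: tuple[float, float] | None = None,
                       alpha: float = 0.05) -> dict:
    """Paired per-frequency comparison of two sets of spectra.

    A two-sided paired t-test is run at every frequency bin and
    Bonferroni-corrected across bins; each band is additionally tested
    at the band level (paired t-test on band-summed relative power,
    Bonferroni-corrected across the two bands), which is the decision a
    band comparison reports — per-bin power is too variable for
    bin-wise significance at small subject counts. Band summaries carry
    significant bins and their direction (+1 where B > A).
    ``high_band`` defaults to (0.03, Nyquist).
    """
    if len(group_a) != len(group_b) or len(group_a) < 3:
        raise ValueError("need >= 3 paired spectra")
    freqs = group_a[0].frequencies
    for sp in list(group_a) + list(group_b):
        if not np.allclose(sp.frequencies, freqs):
            raise ValueError("frequency grids differ")
    a = np.array([sp.relative_power for sp in group_a])
    b = np.array([sp.relative_power for sp in group_b])
    nbins = freqs.size
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_rel(b, a, axis=0)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    p_corr = np.minimum(pvals * nbins, 1.0)
    sig = p_corr < alpha
    direction = np.sign(np.where(np.isnan(tstat), 0.0, tstat))
    if high_band is None:
        high_band = (0.03, freqs.max())

    n_bands = 2

    def band_summary(lo, hi):
        in_band = (freqs >= lo) & (freqs <= hi)
        s = sig & in_band
        band_a = a[:, in_band].sum(axis=1)
        band_b = b[:, in_band].sum(axis=1)
        if in_band.any() and not np.allclose(band_a, band_b):
            t_band, p_band = stats.ttest_rel(band_b, band_a)
            p_band = min(float(p_band) * n_bands, 1.0)
        else:
            t_band, p_band = 0.0, 1.0
        return {
            "n_bins": int(in_band.sum()),
            "n_significant": int(s.sum()),
            "n_b_greater": int((s & (direction > 0)).sum()),
            "n_a_greater": int((s & (direction < 0)).sum()),
            "mean_delta": float((band_b - band_a).mean()) if in_band.any() else np.nan,
            "band_p": p_band,
            "band_significant": bool(p_band < alpha),
            "band_direction": int(np.sign(t_band)),
        }

    return {
        "frequencies": freqs,
        "p_corrected": p_corr,
        "significant": sig,
        "direction": direction,
        "low_band": band_summary(*low_band),
        "high_band": band_summary(*high_band),
    }
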