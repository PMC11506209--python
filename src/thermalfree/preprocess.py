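"""Standard preprocessing stages: dummy removal, global linear detrend,
brick-wall band-pass filtering, and 3D Gaussian smoothing.

The default stage order follows the processing chain the denoisers sit
in: dummy removal -> (denoise) -> smoothing -> global detrend ->
band-pass. Slice-timing adjustment is interface-parity only: the
phantom has no slice-time structure, so the stage is a documented no-op.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import Volume4D, Timeseries, _check_mask

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def drop_dummies(vol: Volume4D, n: int = 10) -> Volume4D:
    """Remove the first ``n`` volumes (pre-equilibrium dummies)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= vol.n_timepoints:
        raise ValueError(f"cannot drop {n} of {vol.n_timepoints} volumes")
    return vol.with_data(vol.data[..., n:])


def detrend_global(vol: Volume4D, mask: np.ndarray | None = None) -> Volume4D:
    """Subtract the whole-brain global linear trend from every voxel.

    A line is least-squares fitted to the spatial-mean timeseries over
    ``mask``; the zero-mean trend component ``slope * (t - t_mean)`` is
    subtracted from each voxel, so voxel temporal means are unchanged
    and only the shared drift is removed (private voxel slopes survive).
    """
    nt = vol.n_timepoints
    if nt < 3:
        raise ValueError("need at least 3 time points to detrend")
    if mask is not None:
        mask = _check_mask(mask, vol.spatial_shape)
        if not mask.any():
            raise ValueError("mask is empty")
        gs = vol.data[mask].mean(axis=0)
    else:
        gs = vol.data.reshape(-1, nt).mean(axis=0)
    t = np.arange(nt, dtype=float)
    tc = t - t.mean()
    slope = float(tc @ (gs - gs.mean()) / (tc @ tc))
    return vol.with_data(vol.data - slope * tc)


def bandpass(vol: Volume4D, low: float, high: float) -> Volume4D:
    """Ideal (brick-wall) frequency-domain band-pass per voxel.

    Fourier bins with frequency in ``[low, high]`` Hz are kept exactly;
    everything else, including DC when ``low > 0``, is zeroed. Applying
    the same band twice is therefore a no-op after the first pass.
    """
    nyquist = 1.0 / (2.0 * vol.tr)
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high > nyquist + 1e-12:
        raise ValueError(f"high {high} Hz exceeds Nyquist {nyquist} Hz")
    nt = vol.n_timepoints
    freqs = np.fft.rfftfreq(nt, d=vol.tr)
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(vol.data, axis=-1)
    spec[..., ~keep] = 0.0
    return vol.with_data(np.fft.irfft(spec, n=nt, axis=-1))


def bandpass_ts(ts: Timeseries, low: float, high: float) -> Timeseries:
    """Brick-wall band-pass of a single timeseries (same rule as :func:`bandpass`)."""
    vol = Volume4D(ts.values[None, None, None, :], tr=ts.tr)
    return Timeseries(bandpass(vol, low, high).data[0, 0, 0], tr=ts.tr)


def smooth_gaussian(vol: Volume4D, fwhm: float = 2.0) -> Volume4D:
    """Per-volume 3D Gaussian smoothing, FWHM in voxels, reflect boundary."""
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return vol.with_data(vol.data.copy())
    sigma = fwhm * FWHM_TO_SIGMA
    out = gaussian_filter(vol.data, sigma=(sigma, sigma, sigma, 0.0), mode="reflect")
    return vol.with_data(out)


def slice_timing_noop(vol: Volume4D) -> Volume4D:
    """Slice-timing stage placeholder: identity (no slice-time structure here)."""
    return vol.with_data(vol.data.copy())
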