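"""Patch-based SVD denoising of thermal noise in magnitude fMRI.

Two estimators operate on local Casorati matrices (patch voxels x time):

* NORDIC-style denoising: the volume is first noise-flattened (each
  voxel timeseries divided by its local noise SD so thermal noise is
  spatially identical), then every patch is hard-thresholded at the
  largest singular value expected from a pure-Gaussian matrix of the
  same size, and overlapping reconstructions are averaged.
* MPPCA: per patch, the Marchenko-Pastur bulk is fitted to the
  eigenvalue spectrum and only components beyond its right edge are
  kept (Veraart-style criterion); no prior noise map is needed.

The cubic patch edge follows the 11:1 spatial-to-temporal voxel rule:
``edge = round((11 * n_timepoints)^(1/3))``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import Volume4D, _check_mask


@dataclass
class PatchConfig:
    """Patch geometry and thresholding policy for patch-SVD denoising."""

    kernel: tuple[int, int, int] | int | str = "auto"
    shift: tuple[int, int, int] | int | str = "half"
    threshold_scale: float = 1.0
    threshold_method: str = "analytic"     # "analytic" | "montecarlo"
    mc_draws: int = 100
    mc_seed: int = 0

    def resolve(self, spatial_shape: tuple[int, int, int], nt: int
                ) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        if self.kernel == "auto":
            edge = auto_kernel(nt)
            kernel = (edge, edge, edge)
        elif isinstance(self.kernel, int):
            kernel = (self.kernel,) * 3
        else:
            kernel = tuple(int(k) for k in self.kernel)
        kernel = tuple(min(k, ext) for k, ext in zip(kernel, spatial_shape))
        if self.shift == "half":
            shift = tuple(max(k // 2, 1) for k in kernel)
        elif isinstance(self.shift, int):
            shift = (self.shift,) * 3
        else:
            shift = tuple(int(s) for s in self.shift)
        for s, k in zip(shift, kernel):
            if not 1 <= s <= k:
                raise ValueError(f"shift {s} must satisfy 1 <= shift <= kernel {k}")
        return kernel, shift


@dataclass
class NoiseEstimate:
    """Per-voxel thermal-noise SD map plus a scalar global sigma."""

    sigma_map: np.ndarray
    global_sigma: float
    method: str = "mppca"

    def __post_init__(self) -> None:
        self.sigma_map = np.asarray(self.sigma_map, dtype=np.float64)
        if self.sigma_map.ndim != 3:
            raise ValueError("sigma_map must be 3D")


@dataclass
class DenoiseResult:
    volume: Volume4D
    n_components: np.ndarray        # per patch-center retained-component count
    threshold: np.ndarray           # tau used per patch
    overlap_weight: np.ndarray      # number of patches covering each voxel


def auto_kernel(n_timepoints: int) -> int:
    """Cubic patch edge from the 11:1 spatial-to-temporal voxel ratio.

    Returns the integer edge whose cube best matches ``11 * T`` voxels,
    i.e. ``round((11 T)^(1/3))``; e.g. T=250 -> 14, T=590 -> 19,
    T=512 -> 18, T=240 -> 14.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    return int(round((11.0 * n_timepoints) ** (1.0 / 3.0)))


# --------------------------------------------------------------------------- #
# Noise estimation and flattening
# --------------------------------------------------------------------------- #

def _mp_edge(m: int, n: int) -> float:
    """Upper edge of the pure-noise eigen-spectrum of an m x n Gaussian
    matrix, in units of ``sigma^2 / max(m, n)``.

    The asymptotic Marchenko-Pastur edge ``(sqrt(m)+sqrt(n))^2`` plus a
    Tracy-Widom finite-size allowance (upper-quantile scale factor 2.0)
    so that a pure-noise largest eigenvalue rarely crosses it.
    """
    root = np.sqrt(m) + np.sqrt(n)
    tw_scale = root * (1.0 / np.sqrt(m) + 1.0 / np.sqrt(n)) ** (1.0 / 3.0)
    return (root ** 2 + 2.0 * tw_scale) / max(m, n)


def _mp_sigma(casorati: np.ndarray) -> tuple[float, int]:
    """Noise SD and signal-component count from a patch eigen-spectrum.

    The Casorati matrix is demeaned over time and its eigenvalues
    scanned from the largest down: the smallest ``p`` for which the
    remaining spectrum fits under the Marchenko-Pastur right edge
    (noise variance estimated from those same eigenvalues) gives the
    signal count; the bulk mean gives ``sigma^2``.
    """
    m, n = casorati.shape
    x = casorati - casorati.mean(axis=1, keepdims=True)
    larger = max(m, n)
    s = np.linalg.svd(x, compute_uv=False)
    eigs = (s ** 2) / larger                  # descending, length min(m, n)
    k = eigs.size
    edge = _mp_edge(m, n)
    for p in range(k):
        sigma2 = eigs[p:].mean()
        if eigs[p] <= sigma2 * edge:
            return float(np.sqrt(max(sigma2, 0.0))), p
    return float(np.sqrt(max(eigs[-1], 0.0))), k - 1


def estimate_noise(vol: Volume4D, mask: np.ndarray | None = None,
                   patch_edge: int = 5, smooth_sigma: float = 1.5) -> NoiseEstimate:
    """Spatial noise-SD map from local Marchenko-Pastur fits.

    Half-overlapping cubic patches are fitted with :func:`_mp_sigma`,
    the per-patch SDs are averaged onto their voxels, and the result is
    smoothed into a slowly varying map (the noise field is assumed
    smooth, g-factor-like). ``global_sigma`` is the median over the mask.
    """
    nx, ny, nz, nt = vol.shape
    if nt < 2:
        raise ValueError("need at least 2 time points")
    mask = _check_mask(mask, vol.spatial_shape) if mask is not None else np.ones(vol.spatial_shape, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    edge = min(patch_edge, nx, ny, nz)
    acc = np.zeros((nx, ny, nz))
    cover = np.zeros((nx, ny, nz))
    half = max(edge // 2, 1)
    starts = [_patch_starts(ext, edge, half) for ext in (nx, ny, nz)]
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                block = vol.data[sx:sx + edge, sy:sy + edge, sz:sz + edge]
                cas = block.reshape(-1, nt)
                sigma, _ = _mp_sigma(cas)
                acc[sx:sx + edge, sy:sy + edge, sz:sz + edge] += sigma
                cover[sx:sx + edge, sy:sy + edge, sz:sz + edge] += 1.0
    raw = acc / cover
    smooth = gaussian_filter(raw, sigma=smooth_sigma, mode="reflect") if smooth_sigma > 0 else raw
    smooth = np.maximum(smooth, 1e-12)
    return NoiseEstimate(sigma_map=smooth,
                         global_sigma=float(np.median(smooth[mask])),
                         method="mppca")


def flatten_noise(vol: Volume4D, noise: NoiseEstimate,
                  direction: str = "forward") -> Volume4D:
    """Divide (forward) or multiply (inverse) each timeseries by its noise SD."""
    if noise.sigma_map.shape != vol.spatial_shape:
        raise ValueError("sigma map shape mismatch")
    if np.any(noise.sigma_map <= 0):
        raise ValueError("sigma map must be strictly positive")
    if direction == "forward":
        return vol.with_data(vol.data / noise.sigma_map[..., None])
    if direction == "inverse":
        return vol.with_data(vol.data * noise.sigma_map[..., None])
    raise ValueError("direction must be 'forward' or 'inverse'")


# --------------------------------------------------------------------------- #
# Thresholds
# --------------------------------------------------------------------------- #

def gaussian_sv_threshold(m: int, n: int, sigma: float = 1.0,
                          method: str = "analytic", scale: float = 1.0,
                          n_draws: int = 100, seed: int = 0) -> float:
    """Largest singular value expected from an i.i.d. Gaussian m x n matrix.

    ``analytic`` uses the asymptotic edge ``sigma * (sqrt(m) + sqrt(n))``;
    ``montecarlo`` averages the empirical maximum singular value over
    ``n_draws`` seeded draws. Both are multiplied by ``scale``.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return 0.0
    if method == "analytic":
        tau = sigma * (np.sqrt(m) + np.sqrt(n))
    elif method == "montecarlo":
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        rng = np.random.default_rng(seed)
        tops = [np.linalg.svd(rng.standard_normal((m, n)), compute_uv=False)[0]
                for _ in range(n_draws)]
        tau = sigma * float(np.mean(tops))
    else:
        raise ValueError("method must be 'analytic' or 'montecarlo'")
    return float(scale * tau)


# --------------------------------------------------------------------------- #
# Patch machinery
# --------------------------------------------------------------------------- #

def _patch_starts(extent: int, kernel: int, shift: int) -> list[int]:
    """Start offsets of a patch lattice covering [0, extent).

    Steps of ``shift``; the final start is clamped to ``extent - kernel``
    so the lattice always reaches the boundary (no padding needed).
    """
    if kernel > extent:
        raise ValueError(f"kernel {kernel} larger than extent {extent}")
    last = extent - kernel
    starts = list(range(0, last + 1, shift))
    if starts[-1] != last:
        starts.append(last)
    return starts


def _svd_hard_threshold(cas: np.ndarray, tau: float) -> tuple[np.ndarray, int]:
    u, s, vt = np.linalg.svd(cas, full_matrices=False)
    keep = s >= tau
    kept = int(keep.sum())
    if kept == 0:
        return np.zeros_like(cas), 0
    return (u[:, keep] * s[keep]) @ vt[keep], kept


def _mppca_patch(cas: np.ndarray) -> tuple[np.ndarray, int, float]:
    m, n = cas.shape
    mean = cas.mean(axis=1, keepdims=True)
    x = cas - mean
    larger = max(m, n)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigs = (s ** 2) / larger
    k = eigs.size
    edge = _mp_edge(m, n)
    kept = k - 1
    sigma2 = eigs[-1]
    for p in range(k):
        sig2 = eigs[p:].mean()
        if eigs[p] <= sig2 * edge:
            kept, sigma2 = p, sig2
            break
    if kept == 0:
        recon = np.zeros_like(x)
    else:
        recon = (u[:, :kept] * s[:kept]) @ vt[:kept]
    return recon + mean, kept, float(np.sqrt(max(sigma2, 0.0)))


def _run_patches(data: np.ndarray, kernel, shift, patch_fn):
    """Apply ``patch_fn(casorati) -> (recon, n_kept, tau)`` over the lattice."""
    nx, ny, nz, nt = data.shape
    out = np.zeros_like(data)
    weight = np.zeros((nx, ny, nz))
    starts = [_patch_starts(ext, k, s) for ext, k, s in zip((nx, ny, nz), kernel, shift)]
    n_patches = len(starts[0]) * len(starts[1]) * len(starts[2])
    ncomp = np.zeros(n_patches, dtype=int)
    taus = np.zeros(n_patches)
    i = 0
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = (slice(sx, sx + kernel[0]), slice(sy, sy + kernel[1]),
                      slice(sz, sz + kernel[2]))
                cas = data[sl].reshape(-1, nt)
                recon, kept, tau = patch_fn(cas)
                out[sl] += recon.reshape(kernel + (nt,))
                weight[sl] += 1.0
                ncomp[i], taus[i] = kept, tau
                i += 1
    out /= weight[..., None]
    return out, ncomp, taus, weight


# --------------------------------------------------------------------------- #
# Denoisers
# --------------------------------------------------------------------------- #

def nordic_denoise(vol: Volume4D, cfg: PatchConfig | None = None,
                   noise: NoiseEstimate | None = None) -> DenoiseResult:
    """NORDIC-style magnitude denoising.

    The volume is noise-flattened with ``noise`` (estimated from the
    data if not given), each patch Casorati matrix is hard-thresholded
    at the largest singular value expected from unit-variance Gaussian
    noise of the same dimensions, overlapping patch reconstructions are
    averaged with uniform weights, and the flattening is inverted.
    """
    cfg = cfg or PatchConfig()
    if vol.n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    if noise is None:
        noise = estimate_noise(vol)
    kernel, shift = cfg.resolve(vol.spatial_shape, vol.n_timepoints)
    flat = flatten_noise(vol, noise, "forward")
    m = int(np.prod(kernel))
    tau = gaussian_sv_threshold(m, vol.n_timepoints, sigma=1.0,
                                method=cfg.threshold_method, scale=cfg.threshold_scale,
                                n_draws=cfg.mc_draws, seed=cfg.mc_seed)

    def patch_fn(cas):
        recon, kept = _svd_hard_threshold(cas, tau)
        return recon, kept, tau

    out, ncomp, taus, weight = _run_patches(flat.data, kernel, shift, patch_fn)
    result = flatten_noise(vol.with_data(out), noise, "inverse")
    return DenoiseResult(volume=result, n_components=ncomp, threshold=taus,
                         overlap_weight=weight)


def mppca_denoise(vol: Volume4D, cfg: PatchConfig | None = None) -> DenoiseResult:
    """Marchenko-Pastur PCA denoising (right-edge component selection)."""
    cfg = cfg or PatchConfig(kernel=7)
    if vol.n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    kernel, shift = cfg.resolve(vol.spatial_shape, vol.n_timepoints)

    def patch_fn(cas):
        recon, kept, sigma = _mppca_patch(cas)
        return recon, kept, sigma

    out, ncomp, taus, weight = _run_patches(vol.data, kernel, shift, patch_fn)
    return DenoiseResult(volume=vol.with_data(out), n_components=ncomp,
                         threshold=taus, overlap_weight=weight)
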