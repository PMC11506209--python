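"""Population receptive field (pRF) grid modeling and cluster-extent
thresholding.

Each voxel is modeled as an isotropic 2D Gaussian receptive field
(center x, y; size sigma, all in degrees of visual angle). For every
grid model the stimulus aperture movie is projected through the
Gaussian, convolved with an HRF, and regressed against the voxel
timeseries; a winner-take-all rule keeps the grid model with the
highest R^2 (positive response amplitude only). Display thresholding
uses R = sqrt(R^2); multiple comparisons are handled by Monte-Carlo
cluster-extent thresholding on smoothed Gaussian null fields.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter, label

from .core import Timeseries
from .phantom import PRFStimulus
from .preprocess import FWHM_TO_SIGMA

SIX_CONNECTIVITY = np.array([[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
                             [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
                             [[0, 0, 0], [0, 1, 0], [0, 0, 0]]])


@dataclass
class PRFGrid:
    """Search grid of candidate receptive-field centers and sizes (degrees)."""

    x: np.ndarray
    y: np.ndarray
    size: np.ndarray

    @property
    def n_models(self) -> int:
        return self.x.size * self.y.size * self.size.size

    def models(self) -> np.ndarray:
        """All (x, y, size) combinations in linear-index order (x slowest)."""
        xx, yy, ss = np.meshgrid(self.x, self.y, self.size, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), ss.ravel()])


@dataclass
class PRFFit:
    x: float
    y: float
    size: float
    r2: float
    r: float
    eccentricity: float
    polar_angle: float
    model_index: int


@dataclass
class ClusterResult:
    min_cluster_size: int
    cluster_sizes: np.ndarray      # surviving clusters only
    largest_cluster_size: int
    surviving_mask: np.ndarray
    null_max_sizes: np.ndarray


def build_grid(fov: float = 26.0, nx: int = 30, ny: int = 30, nsizes: int = 30,
               size_range: tuple[float, float] = (0.20, 7.00)) -> PRFGrid:
    """Linear grid: centers span [-fov/2, fov/2], sizes span ``size_range``."""
    if nx < 1 or ny < 1 or nsizes < 1:
        raise ValueError("grid counts must be >= 1")
    if fov <= 0:
        raise ValueError("fov must be positive")
    if size_range[0] <= 0 or size_range[1] < size_range[0]:
        raise ValueError("sizes must be positive and ordered")
    half = fov / 2.0
    return PRFGrid(x=np.linspace(-half, half, nx) if nx > 1 else np.array([0.0]),
                   y=np.linspace(-half, half, ny) if ny > 1 else np.array([0.0]),
                   size=np.linspace(size_range[0], size_range[1], nsizes)
                   if nsizes > 1 else np.array([size_range[0]]))


def predict_response(x: float, y: float, size: float, stimulus: PRFStimulus,
                     hrf_kernel: np.ndarray, tr: float) -> np.ndarray:
    """Predicted BOLD timeseries for one candidate receptive field.

    Per frame, the overlap is the aperture-weighted integral of the
    Gaussian RF (normalized by the Gaussian's full integral, so a
    full-field aperture gives overlap 1); the overlap series is then
    convolved with the HRF and truncated to the scan length. Stimulus
    frames must already be at TR resolution (the default paradigm has
    2 s frames at TR = 2 s).
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if abs(stimulus.frame_duration - tr) > 1e-9:
        raise ValueError("stimulus frames must be resampled to the TR")
    X, Y = stimulus.pixel_grid()
    rf = np.exp(-((X - x) ** 2 + (Y - y) ** 2) / (2.0 * size ** 2))
    total = rf.sum()
    overlap = stimulus.apertures.reshape(stimulus.n_frames, -1) @ (rf.ravel() / total)
    return np.convolve(overlap, hrf_kernel)[: stimulus.n_frames]


def grid_predictions(grid: PRFGrid, stimulus: PRFStimulus,
                     hrf_kernel: np.ndarray, tr: float) -> np.ndarray:
    """Predicted timeseries for every grid model, shape (n_models, T).

    Separable in (center, size): RF integrals against each aperture
    frame are evaluated per (x, y, size) combination via one matrix
    product per size to keep the 27,000-model default tractable.
    """
    X, Y = stimulus.pixel_grid()
    ap = stimulus.apertures.reshape(stimulus.n_frames, -1).astype(float)
    models = grid.models()
    n_models = models.shape[0]
    preds = np.empty((n_models, stimulus.n_frames))
    hrf_kernel = np.asarray(hrf_kernel, float)
    for s in np.unique(models[:, 2]):
        sel = np.flatnonzero(models[:, 2] == s)
        rfs = np.empty((sel.size, ap.shape[1]))
        for i, idx in enumerate(sel):
            x0, y0 = models[idx, 0], models[idx, 1]
            rf = np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * s ** 2))
            rfs[i] = rf.ravel() / rf.sum()
        overlaps = rfs @ ap.T                         # models x frames
        for i, idx in enumerate(sel):
            preds[idx] = np.convolve(overlaps[i], hrf_kernel)[: stimulus.n_frames]
    return preds


def fit_prf(ts: Timeseries | np.ndarray, grid: PRFGrid, stimulus: PRFStimulus,
            hrf_kernel: np.ndarray, tr: float = 2.0,
            predictions: np.ndarray | None = None) -> PRFFit:
    """Winner-take-all grid search for a single voxel timeseries.

    Each model is fit by OLS (prediction + intercept); the model with
    the highest R^2 wins, restricted to positive response amplitudes
    (negative-slope fits score 0). Ties break to the smallest grid
    linear index, so the fit is fully deterministic.
    """
    y = ts.values if isinstance(ts, Timeseries) else np.asarray(ts, float).ravel()
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise ValueError("constant timeseries cannot be fit")
    if predictions is None:
        predictions = grid_predictions(grid, stimulus, hrf_kernel, tr)
    r2, slope_sign = _r2_against(predictions, yc, ynorm)
    r2 = np.clip(np.where(slope_sign > 0, r2, 0.0), 0.0, 1.0)
    best = int(np.argmax(r2))                 # argmax takes the first maximum
    mx, my, msize = grid.models()[best]
    best_r2 = float(r2[best])
    ecc, ang = to_polar(mx, my)
    return PRFFit(x=float(mx), y=float(my), size=float(msize), r2=best_r2,
                  r=float(np.sqrt(best_r2)), eccentricity=ecc, polar_angle=ang,
                  model_index=best)


def _r2_against(predictions: np.ndarray, yc: np.ndarray, ynorm: float):
    pc = predictions - predictions.mean(axis=1, keepdims=True)
    pnorm = np.linalg.norm(pc, axis=1)
    ok = pnorm > 1e-12
    dot = pc @ yc
    corr = np.zeros(predictions.shape[0])
    corr[ok] = dot[ok] / (pnorm[ok] * ynorm)
    return corr ** 2, np.sign(dot)


def fit_prf_volume(data: np.ndarray, grid: PRFGrid, stimulus: PRFStimulus,
                   hrf_kernel: np.ndarray, tr: float = 2.0,
                   mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Vectorized winner-take-all fit over a 4D array; returns parameter maps."""
    spatial = data.shape[:3]
    mask = np.ones(spatial, bool) if mask is None else np.asarray(mask, bool)
    preds = grid_predictions(grid, stimulus, hrf_kernel, tr)
    pc = preds - preds.mean(axis=1, keepdims=True)
    pnorm = np.linalg.norm(pc, axis=1)
    ok = pnorm > 1e-12
    Y = data[mask]                             # voxels x time
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ynorm = np.linalg.norm(Yc, axis=1)
    good = ynorm > 0
    corr = np.zeros((pc.shape[0], Yc.shape[0]))
    corr[np.ix_(ok, good)] = (pc[ok] @ Yc[good].T) / np.outer(pnorm[ok], ynorm[good])
    r2 = np.clip(np.where(corr > 0, corr ** 2, 0.0), 0.0, 1.0)  # positive amplitude only
    best = np.argmax(r2, axis=0)
    best_r2 = r2[best, np.arange(r2.shape[1])]
    models = grid.models()
    out = {}
    for name, vals in (("x", models[best, 0]), ("y", models[best, 1]),
                       ("size", models[best, 2]), ("r2", best_r2),
                       ("r", np.sqrt(best_r2))):
        m = np.full(spatial, np.nan)
        m[mask] = np.where(good, vals, np.nan)
        out[name] = m
    ecc, ang = to_polar(out["x"], out["y"])
    out["eccentricity"], out["polar_angle"] = ecc, ang
    out["model_index"] = np.full(spatial, -1, dtype=int)
    out["model_index"][mask] = np.where(good, best, -1)
    return out


def to_polar(x, y):
    """Eccentricity and polar angle (degrees, CCW from +x; origin -> 0)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ecc = np.hypot(x, y)
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    ang = np.where(ang >= 360.0, 0.0, ang)    # fp: tiny negative % 360 -> 360.0
    ang = np.where(ecc == 0, 0.0, ang)
    if ecc.ndim == 0:
        return float(ecc), float(ang)
    return ecc, ang


def r_null_tail_prob(r: float, n: int) -> float:
    """P(|correlation| > r) for an n-sample correlation of independent
    Gaussians — the voxelwise null tail used to match an R threshold to
    a Gaussian quantile in the cluster-extent null."""
    if n < 4:
        raise ValueError("need n >= 4")
    t = r * np.sqrt((n - 2) / max(1e-12, 1.0 - r ** 2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def cluster_threshold(stat_map: np.ndarray, threshold: float,
                      smoothness_fwhm: float = 0.0, alpha: float = 0.05,
                      n_iter: int = 1000, seed: int = 0,
                      null_tail_prob: float | None = None,
                      mask: np.ndarray | None = None) -> ClusterResult:
    """Monte-Carlo cluster-extent thresholding (6-neighbor connectivity).

    ``n_iter`` Gaussian null fields (smoothed to ``smoothness_fwhm``
    voxels and re-standardized) are thresholded and the null
    distribution of maximum cluster size collected; the minimum cluster
    size is its ``1 - alpha`` quantile. When the stat map is not
    z-scaled (e.g. a pRF R map), pass ``null_tail_prob`` — the
    voxelwise tail probability of ``threshold`` under the map's own
    null — and the null fields are cut at the matching Gaussian
    quantile. Clusters of the stat map above ``threshold`` smaller than
    the minimum size are removed.
    """
    stat_map = np.asarray(stat_map, float)
    if not np.all(np.isfinite(stat_map[mask] if mask is not None else stat_map)):
        raise ValueError("stat map must be finite inside the mask")
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives an unstable cluster-size null", stacklevel=2)
    z_cut = (threshold if null_tail_prob is None
             else float(stats.norm.isf(null_tail_prob / 2.0)))
    rng = np.random.default_rng(seed)
    sigma = smoothness_fwhm * FWHM_TO_SIGMA
    null_max = np.empty(n_iter, dtype=int)
    shape = stat_map.shape
    mask_arr = np.asarray(mask, bool) if mask is not None else None
    for i in range(n_iter):
        field = rng.standard_normal(shape)
        if sigma > 0:
            field = gaussian_filter(field, sigma=sigma, mode="reflect")
            field = field / field.std()
        supra = field > z_cut
        if mask_arr is not None:
            supra &= mask_arr
        labels, n = label(supra, structure=SIX_CONNECTIVITY)
        null_max[i] = 0 if n == 0 else int(np.bincount(labels.ravel())[1:].max())
    min_size = int(np.ceil(np.quantile(null_max, 1.0 - alpha)))

    supra = stat_map > threshold
    if mask_arr is not None:
        supra &= mask_arr
    labels, n = label(supra, structure=SIX_CONNECTIVITY)
    surviving = np.zeros(shape, bool)
    sizes = []
    if n:
        counts = np.bincount(labels.ravel())
        for cid in range(1, n + 1):
            if counts[cid] >= min_size:
                surviving |= labels == cid
                sizes.append(int(counts[cid]))
    sizes = np.asarray(sorted(sizes, reverse=True), dtype=int)
    return ClusterResult(min_cluster_size=min_size, cluster_sizes=sizes,
                         largest_cluster_size=int(sizes[0]) if sizes.size else 0,
                         surviving_mask=surviving, null_max_sizes=null_max)
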