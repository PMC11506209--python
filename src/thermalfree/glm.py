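"""Block-design activation mapping: HRF-convolved design, voxelwise OLS
GLM, Benjamini-Hochberg FDR thresholding, and threshold sweeps.

No autocorrelation prewhitening is applied: the phantom's thermal noise
is temporally white, and AR modeling of real-data physiological noise
is outside this package's scope.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Volume4D, _check_mask


@dataclass
class DesignMatrix:
    """Columns: HRF-convolved task regressor(s) then an intercept."""

    matrix: np.ndarray
    names: tuple[str, ...]
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if "intercept" not in self.names:
            raise ValueError("design must contain an intercept column")


@dataclass
class ActivationMap:
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    n_activated: int
    df: int


def build_design(boxcar: np.ndarray, hrf_kernel: np.ndarray, tr: float) -> DesignMatrix:
    """Convolve the boxcar with the HRF (truncated to scan length) and
    append an intercept."""
    boxcar = np.asarray(boxcar, dtype=float).ravel()
    hrf_kernel = np.asarray(hrf_kernel, dtype=float).ravel()
    if hrf_kernel.size > boxcar.size:
        raise ValueError("HRF kernel longer than the scan")
    reg = np.convolve(boxcar, hrf_kernel)[: boxcar.size]
    X = np.column_stack([reg, np.ones_like(reg)])
    return DesignMatrix(matrix=X, names=("task", "intercept"), tr=tr)


def fit_glm(vol: Volume4D, design: DesignMatrix,
            mask: np.ndarray | None = None, contrast_col: int = 0) -> ActivationMap:
    """Voxelwise ordinary least squares with t and two-sided p for one column.

    ``t = beta / SE`` with residual degrees of freedom ``N - rank(X)``.
    Significance masks are left empty here; apply :func:`fdr_correct`.
    """
    X = design.matrix
    nt = vol.n_timepoints
    if X.shape[0] != nt:
        raise ValueError("design rows != time points")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    mask = _check_mask(mask, vol.spatial_shape) if mask is not None else np.ones(vol.spatial_shape, bool)
    Y = vol.data[mask].T                     # time x voxels
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    df = nt - rank
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    mse = (resid ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(mse * xtx_inv[contrast_col, contrast_col], 1e-300))
    tvals = betas[contrast_col] / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    def to_map(flat, fill=np.nan):
        out = np.full(vol.spatial_shape, fill)
        out[mask] = flat
        return out

    return ActivationMap(beta=to_map(betas[contrast_col]), t=to_map(tvals),
                         p=to_map(pvals, fill=1.0),
                         significant=np.zeros(vol.spatial_shape, bool),
                         n_activated=0, df=df)


def fdr_correct(p: np.ndarray, q: float = 0.05, mode: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg multiple-testing control.

    ``mode='bh'`` rejects via the BH step-up procedure at level ``q``;
    ``mode='adjusted'`` computes BH-adjusted p-values and thresholds
    them at ``q``. The two modes coincide for the rejection set, but
    both are exposed because "p < 0.001, FDR corrected" can be read as
    either a BH level or an adjusted-p threshold.
    """
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    if np.any((flat < 0) | (flat > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mode == "bh":
        reject, _, _, _ = multipletests(flat, alpha=q, method="fdr_bh")
    elif mode == "adjusted":
        _, p_adj, _, _ = multipletests(flat, alpha=q, method="fdr_bh")
        reject = p_adj < q
    else:
        raise ValueError("mode must be 'bh' or 'adjusted'")
    return reject.reshape(p.shape)


def apply_fdr(act: ActivationMap, mask: np.ndarray, q: float = 0.001,
              mode: str = "bh") -> ActivationMap:
    """Return a copy of ``act`` with the FDR significance mask filled in."""
    mask = np.asarray(mask, bool)
    reject = np.zeros(act.p.shape, bool)
    reject[mask] = fdr_correct(act.p[mask], q=q, mode=mode)
    return ActivationMap(beta=act.beta, t=act.t, p=act.p, significant=reject,
                         n_activated=int(reject.sum()), df=act.df)


def threshold_sweep(t_map: np.ndarray, thresholds, mask: np.ndarray | None = None) -> np.ndarray:
    """Suprathreshold voxel counts for each t threshold (non-increasing)."""
    t_map = np.asarray(t_map, dtype=float)
    if t_map.size == 0:
        raise ValueError("empty map")
    vals = t_map[np.asarray(mask, bool)] if mask is not None else t_map.ravel()
    vals = vals[np.isfinite(vals)]
    return np.array([int((vals > thr).sum()) for thr in np.asarray(thresholds, float)])
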