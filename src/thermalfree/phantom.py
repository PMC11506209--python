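"""Seeded synthetic 4D BOLD phantoms with known ground truth.

The generator emulates the statistical structure the analysis stages
assume: a block-design evoked response convolved with a rodent-style
double-gamma HRF, band-limited resting-state fluctuations shared across
the brain with a spatially varying vascular gain, a slow linear drift,
and spatially varying (g-factor-scaled) thermal noise, optionally passed
through Rician magnitude formation. Thermal noise is white in time;
temporal autocorrelation enters only through the band-limited
fluctuation term, which is what patch-SVD denoising of thermal noise
presupposes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .core import Volume4D


# --------------------------------------------------------------------------- #
# Parameter containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response function parameters (seconds).

    The defaults are the sharper rodent HRF used for block-design
    optogenetic fMRI: response delay 3.7 s, undershoot delay 4.45 s,
    both dispersions 0.5 s, undershoot ratio 1.5, onset 0, kernel 32 s.
    """

    delay_response: float = 3.7
    delay_undershoot: float = 4.45
    dispersion_response: float = 0.5
    dispersion_undershoot: float = 0.5
    ratio_undershoot: float = 1.5
    onset: float = 0.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        for name in ("delay_response", "delay_undershoot", "dispersion_response",
                     "dispersion_undershoot", "kernel_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ratio_undershoot <= 0:
            raise ValueError("ratio_undershoot must be positive")
        if self.kernel_length < self.delay_undershoot:
            raise ValueError("kernel_length must cover the undershoot delay")


@dataclass(frozen=True)
class BlockDesign:
    """Block stimulation paradigm: baseline then n_blocks of on/off (seconds)."""

    baseline: float = 20.0
    n_blocks: int = 4
    on: float = 20.0
    off: float = 40.0
    tr: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.on <= 0 or self.off <= 0 or self.tr <= 0:
            raise ValueError("baseline, on, off and tr must be positive")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")

    @property
    def total_duration(self) -> float:
        return self.baseline + self.n_blocks * (self.on + self.off)


@dataclass
class PRFStimulus:
    """Binary aperture movie for ring/wedge retinotopic stimulation.

    ``apertures`` has shape (frames, grid_y, grid_x) with values in {0, 1};
    pixel coordinates map linearly onto ``[-fov/2, +fov/2]`` degrees.
    """

    apertures: np.ndarray
    fov: float = 26.0
    frame_duration: float = 2.0
    n_positions: int = 16
    n_cycles: int = 8
    conditions: tuple[str, ...] = ("wedge_cw", "ring_expand", "wedge_ccw", "ring_contract")

    def __post_init__(self) -> None:
        self.apertures = np.asarray(self.apertures)
        if self.apertures.ndim != 3:
            raise ValueError("apertures must be (frames, grid_y, grid_x)")
        vals = np.unique(self.apertures)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("aperture values must be binary")

    @property
    def n_frames(self) -> int:
        return self.apertures.shape[0]

    @property
    def total_duration(self) -> float:
        return self.n_frames * self.frame_duration

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-center coordinates in degrees of visual angle."""
        ny, nx = self.apertures.shape[1:]
        xs = np.linspace(-self.fov / 2, self.fov / 2, nx)
        ys = np.linspace(-self.fov / 2, self.fov / 2, ny)
        return np.meshgrid(xs, ys)


@dataclass
class PhantomSpec:
    """Full description of a synthetic 4D acquisition.

    Amplitudes are fractions of baseline unless noted; ``psc_amplitude``
    is in percent. ``fluct_amp`` is the temporal SD of the shared
    low-frequency fluctuation as a fraction of baseline; ``depth_gain``
    and ``regional_gain`` multiply that fluctuation (vascular gains),
    not the baseline intensity.
    """

    shape: tuple[int, int, int, int] = (32, 32, 16, 260)
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.75)
    tr: float = 1.0
    baseline: float = 100.0
    noise_sigma: float = 5.0
    gfactor_low: float = 1.0
    gfactor_high: float = 1.0
    gfactor_smoothness: float = 4.0
    magnitude_model: str = "gaussian"      # "gaussian" | "rician"
    drift_per_volume: float = 0.0          # baseline fraction per volume
    psc_amplitude: float = 0.0             # percent signal change
    activation_roi: tuple[slice, slice, slice] | np.ndarray | None = None
    design: BlockDesign | None = None
    hrf: HRFParams = field(default_factory=HRFParams)
    psc_shift: float = 4.0                 # hemodynamic-delay shift for PSC windows (s)
    fluct_amp: float = 0.0                 # baseline fraction (temporal SD)
    fluct_band: tuple[float, float] = (0.005, 0.08)
    depth_gain: tuple[float, float] | None = None   # linear gain pial->white along z
    regional_gain: dict | None = None      # {"roi": mask-or-slices, "gain": float}
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 4 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be a positive 4-tuple")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.psc_amplitude < 0 or self.fluct_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.magnitude_model not in ("gaussian", "rician"):
            raise ValueError("magnitude_model must be 'gaussian' or 'rician'")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    noiseless: Volume4D
    activation_mask: np.ndarray
    true_psc: np.ndarray
    noise_map: np.ndarray          # per-voxel thermal noise SD (sigma * g)
    vascular_gain: np.ndarray      # per-voxel gain on the shared fluctuation
    fluctuation: np.ndarray        # shared fluctuation timeseries, unit SD
    regressor: np.ndarray | None   # HRF-convolved, PSC-calibrated task regressor
    design_boxcar: np.ndarray | None
    prf_params: np.ndarray | None = None   # (nx,ny,nz,3): x, y, size or NaN


# --------------------------------------------------------------------------- #
# Building blocks
# --------------------------------------------------------------------------- #

def make_hrf(params: HRFParams | None = None, tr: float = 1.0) -> np.ndarray:
    """Sample a peak-normalized double-gamma HRF at TR resolution.

    The kernel is the difference of two gamma densities with
    shape = delay/dispersion and scale = dispersion, the undershoot
    divided by ``ratio_undershoot``, sampled at
    ``t = 0, tr, ..., kernel_length - tr`` and scaled to ``max = 1`` so
    that GLM betas carry percent-signal-change units.
    """
    params = params or HRFParams()
    if tr <= 0:
        raise ValueError("tr must be positive")
    n = int(round(params.kernel_length / tr))
    if n < 1:
        raise ValueError("kernel_length shorter than one TR")
    t = np.arange(n) * tr - params.onset
    kernel = _double_gamma(t, params)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return kernel / peak


def _double_gamma(t: np.ndarray, p: HRFParams) -> np.ndarray:
    pos = gamma_dist.pdf(t, a=p.delay_response / p.dispersion_response,
                         scale=p.dispersion_response)
    neg = gamma_dist.pdf(t, a=p.delay_undershoot / p.dispersion_undershoot,
                         scale=p.dispersion_undershoot)
    return pos - neg / p.ratio_undershoot


def make_block_design(design: BlockDesign) -> np.ndarray:
    """Boxcar regressor, one value in {0,1} per TR."""
    for dur in (design.baseline, design.on, design.off):
        if abs(dur / design.tr - round(dur / design.tr)) > 1e-9:
            raise ValueError("durations must be integer multiples of tr")
    nb = int(round(design.baseline / design.tr))
    non = int(round(design.on / design.tr))
    noff = int(round(design.off / design.tr))
    boxcar = [np.zeros(nb)]
    for _ in range(design.n_blocks):
        boxcar.append(np.ones(non))
        boxcar.append(np.zeros(noff))
    return np.concatenate(boxcar)


def make_prf_stimulus(
    n_positions: int = 16,
    n_cycles: int = 8,
    conditions: Sequence[str] = ("wedge_cw", "ring_expand", "wedge_ccw", "ring_contract"),
    frame_duration: float = 2.0,
    fov: float = 26.0,
    grid_size: int = 101,
    wedge_width_deg: float = 45.0,
) -> PRFStimulus:
    """Ring/wedge aperture movie on a square pixel grid.

    Wedges span ``wedge_width_deg`` of polar angle and step through
    ``n_positions`` orientations per cycle; rings have a thickness of
    1/8 of the maximum eccentricity and step through ``n_positions``
    radial positions. Frame count = positions x cycles x conditions.
    """
    if n_positions < 1 or n_cycles < 1 or len(conditions) < 1:
        raise ValueError("positions, cycles and conditions must be >= 1")
    if grid_size < 1:
        raise ValueError("grid size must be positive")
    half = fov / 2.0
    xs = np.linspace(-half, half, grid_size)
    X, Y = np.meshgrid(xs, xs)
    ecc = np.hypot(X, Y)
    ang = np.degrees(np.arctan2(Y, X)) % 360.0
    ring_width = half / 8.0

    frames = []
    for cond in conditions:
        for _ in range(n_cycles):
            for pos in range(n_positions):
                if cond.startswith("wedge"):
                    step = 360.0 / n_positions
                    start = pos * step if cond.endswith("cw") else (n_positions - 1 - pos) * step
                    dang = (ang - start) % 360.0
                    ap = (dang < wedge_width_deg) & (ecc <= half)
                else:
                    idx = pos if cond.endswith("expand") else n_positions - 1 - pos
                    inner = idx * (half - ring_width) / max(n_positions - 1, 1)
                    ap = (ecc >= inner) & (ecc < inner + ring_width)
                frames.append(ap)
    apertures = np.asarray(frames, dtype=np.uint8)
    return PRFStimulus(apertures=apertures, fov=fov, frame_duration=frame_duration,
                       n_positions=n_positions, n_cycles=n_cycles,
                       conditions=tuple(conditions))


def make_gfactor_map(
    shape: tuple[int, int, int],
    low: float = 1.0,
    high: float = 1.0,
    smoothness: float = 4.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Smooth positive noise-amplification map with values in [low, high].

    A white Gaussian field is smoothed with a Gaussian of SD
    ``smoothness`` voxels and linearly rescaled to the requested range;
    a fixed seed gives a bitwise-identical map.
    """
    from scipy.ndimage import gaussian_filter

    if low <= 0:
        raise ValueError("low must be positive")
    if high < low:
        raise ValueError("high must be >= low")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field_ = rng.standard_normal(shape)
    if smoothness > 0:
        field_ = gaussian_filter(field_, sigma=smoothness, mode="reflect")
    lo, hi = field_.min(), field_.max()
    if hi - lo < 1e-12:   # degenerate (e.g. 1-voxel map): uniform at midpoint
        return np.full(shape, (low + high) / 2.0)
    return low + (field_ - lo) * (high - low) / (hi - lo)


# --------------------------------------------------------------------------- #
# Full simulation
# --------------------------------------------------------------------------- #

def _roi_mask(roi, spatial_shape) -> np.ndarray:
    if isinstance(roi, np.ndarray):
        if roi.shape != tuple(spatial_shape):
            raise ValueError("activation ROI mask shape mismatch")
        return roi.astype(bool)
    mask = np.zeros(spatial_shape, dtype=bool)
    try:
        mask[roi] = True
    except IndexError as exc:
        raise ValueError("activation ROI outside grid") from exc
    for sl, ext in zip(roi, spatial_shape):
        if isinstance(sl, slice):
            start, stop, _ = sl.indices(ext)
            if (sl.stop is not None and sl.stop > ext) or (sl.start is not None and sl.start >= ext):
                raise ValueError("activation ROI outside grid")
    if not mask.any():
        raise ValueError("activation ROI outside grid")
    return mask


def _band_limited_series(nt: int, tr: float, band: tuple[float, float],
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian series with spectral support restricted to ``band``."""
    white = rng.standard_normal(nt)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(nt, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    keep[0] = False
    if not keep.any():
        raise ValueError("fluctuation band contains no resolvable frequency")
    spec[~keep] = 0.0
    series = np.fft.irfft(spec, n=nt)
    sd = series.std()
    return series / sd if sd > 0 else series


def psc_windows(boxcar: np.ndarray, shift_volumes: int) -> tuple[np.ndarray, np.ndarray]:
    """On/off sample indices for PSC, with the on-window delayed by the HRF rise."""
    on = np.zeros(boxcar.size, dtype=bool)
    src = np.flatnonzero(boxcar > 0.5) + shift_volumes
    on[src[src < boxcar.size]] = True
    off = np.zeros(boxcar.size, dtype=bool)
    idx = np.flatnonzero(boxcar <= 0.5) + shift_volumes
    off[idx[idx < boxcar.size]] = True
    off[:shift_volumes] = True   # pre-stimulus baseline counts as off
    off &= ~on
    return on, off


def _calibrated_regressor(boxcar: np.ndarray, hrf: np.ndarray,
                          shift_volumes: int) -> np.ndarray:
    """HRF-convolved boxcar rescaled so an on/off-window PSC reads exactly 1.

    The raw convolution is shifted and scaled so its mean over the
    (delay-shifted) off window is 0 and over the on window is 1; an
    activation of amplitude ``a`` percent then produces a measured PSC
    of exactly ``a`` on the noiseless signal.
    """
    raw = np.convolve(boxcar, hrf)[: boxcar.size]
    on, off = psc_windows(boxcar, shift_volumes)
    if not on.any() or not off.any():
        raise ValueError("design lacks on or off samples after shift")
    base = raw[off].mean()
    span = raw[on].mean() - base
    if abs(span) < 1e-12:
        raise ValueError("degenerate design: no evoked contrast")
    return (raw - base) / span


def simulate_fmri(spec: PhantomSpec) -> tuple[Volume4D, GroundTruth]:
    """Generate a seeded 4D phantom and its ground truth.

    The noiseless signal is
    ``baseline * (1 + (a/100)*regressor + gain*fluct_amp*G(t) + drift)``
    with the vascular gain (depth x regional) applied to the shared
    band-limited fluctuation ``G``; thermal noise with SD
    ``noise_sigma * g(voxel)`` is then added either directly (gaussian)
    or through two-channel magnitude formation (rician).
    """
    nx, ny, nz, nt = spec.shape
    rng = np.random.default_rng(spec.seed)

    gmap = make_gfactor_map((nx, ny, nz), spec.gfactor_low, spec.gfactor_high,
                            spec.gfactor_smoothness, seed=rng)

    t_idx = np.arange(nt, dtype=float)
    drift = spec.drift_per_volume * (t_idx - t_idx.mean())

    # Task component
    boxcar = regressor = None
    act_mask = np.zeros((nx, ny, nz), dtype=bool)
    if spec.design is not None and spec.psc_amplitude > 0:
        if spec.activation_roi is None:
            raise ValueError("activation ROI required when psc_amplitude > 0")
        act_mask = _roi_mask(spec.activation_roi, (nx, ny, nz))
        boxcar = make_block_design(spec.design)
        if boxcar.size != nt:
            raise ValueError(f"design length {boxcar.size} != time points {nt}")
        hrf = make_hrf(spec.hrf, spec.design.tr)
        shift = int(round(spec.psc_shift / spec.tr))
        regressor = _calibrated_regressor(boxcar, hrf, shift)

    # Vascular gain on the shared fluctuation
    gain = np.ones((nx, ny, nz))
    if spec.depth_gain is not None:
        g0, g1 = spec.depth_gain
        gain *= np.linspace(g0, g1, nz)[None, None, :]
    if spec.regional_gain is not None:
        rmask = _roi_mask(spec.regional_gain["roi"], (nx, ny, nz))
        gain[rmask] *= float(spec.regional_gain["gain"])

    if spec.fluct_amp > 0:
        fluct = _band_limited_series(nt, spec.tr, spec.fluct_band, rng)
    else:
        fluct = np.zeros(nt)

    signal = np.ones((nx, ny, nz, nt))
    signal += drift[None, None, None, :]
    if regressor is not None:
        signal[act_mask] += (spec.psc_amplitude / 100.0) * regressor
    if spec.fluct_amp > 0:
        signal += spec.fluct_amp * gain[..., None] * fluct[None, None, None, :]
    signal *= spec.baseline

    noise_map = spec.noise_sigma * gmap
    if spec.magnitude_model == "gaussian":
        data = signal + noise_map[..., None] * rng.standard_normal(signal.shape)
    else:
        re = signal + noise_map[..., None] * rng.standard_normal(signal.shape)
        im = noise_map[..., None] * rng.standard_normal(signal.shape)
        data = np.hypot(re, im)

    vol = Volume4D(data=data, voxel_size=spec.voxel_size, tr=spec.tr)
    truth = GroundTruth(
        noiseless=Volume4D(data=signal, voxel_size=spec.voxel_size, tr=spec.tr),
        activation_mask=act_mask,
        true_psc=np.where(act_mask, spec.psc_amplitude, 0.0),
        noise_map=noise_map,
        vascular_gain=gain,
        fluctuation=fluct,
        regressor=regressor,
        design_boxcar=boxcar,
    )
    return vol, truth


def simulate_prf_sheet(
    stimulus: PRFStimulus,
    shape: tuple[int, int, int] = (8, 8, 4),
    active_slices: int = 2,
    baseline: float = 100.0,
    noise_sigma: float = 1.4,
    response_amp: float = 5.0,
    size_deg: float = 2.0,
    center_span: float = 1.5,
    center_offset: tuple[float, float] = (0.0, 0.0),
    hrf: HRFParams | None = None,
    tr: float = 2.0,
    seed: int = 0,
) -> tuple[Volume4D, GroundTruth]:
    """A smooth retinotopic sheet phantom for pRF fitting.

    The first ``active_slices`` z-slices form a cortical sheet whose
    (x, y) voxel indices map linearly onto visual-field positions in a
    ``+-center_span`` degree window around ``center_offset``; remaining
    slices are noise-only. Receptive-field centers vary smoothly from
    voxel to voxel, as on a real cortical patch, so the stimulus-driven
    signal is locally low-rank. Defaults emulate strong checkerboard
    responses (``response_amp`` percent) at a temporal SNR of
    ``baseline / noise_sigma`` ~ 70, typical of 3T visual cortex.
    """
    from .prf import predict_response

    nx, ny, nz = shape
    rng = np.random.default_rng(seed)
    xs = center_offset[0] + np.linspace(-center_span, center_span, nx)
    ys = center_offset[1] + np.linspace(-center_span, center_span, ny)
    kernel = make_hrf(hrf or HRFParams(delay_response=6.0, delay_undershoot=16.0,
                                       dispersion_response=1.0, dispersion_undershoot=1.0,
                                       ratio_undershoot=6.0, kernel_length=32.0), tr)

    nt = stimulus.n_frames
    signal = np.ones((nx, ny, nz, nt)) * baseline
    prf_params = np.full((nx, ny, nz, 3), np.nan)
    for i, x0 in enumerate(xs):
        for j, y0 in enumerate(ys):
            pred = predict_response(x0, y0, size_deg, stimulus, kernel, tr)
            peak = np.abs(pred).max()
            if peak > 0:
                pred = pred / peak
            for k in range(active_slices):
                signal[i, j, k] = baseline * (1 + response_amp / 100.0 * pred)
                prf_params[i, j, k] = (x0, y0, size_deg)
    data = signal + noise_sigma * rng.standard_normal(signal.shape)
    mask = np.zeros((nx, ny, nz), dtype=bool)
    mask[:, :, :active_slices] = True
    vol = Volume4D(data=data, voxel_size=(2.0, 2.0, 3.0), tr=tr)
    truth = GroundTruth(
        noiseless=Volume4D(data=signal, voxel_size=(2.0, 2.0, 3.0), tr=tr),
        activation_mask=mask,
        true_psc=np.where(mask, response_amp, 0.0),
        noise_map=np.full((nx, ny, nz), noise_sigma),
        vascular_gain=np.ones((nx, ny, nz)),
        fluctuation=np.zeros(nt),
        regressor=None,
        design_boxcar=None,
        prf_params=prf_params,
    )
    return vol, truth
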