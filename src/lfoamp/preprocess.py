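"""Temporal preprocessing and screening on already-aligned BOLD data.

Implements the screening and signal-conditioning chain applied before
amplitude computation: dropping initial volumes, motion screening against
the <1 mm / <1 degree criteria, per-voxel linear detrending, an ideal
frequency-mask band-pass filter, volumetric Gaussian smoothing, and
construction of the gray-matter group mask (cohort-mean GM probability
above threshold, 0.15 by default).

The band-pass is an ideal DFT-bin mask rather than an IIR design: bins whose
frequency f satisfies f_lo <= f <= f_hi are retained, all others zeroed.
This makes filtering exactly consistent with the in-band amplitude average
used by ALFF (both select the same bins) and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import BoldRun, BrainMask, MotionSummary, VolumeGrid

__all__ = [
    "Band",
    "ScreenResult",
    "drop_initial_volumes",
    "screen_motion",
    "detrend_linear",
    "bandpass",
    "band_bin_indices",
    "gaussian_smooth",
    "smooth_run",
    "make_group_mask",
    "fwhm_to_sigma_mm",
]

#: FWHM = sigma * sqrt(8 ln 2)
_FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))

#: tolerance when comparing DFT bin frequencies to band edges (Hz)
_EDGE_TOL_HZ = 1e-9


def fwhm_to_sigma_mm(fwhm_mm: float) -> float:
    return fwhm_mm / _FWHM_PER_SIGMA


@dataclass(frozen=True)
class Band:
    """A frequency band [f_lo, f_hi] in Hz; edges inclusive on DFT bins."""

    f_lo_hz: float
    f_hi_hz: float

    def __post_init__(self) -> None:
        if self.f_lo_hz < 0:
            raise ValueError(f"f_lo_hz must be >= 0, got {self.f_lo_hz}")
        if self.f_hi_hz <= self.f_lo_hz:
            raise ValueError(
                f"f_hi_hz ({self.f_hi_hz}) must exceed f_lo_hz ({self.f_lo_hz})"
            )

    def contains(self, other: "Band") -> bool:
        return (
            self.f_lo_hz <= other.f_lo_hz + _EDGE_TOL_HZ
            and other.f_hi_hz <= self.f_hi_hz + _EDGE_TOL_HZ
        )

    def validate_for(self, nyquist_hz: float) -> None:
        if self.f_hi_hz > nyquist_hz + _EDGE_TOL_HZ:
            raise ValueError(
                f"band upper edge {self.f_hi_hz} Hz exceeds Nyquist {nyquist_hz} Hz"
            )


#: the 0.01-0.08 Hz low-frequency band used throughout
LOW_FREQUENCY_BAND = Band(0.01, 0.08)


def drop_initial_volumes(run: BoldRun, n_drop: int) -> BoldRun:
    """Remove the first ``n_drop`` time points (scanner calibration period)."""
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if n_drop >= run.n_volumes:
        raise ValueError(
            f"cannot drop {n_drop} volumes from a run of {run.n_volumes}"
        )
    if n_drop == 0:
        return BoldRun(run.grid, run.data.copy(), run.tr_s)
    return BoldRun(run.grid, run.data[..., n_drop:].copy(), run.tr_s)


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


_AXIS_NAMES = ("x", "y", "z")
_ROT_NAMES = ("roll", "pitch", "yaw")


def screen_motion(
    summary: MotionSummary,
    trans_limit_mm: float = 1.0,
    rot_limit_deg: float = 1.0,
) -> ScreenResult:
    """Pass iff every translation < trans_limit and every rotation < rot_limit.

    The comparison is strict ("less than 1 mm ... less than 1 degree"), so a
    value exactly at the limit fails.
    """
    if trans_limit_mm < 0 or rot_limit_deg < 0:
        raise ValueError("motion limits must be non-negative")
    for name, value in zip(_AXIS_NAMES, summary.max_translation_mm):
        if value >= trans_limit_mm:
            return ScreenResult(
                False,
                f"{name}-translation {value:g} mm >= limit {trans_limit_mm:g} mm",
            )
    for name, value in zip(_ROT_NAMES, summary.max_rotation_deg):
        if value >= rot_limit_deg:
            return ScreenResult(
                False,
                f"{name}-rotation {value:g} deg >= limit {rot_limit_deg:g} deg",
            )
    return ScreenResult(True)


def _detrend_array(data: np.ndarray) -> np.ndarray:
    """Remove per-voxel least-squares line over the last axis."""
    n = data.shape[-1]
    t = np.arange(n, dtype=float)
    # orthonormal basis for span{1, t} -> projection is numerically exact
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), t]))
    flat = data.reshape(-1, n)
    fitted = (flat @ q) @ q.T
    return (flat - fitted).reshape(data.shape)


def detrend_linear(run: BoldRun) -> BoldRun:
    """Remove each voxel's least-squares line (intercept + slope)."""
    if run.n_volumes < 3:
        raise ValueError("linear detrending needs at least 3 time points")
    return BoldRun(run.grid, _detrend_array(run.data), run.tr_s)


def band_bin_indices(n: int, tr_s: float, band: Band) -> np.ndarray:
    """Indices of one-sided DFT bins whose frequency lies inside ``band``."""
    freqs = np.fft.rfftfreq(n, d=tr_s)
    return np.flatnonzero(
        (freqs >= band.f_lo_hz - _EDGE_TOL_HZ) & (freqs <= band.f_hi_hz + _EDGE_TOL_HZ)
    )


def bandpass(run: BoldRun, band: Band) -> BoldRun:
    """Ideal frequency-mask filter: keep DFT bins with f_lo <= f <= f_hi."""
    band.validate_for(run.nyquist_hz)
    n = run.n_volumes
    spectrum = np.fft.rfft(run.data, axis=-1)
    keep = np.zeros(spectrum.shape[-1], dtype=bool)
    keep[band_bin_indices(n, run.tr_s, band)] = True
    spectrum[..., ~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=n, axis=-1)
    return BoldRun(run.grid, filtered, run.tr_s)


def gaussian_smooth(volume: np.ndarray, grid: VolumeGrid, fwhm_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing of a 3D map.

    sigma per axis is ``fwhm / sqrt(8 ln 2)`` converted from mm to voxels.
    Boundary handling is reflective, which conserves the global sum (and
    hence the mean) of the map.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if volume.shape != grid.dims:
        raise ValueError(f"volume shape {volume.shape} does not match grid {grid.dims}")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = [fwhm_to_sigma_mm(fwhm_mm) / v for v in grid.voxel_size_mm]
    return ndimage.gaussian_filter(volume, sigma_vox, mode="reflect")


def smooth_run(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Apply :func:`gaussian_smooth` to every volume of a 4D run."""
    if fwhm_mm == 0:
        return BoldRun(run.grid, run.data.copy(), run.tr_s)
    sigma_vox = [fwhm_to_sigma_mm(fwhm_mm) / v for v in run.grid.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(run.data, sigma_vox + [0.0], mode="reflect")
    return BoldRun(run.grid, smoothed, run.tr_s)


def make_group_mask(
    gm_maps: Sequence[np.ndarray],
    grid: VolumeGrid,
    threshold: float = 0.15,
    strict: bool = True,
) -> BrainMask:
    """Gray-matter group mask: voxels where the cohort-mean GM map exceeds
    ``threshold`` (strict ``>`` by default)."""
    if len(gm_maps) == 0:
        raise ValueError("make_group_mask needs at least one GM map")
    stack = np.stack([np.asarray(m, dtype=float) for m in gm_maps])
    if stack.shape[1:] != grid.dims:
        raise ValueError(
            f"GM map shape {stack.shape[1:]} does not match grid {grid.dims}"
        )
    mean_map = stack.mean(axis=0)
    include = mean_map > threshold if strict else mean_map >= threshold
    mask = BrainMask(grid, include)
    if mask.n_voxels == 0:
        raise ValueError(
            f"group GM mask is empty at threshold {threshold}; "
            f"mean GM max is {mean_map.max():.4g}"
        )
    return mask
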