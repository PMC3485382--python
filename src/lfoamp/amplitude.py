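"""ALFF and fALFF amplitude maps.

ALFF (amplitude of low-frequency fluctuation) is the mean of the one-sided
discrete amplitude spectrum over the low-frequency band (0.01-0.08 Hz here);
it measures the absolute intensity of spontaneous BOLD fluctuations. fALFF
(fractional ALFF) is the sum of in-band amplitudes divided by the amplitude
sum over the whole measurable spectrum (0 to Nyquist, 0.25 Hz at TR = 2 s),
which normalizes away broadband physiological noise.

Amplitude convention: for an N-point series with unnormalized DFT X, the
amplitude at bin k > 0 is 2|X_k|/N and |X_0|/N at DC, so a unit sinusoid at
a bin frequency has amplitude 1. The absolute scale cancels after per-subject
standardization (division by the in-mask mean), which is what makes the group
statistics robust to this convention.

fALFF's denominator excludes the DC bin: DC is the series mean, not a
fluctuation. It can be re-included via ``include_dc=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Band, band_bin_indices
from .volume_io import BoldRun, BrainMask, VolumeGrid

__all__ = [
    "AmplitudeMap",
    "amplitude_spectrum",
    "compute_alff",
    "compute_falff",
    "standardize_map",
]


@dataclass
class AmplitudeMap:
    """Per-subject 3D ALFF or fALFF map with band metadata."""

    grid: VolumeGrid
    values: np.ndarray
    metric: str  # 'alff' | 'falff'
    band: Band
    full_band: Band | None = None  # falff only
    standardized: bool = False
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.dims}"
            )
        if self.metric not in ("alff", "falff"):
            raise ValueError(f"metric must be 'alff' or 'falff', got {self.metric!r}")


def amplitude_spectrum(
    series: np.ndarray, tr_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided discrete amplitude spectrum of a time series.

    Returns ``(frequencies_hz, amplitudes)`` with amplitude 2|X_k|/N for
    k > 0 and |X_0|/N at DC. Under this convention the amplitude is the
    square root of the (per-bin, sinusoid-calibrated) power.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("amplitude_spectrum expects a 1D series")
    n = series.shape[0]
    if n < 4:
        raise ValueError("amplitude_spectrum needs at least 4 time points")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    freqs = np.fft.rfftfreq(n, d=tr_s)
    amps = np.abs(np.fft.rfft(series)) / n
    amps[1:] *= 2.0
    return freqs, amps


def _amplitudes_4d(data: np.ndarray) -> np.ndarray:
    """One-sided amplitude spectra along the time axis of a 4D array."""
    n = data.shape[-1]
    amps = np.abs(np.fft.rfft(data, axis=-1)) / n
    amps[..., 1:] *= 2.0
    return amps


def compute_alff(run: BoldRun, band: Band = Band(0.01, 0.08)) -> AmplitudeMap:
    """Mean in-band amplitude per voxel.

    The run should already be detrended (and may be band-pass filtered with
    the same band; the ideal filter and the band average select the same DFT
    bins, so filtering does not change the result).
    """
    band.validate_for(run.nyquist_hz)
    bins = band_bin_indices(run.n_volumes, run.tr_s, band)
    if bins.size == 0:
        raise ValueError(
            f"band [{band.f_lo_hz}, {band.f_hi_hz}] Hz contains no DFT bin "
            f"for n={run.n_volumes}, TR={run.tr_s}s"
        )
    amps = _amplitudes_4d(run.data)
    values = amps[..., bins].mean(axis=-1)
    return AmplitudeMap(run.grid, values, "alff", band)


def compute_falff(
    run: BoldRun,
    band: Band = Band(0.01, 0.08),
    full_band: Band | None = None,
    include_dc: bool = False,
) -> AmplitudeMap:
    """Ratio of in-band amplitude sum to the full-spectrum amplitude sum.

    The run must be detrended but *not* band-pass filtered. ``full_band``
    defaults to (0, Nyquist), i.e. 0-0.25 Hz at TR = 2 s. The DC bin is
    excluded from the denominator unless ``include_dc`` is set. Voxels with
    a zero denominator get fALFF 0.
    """
    if full_band is None:
        full_band = Band(0.0, run.nyquist_hz)
    full_band.validate_for(run.nyquist_hz)
    if not full_band.contains(band):
        raise ValueError(
            f"numerator band [{band.f_lo_hz}, {band.f_hi_hz}] is not contained "
            f"in full band [{full_band.f_lo_hz}, {full_band.f_hi_hz}]"
        )
    n = run.n_volumes
    num_bins = band_bin_indices(n, run.tr_s, band)
    den_bins = band_bin_indices(n, run.tr_s, full_band)
    if not include_dc:
        den_bins = den_bins[den_bins > 0]
        num_bins = num_bins[num_bins > 0]
    if num_bins.size == 0 or den_bins.size == 0:
        raise ValueError("bands contain no DFT bins for this run")
    amps = _amplitudes_4d(run.data)
    num = amps[..., num_bins].sum(axis=-1)
    den = amps[..., den_bins].sum(axis=-1)
    values = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return AmplitudeMap(run.grid, values, "falff", band, full_band=full_band)


def standardize_map(amap: AmplitudeMap, mask: BrainMask) -> AmplitudeMap:
    """Divide by the map's own in-mask mean; zero outside the mask.

    After standardization the in-mask mean is exactly 1, making maps
    comparable across subjects regardless of the absolute amplitude scale.
    """
    if not amap.grid.matches(mask.grid):
        raise ValueError("amplitude map and mask are on different grids")
    mask.require_nonempty()
    mean = float(amap.values[mask.include].mean())
    if not np.isfinite(mean) or abs(mean) <= 1e-12:
        raise ValueError(
            f"in-mask mean {mean!r} too close to zero to standardize "
            f"(subject {amap.subject_id!r})"
        )
    values = np.zeros_like(amap.values)
    values[mask.include] = amap.values[mask.include] / mean
    return AmplitudeMap(
        amap.grid,
        values,
        amap.metric,
        amap.band,
        full_band=amap.full_band,
        standardized=True,
        subject_id=amap.subject_id,
    )
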