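"""Amplitude of low-frequency fluctuations (ALFF) and map normalization.

ALFF is the mean of the one-sided amplitude spectrum of the linearly
detrended voxel signal over a low-frequency band (default 0.01-0.08 Hz, the
band conventionally used by resting-state toolboxes).  Amplitudes are scaled
so that the sum of squared amplitudes over all bins equals the mean square
of the detrended signal (a Parseval identity), i.e. a_k = sqrt(2)|X_k|/T for
interior rfft bins.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import detrend

from .errors import BandError, DegenerateSignalError
from .io_core import BoldRun, ScalarMap


def amplitude_spectrum(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of detrended rows.

    Returns (freq_fraction, amplitudes); frequencies are cycles per sample
    and must be divided by TR for Hz.  sum(a**2, axis=1) equals the mean
    square of the detrended signal.
    """
    d = detrend(np.asarray(data, dtype=float), axis=-1, type="linear")
    T = d.shape[-1]
    spec = np.fft.rfft(d, axis=-1)
    amp = np.abs(spec) * (np.sqrt(2.0) / T)
    amp[..., 0] /= np.sqrt(2.0)
    if T % 2 == 0:
        amp[..., -1] /= np.sqrt(2.0)
    freqs = np.fft.rfftfreq(T)
    return freqs, amp


def compute_alff(run: BoldRun, band_hz: tuple[float, float] = (0.01, 0.08)) -> ScalarMap:
    """Mean in-band spectral amplitude per voxel."""
    low, high = float(band_hz[0]), float(band_hz[1])
    nyquist = 1.0 / (2.0 * run.tr_seconds)
    if not (0 <= low < high <= nyquist + 1e-12):
        raise BandError(
            f"band [{low}, {high}] Hz outside [0, Nyquist={nyquist:.4g}] Hz"
        )
    freqs, amp = amplitude_spectrum(run.data)
    freqs_hz = freqs / run.tr_seconds
    in_band = (freqs_hz >= low) & (freqs_hz <= high)
    if not in_band.any():
        raise BandError(
            f"no frequency bins in [{low}, {high}] Hz at T={run.n_timepoints}, "
            f"TR={run.tr_seconds}"
        )
    values = amp[:, in_band].mean(axis=1)
    return ScalarMap(
        values=values,
        mask=run.mask,
        name=f"alff_{low:g}-{high:g}Hz",
        units="a.u.",
    )


def normalize_map(scalar_map: ScalarMap, mode: str = "mean_divide") -> ScalarMap:
    """Normalize across gray-matter voxels.

    ``mean_divide`` divides by the across-voxel mean (the convention for
    normalized ALFF); ``zscore`` subtracts the mean and divides by the
    sample standard deviation (the convention for FCD maps).  Missing voxels
    stay missing and are excluded from the moments.
    """
    vals = scalar_map.values
    ok = ~np.isnan(vals)
    if ok.sum() < 2:
        raise DegenerateSignalError("need at least 2 non-missing voxels")
    v = vals[ok]
    out = np.full_like(vals, np.nan)
    if mode == "mean_divide":
        mean = v.mean()
        if np.isclose(mean, 0.0, atol=1e-300) or abs(mean) < 1e-12 * max(
            np.abs(v).max(), 1e-300
        ):
            raise DegenerateSignalError("across-voxel mean is zero")
        out[ok] = v / mean
    elif mode == "zscore":
        sd = v.std(ddof=1)
        if sd <= 1e-12 * max(np.abs(v - v.mean()).max(), 1e-300) or sd == 0:
            raise DegenerateSignalError("across-voxel standard deviation is zero")
        out[ok] = (v - v.mean()) / sd
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return ScalarMap(
        values=out,
        mask=scalar_map.mask,
        name=f"{scalar_map.name}_{mode}",
        units="" if mode == "zscore" else scalar_map.units,
    )
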