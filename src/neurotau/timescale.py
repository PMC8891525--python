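"""Intrinsic neural timescale estimation from the BOLD autocorrelation function.

Two definitions of the timescale tau are implemented:

``positive_sum``
    tau = TR * sum of ACF values over the initial run of strictly positive
    lags (lag 0 excluded).  For an AR(1) process with coefficient phi the
    population value is TR * phi / (1 - phi).  White noise maps to tau = 0.

``half_fwhm``
    Half of the full width at half maximum of the (symmetric) ACF: the lag at
    which the ACF first decays through 0.5, located by linear interpolation
    between the bracketing integer lags, times TR.  For AR(1) the population
    value is TR * ln 2 / ln(1/phi).  When the ACF never drops below 0.5
    within ``max_lag`` the estimate is right-censored at TR * max_lag.

The sample ACF uses the biased normalization (single global mean, divide by
the lag-0 sum of squares), which guarantees |r_k| <= 1 and is the common
neuroimaging convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateSignalError
from .io_core import BoldRun, ScalarMap

DEFAULT_MAX_LAG = 50


@dataclass(frozen=True)
class ACFProfile:
    """Sample autocorrelation r_k at lags 0..K with the sampling interval."""

    lags: np.ndarray
    values: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if lags.shape != values.shape or lags.size < 2:
            raise DataError("ACFProfile needs matching lags/values with K >= 1")
        if lags[0] != 0 or abs(values[0] - 1.0) > 1e-12:
            raise DataError("ACF must start at lag 0 with r_0 = 1")
        if np.any(np.abs(values) > 1 + 1e-9):
            raise DataError("|r_k| exceeds 1 beyond numerical slack")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class TimescaleResult:
    """A single-voxel timescale estimate.

    ``tau_seconds`` is NaN when the voxel is degenerate; ``censored`` marks a
    half-FWHM estimate that is only a lower bound (ACF never reached 0.5).
    """

    tau_seconds: float
    method: str
    n_positive_lags: int | None = None
    crossing_lag: float | None = None
    censored: bool = False


def _acf_from_demeaned(d: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample ACF of rows of ``d`` (already demeaned), lags 0..max_lag.

    FFT-based; identical (to ~1e-14) to the double-loop definition
    r_k = sum_t d_t d_{t+k} / sum_t d_t^2.
    """
    n_series, T = d.shape
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    f = np.fft.rfft(d, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, : max_lag + 1]
    denom = acov[:, :1].copy()
    return acov / denom


def sample_acf(series: np.ndarray, max_lag: int, tr_seconds: float = 1.0) -> ACFProfile:
    """Biased sample ACF without the minimum-length gate of :func:`estimate_acf`.

    Intended for short worked examples and oracle comparisons; BOLD analysis
    should go through :func:`estimate_acf`.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DataError("series must be 1D")
    T = x.size
    if max_lag < 1 or max_lag >= T:
        raise DataError(f"max_lag must be in [1, T-1], got {max_lag}")
    d = x - x.mean()
    ss = float(d @ d)
    scale = float(np.abs(x).max()) if T else 0.0
    if ss <= (1e-12 * max(scale, 1e-300)) ** 2 * T:
        raise DegenerateSignalError("zero-variance series")
    r = _acf_from_demeaned(d[None, :], max_lag)[0]
    r[0] = 1.0
    return ACFProfile(lags=np.arange(max_lag + 1), values=r, tr_seconds=tr_seconds)


def estimate_acf(series: np.ndarray, max_lag: int, tr_seconds: float) -> ACFProfile:
    """Sample ACF of one series: r_k = sum (x_t - xbar)(x_{t+k} - xbar) / sum (x_t - xbar)^2."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DataError("series must be 1D")
    T = x.size
    if T < 20:
        raise DataError(f"series too short: T={T} < 20")
    if max_lag < 1 or max_lag > T // 2:
        raise DataError(f"max_lag must be in [1, T/2], got {max_lag}")
    d = x - x.mean()
    ss = float(d @ d)
    # relative threshold: constant-up-to-rounding series are degenerate, but
    # arbitrarily small genuine amplitudes are not (scale invariance)
    scale = float(np.abs(x).max())
    if ss <= (1e-12 * max(scale, 1e-300)) ** 2 * T:
        raise DegenerateSignalError("zero-variance series")
    r = _acf_from_demeaned(d[None, :], max_lag)[0]
    r[0] = 1.0
    return ACFProfile(lags=np.arange(max_lag + 1), values=r, tr_seconds=tr_seconds)


def timescale_positive_sum(acf: ACFProfile) -> TimescaleResult:
    """tau = TR * sum of r_k over the initial strictly-positive run of lags >= 1."""
    r = acf.values[1:]
    nonpos = np.flatnonzero(r <= 0)
    m = int(nonpos[0]) if nonpos.size else r.size
    tau = float(acf.tr_seconds * r[:m].sum()) if m > 0 else 0.0
    return TimescaleResult(tau_seconds=tau, method="positive_sum", n_positive_lags=m)


def timescale_half_fwhm(acf: ACFProfile) -> TimescaleResult:
    """tau = TR * (interpolated lag where the ACF decays through 0.5)."""
    r = acf.values
    below = np.flatnonzero(r < 0.5)
    if below.size == 0:
        k_max = int(acf.lags[-1])
        return TimescaleResult(
            tau_seconds=float(acf.tr_seconds * k_max),
            method="half_fwhm",
            crossing_lag=float(k_max),
            censored=True,
        )
    k1 = int(below[0])  # first lag with r < 0.5; r[k1-1] >= 0.5 since r_0 = 1
    k0 = k1 - 1
    crossing = k0 + (r[k0] - 0.5) / (r[k0] - r[k1])
    return TimescaleResult(
        tau_seconds=float(acf.tr_seconds * crossing),
        method="half_fwhm",
        crossing_lag=float(crossing),
    )


def _positive_sum_vec(r: np.ndarray, tr: float) -> np.ndarray:
    """Vectorized positive-sum timescale over rows of an ACF matrix."""
    tail = r[:, 1:]
    nonpos = tail <= 0
    has_stop = nonpos.any(axis=1)
    m = np.where(has_stop, nonpos.argmax(axis=1), tail.shape[1])
    csum = np.concatenate(
        [np.zeros((tail.shape[0], 1)), np.cumsum(tail, axis=1)], axis=1
    )
    return tr * csum[np.arange(tail.shape[0]), m]


def _half_fwhm_vec(r: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized half-FWHM timescale; returns (tau, censored)."""
    below = r < 0.5
    has_cross = below.any(axis=1)
    k1 = np.where(has_cross, below.argmax(axis=1), r.shape[1] - 1)
    k0 = np.maximum(k1 - 1, 0)
    rows = np.arange(r.shape[0])
    r0, r1 = r[rows, k0], r[rows, k1]
    with np.errstate(divide="ignore", invalid="ignore"):
        crossing = k0 + (r0 - 0.5) / (r0 - r1)
    k_max = r.shape[1] - 1
    tau = np.where(has_cross, tr * crossing, tr * k_max)
    return tau, ~has_cross


def timescale_map(
    run: BoldRun, method: str = "positive_sum", max_lag: int | None = None
) -> ScalarMap:
    """Per-voxel timescale map; degenerate voxels are flagged missing (NaN)."""
    if method not in ("positive_sum", "half_fwhm"):
        raise DataError(f"unknown method {method!r}")
    T = run.n_timepoints
    if max_lag is None:
        max_lag = min(DEFAULT_MAX_LAG, T // 2)
    if max_lag < 1 or max_lag > T // 2:
        raise DataError(f"max_lag must be in [1, T/2], got {max_lag}")
    d = run.data - run.data.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", d, d)
    scale = np.abs(run.data).max(axis=1)
    ok = ss > (1e-12 * np.maximum(scale, 1e-300)) ** 2 * T
    if not ok.any():
        raise DegenerateSignalError("all voxels have zero variance")
    r = _acf_from_demeaned(d[ok], max_lag)
    r[:, 0] = 1.0
    tau_ok = (
        _positive_sum_vec(r, run.tr_seconds)
        if method == "positive_sum"
        else _half_fwhm_vec(r, run.tr_seconds)[0]
    )
    tau = np.full(run.mask.n_voxels, np.nan)
    tau[ok] = tau_ok
    return ScalarMap(
        values=tau,
        mask=run.mask,
        name=f"tau_{method}_maxlag{max_lag}",
        units="s",
    )
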