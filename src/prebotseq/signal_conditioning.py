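"""LFP integration/decimation and spatio-temporal movie filtering.

The raw electrode trace is full-wave rectified and smoothed with a
single-pole exponential integrator (time constant 100-200 ms, default
150 ms), then decimated to the imaging frame rate through a zero-phase
Chebyshev type-I order-8 anti-aliasing low-pass. The calcium movie is
band-pass filtered per pixel (0.025-1.5 Hz, third-order zero-phase
Butterworth) and spatially smoothed with an unweighted 3x3 mean. All
timing analysis downstream consumes these two conditioned signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io_formats import LfpTrace, Movie

__all__ = [
    "IntegratedLfp",
    "FilteredMovie",
    "integrate_lfp",
    "resample_to_frames",
    "filter_movie",
    "moving_median_detrend",
]


@dataclass
class IntegratedLfp:
    """Rectified-integrated LFP sampled at the movie frames."""

    values: np.ndarray
    frame_times: np.ndarray
    tau_s: float
    sd_detrended: float
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must align")
        if np.any(self.values < 0):
            raise ValueError("integrated LFP must be non-negative")
        if not 0.1 <= self.tau_s <= 0.2:
            warnings.warn(
                f"integrator time constant {self.tau_s} s outside the usual "
                "0.1-0.2 s range", stacklevel=2,
            )


@dataclass
class FilteredMovie:
    """Band-passed, spatially smoothed movie; per-pixel DC removed."""

    data: np.ndarray
    frame_times: np.ndarray
    band_hz: tuple[float, float]
    filter_order: int
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        resid = np.abs(self.data.mean(axis=0, dtype=np.float64)).max()
        scale = float(self.data.std(dtype=np.float64))
        if scale > 0 and resid > 1e-6 * scale:
            # DC leakage beyond what band-pass numerics should leave
            warnings.warn("filtered movie has nonzero per-pixel mean", stacklevel=2)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def integrate_lfp(lfp: LfpTrace, tau_s: float = 0.15) -> np.ndarray:
    """Full-wave rectify then single-pole exponential low-pass.

    Discretized exactly: y[n] = y[n-1] + a (|x[n]| - y[n-1]) with
    a = 1 - exp(-dt/tau), so a step of amplitude A rises as
    A (1 - exp(-t/tau)). Returns the full-rate non-negative trace.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if lfp.raw.size < 10 * tau_s * lfp.raw_rate_hz:
        raise ValueError("trace too short for the requested time constant")
    a = 1.0 - np.exp(-1.0 / (tau_s * lfp.raw_rate_hz))
    return signal.lfilter([a], [1.0, -(1.0 - a)], np.abs(lfp.raw))


def moving_median_detrend(values: np.ndarray, rate_hz: float,
                          window_s: float = 10.0) -> np.ndarray:
    """Subtract a moving-median baseline (default 10 s window).

    The moving median tracks slow drift while stepping over the brief
    bursts, so burst amplitudes survive detrending.
    """
    n = int(round(window_s * rate_hz))
    n = max(3, n | 1)  # odd window
    baseline = ndimage.median_filter(values, size=min(n, values.size | 1),
                                     mode="nearest")
    return values - baseline


def resample_to_frames(
    integrated: np.ndarray,
    lfp: LfpTrace,
    movie: Movie,
    detrend_window_s: float = 10.0,
    tau_s: float = 0.15,
) -> IntegratedLfp:
    """Decimate the full-rate integrated trace to the movie frames.

    Anti-aliasing uses a Chebyshev type-I order-8 low-pass with cutoff at
    0.8x the frame-rate Nyquist, applied forward-backward (zero phase);
    the numerator is rescaled to exact unit DC gain so a constant trace
    passes unchanged. Frame samples are linearly interpolated at the
    frame trigger times (uniform times when triggers are absent).
    """
    frame_times = (
        lfp.frame_trigger_times
        if lfp.frame_trigger_times is not None
        else movie.frame_times
    )
    if frame_times[0] < lfp.time[0] - 1e-9 or frame_times[-1] > lfp.time[-1] + 1e-9:
        raise ValueError("movie frame span outside the LFP trace span")
    cutoff = 0.8 * (movie.sampling_rate_hz / 2.0)
    # second-order sections: the ba form of an order-8 filter with cutoff
    # ~4e-4 of the sample rate is numerically singular
    sos = signal.cheby1(8, 0.05, cutoff, btype="low", fs=lfp.raw_rate_hz,
                        output="sos")
    dc = np.prod(np.sum(sos[:, :3], axis=1) / np.sum(sos[:, 3:], axis=1))
    sos[0, :3] /= dc  # exact unit DC gain
    padlen = min(integrated.size - 1, int(round(3 * lfp.raw_rate_hz / cutoff)))
    filtered = signal.sosfiltfilt(sos, integrated, padlen=padlen)
    values = np.interp(frame_times, lfp.time, filtered)
    values = np.clip(values, 0.0, None)
    detrended = moving_median_detrend(values, movie.sampling_rate_hz,
                                      detrend_window_s)
    return IntegratedLfp(
        values=values,
        frame_times=np.asarray(frame_times, dtype=float),
        tau_s=tau_s,
        sd_detrended=float(np.std(detrended)),
        sampling_rate_hz=movie.sampling_rate_hz,
    )


def _spatial_mean_3x3(frames: np.ndarray) -> np.ndarray:
    """Unweighted 3x3 spatial mean; the kernel shrinks at the borders."""
    summed = ndimage.uniform_filter(frames, size=(1, 3, 3), mode="constant") * 9.0
    ones = np.ones(frames.shape[1:], dtype=frames.dtype)
    counts = ndimage.uniform_filter(ones, size=3, mode="constant") * 9.0
    return summed / counts[None, :, :]


def filter_movie(
    movie: Movie,
    band_hz: tuple[float, float] = (0.025, 1.5),
    order: int = 3,
    chunk_pixels: int = 4096,
) -> FilteredMovie:
    """Temporal band-pass then 3x3 spatial smoothing.

    The temporal stage is a zero-phase (forward-backward) Butterworth
    band-pass applied per pixel with reflective padding of 6/low_cut
    seconds (several settle times of the slowest high-pass pole, so edge
    transients are negligible and the operator is time-reversal symmetric
    to float precision); a symmetric temporal pulse keeps its peak frame.
    Pixels are processed in chunks to bound the float64 working set.
    """
    lo, hi = band_hz
    fs = movie.sampling_rate_hz
    if not 0 < lo < hi < fs / 2:
        raise ValueError("band must lie inside (0, Nyquist)")
    t, h, w = movie.data.shape
    if t / fs <= 2.0 / lo:
        warnings.warn(
            "recording shorter than twice the low-cut period; low-frequency "
            "response will be unreliable", stacklevel=2,
        )
    sos = signal.butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    padlen = min(t - 1, int(round(6 * fs / lo)))
    flat = movie.data.reshape(t, h * w)
    out = np.empty_like(flat, dtype=np.float32)
    for start in range(0, h * w, chunk_pixels):
        sl = np.s_[:, start : start + chunk_pixels]
        out[sl] = signal.sosfiltfilt(
            sos, flat[sl].astype(np.float64), axis=0, padtype="even",
            padlen=padlen,
        ).astype(np.float32)
    data = _spatial_mean_3x3(out.reshape(t, h, w))
    # remove residual per-pixel DC left by finite-length filtering
    data -= data.mean(axis=0, keepdims=True, dtype=np.float64).astype(np.float32)
    return FilteredMovie(
        data=data,
        frame_times=movie.frame_times,
        band_hz=band_hz,
        filter_order=order,
        sampling_rate_hz=fs,
    )
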