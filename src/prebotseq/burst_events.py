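"""Burst-peak detection on the integrated LFP and sigh flagging.

A rhythmic burst is accepted when the detrended integrated LFP shows a
local maximum whose height and prominence both exceed 0.8x the SD of the
detrended signal; closely spaced peaks keep the larger. Occasional
sigh-like bursts (amplitude far above the median) are flagged and
excluded from sequence analysis but never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .signal_conditioning import IntegratedLfp, moving_median_detrend

__all__ = ["BurstEvent", "detect_bursts", "flag_sighs"]


@dataclass(frozen=True)
class BurstEvent:
    peak_frame: int
    peak_time_s: float
    amplitude: float
    is_sigh: bool = False
    accepted: bool = True


def detect_bursts(
    ilfp: IntegratedLfp,
    sd_factor: float = 0.8,
    min_interval_s: float = 1.0,
    detrend_window_s: float = 10.0,
) -> list[BurstEvent]:
    """Find burst peaks in the frame-aligned integrated LFP.

    The trace is detrended with a 10 s moving median; peaks must exceed
    ``sd_factor`` x SD of the detrended trace in both height and
    prominence. ``min_interval_s`` enforces spacing, keeping the larger
    of two merged peaks. Amplitudes are detrended values at the peak.
    """
    duration = ilfp.frame_times[-1] - ilfp.frame_times[0]
    if duration < 30.0:
        raise ValueError("recording shorter than 30 s")
    detrended = moving_median_detrend(
        ilfp.values, ilfp.sampling_rate_hz, detrend_window_s
    )
    sd = float(np.std(detrended))
    if sd == 0:
        return []
    distance = max(1, int(round(min_interval_s * ilfp.sampling_rate_hz)))
    peaks, props = signal.find_peaks(
        detrended,
        height=sd_factor * sd,
        prominence=sd_factor * sd,
        distance=distance,
    )
    return [
        BurstEvent(
            peak_frame=int(p),
            peak_time_s=float(ilfp.frame_times[p]),
            amplitude=float(detrended[p]),
        )
        for p in peaks
    ]


def flag_sighs(events: list[BurstEvent], sigh_factor: float = 2.0) -> list[BurstEvent]:
    """Mark amplitude outliers (> sigh_factor x median) as sighs.

    Sigh events keep their record but become ``accepted=False``. With
    fewer than 3 events the median is unstable and nothing is flagged.
    """
    if len(events) < 3:
        warnings.warn("fewer than 3 bursts; sigh flagging skipped", stacklevel=2)
        return list(events)
    med = float(np.median([e.amplitude for e in events]))
    out = []
    for e in events:
        if e.amplitude > sigh_factor * med:
            out.append(replace(e, is_sigh=True, accepted=False))
        else:
            out.append(e)
    return out
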