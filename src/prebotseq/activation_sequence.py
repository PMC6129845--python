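"""Per-cycle activation detection, ordering and percent ranks.

An activation is a cell's fluorescence peak inside a +/-24-frame window
around an accepted LFP burst peak, provided the peak rises above a robust
(MAD-based) estimate of that cell's inter-burst noise. Its timing is the
peak time minus the LFP peak time (negative = the cell leads the
population burst). Cycles in which fewer than half of the classified
inspiratory cells activate are excluded; within an included cycle, cells
are sorted by timing and their positions rescaled to percent ranks in
(0, 100] so cycles with different numbers of active cells are comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .burst_events import BurstEvent

__all__ = [
    "Activation",
    "CycleRecord",
    "interburst_noise",
    "detect_activation",
    "detect_all_activations",
    "build_cycles",
    "timing_cumulative",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Activation:
    cell_id: int
    burst_id: int
    peak_frame: int
    timing_s: float
    peak_amplitude: float


@dataclass
class CycleRecord:
    burst_id: int
    included: bool
    order: list[int]
    percent_ranks: list[float]

    def __post_init__(self) -> None:
        if self.included:
            if len(self.percent_ranks) != len(self.order):
                raise ValueError("one percent rank per ordered cell")
            if self.percent_ranks and not (
                0 < min(self.percent_ranks)
                and max(self.percent_ranks) <= 100.0
                and np.all(np.diff(self.percent_ranks) >= 0)
            ):
                raise ValueError("percent ranks must be nondecreasing in (0, 100]")


def interburst_noise(
    trace: np.ndarray, bursts: list[BurstEvent], window_frames: int = 24
) -> float:
    """Robust noise SD of a cell's trace away from every detected burst.

    Uses 1.4826 x MAD of samples farther than ``window_frames`` from all
    burst peaks — including rejected (sigh) bursts, whose large calcium
    transients would otherwise contaminate the noise sample; falls back to
    the whole trace if no sample qualifies (warned, happens only for
    pathological burst densities).
    """
    n = trace.size
    mask = np.ones(n, dtype=bool)
    for b in bursts:
        lo = max(0, b.peak_frame - window_frames)
        hi = min(n, b.peak_frame + window_frames + 1)
        mask[lo:hi] = False
    sample = trace[mask]
    if sample.size < 10:
        warnings.warn(
            "almost no inter-burst frames; noise estimated from full trace",
            stacklevel=2,
        )
        sample = trace
    med = np.median(sample)
    return float(1.4826 * np.median(np.abs(sample - med)))


def detect_activation(
    trace: np.ndarray,
    burst: BurstEvent,
    sampling_rate_hz: float,
    noise_sigma: float,
    cell_id: int = -1,
    burst_id: int = -1,
    window_frames: int = 24,
    noise_k: float = 3.0,
) -> Activation | None:
    """Largest local trace maximum within the burst window, if above noise.

    Windows clipped by the recording edge are truncated with a warning.
    Returns None when no local maximum exceeds ``noise_k * noise_sigma``.
    """
    n = trace.size
    lo = burst.peak_frame - window_frames
    hi = burst.peak_frame + window_frames + 1
    if lo < 0 or hi > n:
        warnings.warn("activation window truncated at recording edge", stacklevel=2)
        lo, hi = max(0, lo), min(n, hi)
    seg = trace[lo:hi]
    if seg.size < 3:
        return None
    interior = seg[1:-1]
    is_max = (interior > seg[:-2]) & (interior >= seg[2:])
    idx = np.flatnonzero(is_max)
    if idx.size == 0:
        return None
    best = idx[np.argmax(interior[idx])] + 1
    amp = float(seg[best])
    if amp <= noise_k * noise_sigma:
        return None
    frame = lo + int(best)
    return Activation(
        cell_id=cell_id,
        burst_id=burst_id,
        peak_frame=frame,
        timing_s=(frame - burst.peak_frame) / sampling_rate_hz,
        peak_amplitude=amp,
    )


def detect_all_activations(
    traces: dict[int, np.ndarray],
    bursts: list[BurstEvent],
    sampling_rate_hz: float,
    window_frames: int = 24,
    noise_k: float = 3.0,
) -> list[Activation]:
    """Run activation detection for every (cell, accepted burst) pair."""
    out: list[Activation] = []
    for cell_id, trace in traces.items():
        sigma = interburst_noise(trace, bursts, window_frames)
        for burst_id, burst in enumerate(bursts):
            if not burst.accepted:
                continue
            act = detect_activation(
                trace, burst, sampling_rate_hz, sigma,
                cell_id=cell_id, burst_id=burst_id,
                window_frames=window_frames, noise_k=noise_k,
            )
            if act is not None:
                out.append(act)
    return out


def build_cycles(
    activations: list[Activation],
    n_inspiratory_cells: int,
    bursts: list[BurstEvent],
    inclusion: float = 0.5,
) -> list[CycleRecord]:
    """Assemble per-cycle activation orders with the 50% inclusion rule.

    A cycle is included iff the number of activated cells reaches
    ``inclusion`` x ``n_inspiratory_cells`` (the classified five-type
    cells in the slice). Within a cycle cells sort by timing, ties by
    cell id (logged); position i of N maps to percent rank 100*i/N.
    """
    if not any(b.accepted for b in bursts):
        raise ValueError("no accepted bursts")
    by_burst: dict[int, list[Activation]] = {}
    for a in activations:
        by_burst.setdefault(a.burst_id, []).append(a)
    cycles = []
    n_ties = 0
    for burst_id, burst in enumerate(bursts):
        if not burst.accepted:
            continue
        acts = by_burst.get(burst_id, [])
        included = len(acts) >= inclusion * n_inspiratory_cells and len(acts) > 0
        if not included:
            cycles.append(CycleRecord(burst_id, False, [], []))
            continue
        acts_sorted = sorted(acts, key=lambda a: (a.timing_s, a.cell_id))
        timings = [a.timing_s for a in acts_sorted]
        n_ties += sum(1 for i in range(1, len(timings)) if timings[i] == timings[i - 1])
        n = len(acts_sorted)
        cycles.append(
            CycleRecord(
                burst_id,
                True,
                [a.cell_id for a in acts_sorted],
                [100.0 * (i + 1) / n for i in range(n)],
            )
        )
    if n_ties:
        log.info("%d timing ties broken by cell id", n_ties)
    return cycles


def timing_cumulative(
    timings_by_type: dict[str, np.ndarray], grid: np.ndarray
) -> dict[str, np.ndarray]:
    """Empirical CDF of activation timing per cell type on a common grid."""
    out = {}
    for ctype, timings in timings_by_type.items():
        t = np.sort(np.asarray(timings, dtype=float))
        if t.size == 0:
            warnings.warn(f"no activations for type {ctype!r}; curve omitted",
                          stacklevel=2)
            continue
        out[ctype] = np.searchsorted(t, grid, side="right") / t.size
    return out
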