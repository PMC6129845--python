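"""Pixelwise lagged correlation with the integrated LFP and ROI placement.

The detection statistic is maxCC: the maximum over a bounded lag range
(0-40 frames, positive lag = fluorescence delayed relative to the LFP) of
the Pearson correlation between a pixel's band-passed fluorescence and the
integrated LFP. Pixels above a preset threshold (default 0.2) are grouped
into connected components; each component contributes one 7x7 ROI centred
on its maxCC peak, and overlapping candidates are resolved greedily in
favour of the higher maxCC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .signal_conditioning import FilteredMovie, IntegratedLfp

__all__ = [
    "CorrelationMap",
    "FunctionalRoi",
    "normalized_xcorr_max",
    "correlation_image",
    "detect_rois",
    "roi_trace",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationMap:
    """Per-pixel maxCC and its argmax lag."""

    maxcc: np.ndarray
    best_lag_frames: np.ndarray
    lag_range: tuple[int, int]

    def __post_init__(self) -> None:
        if np.any(np.abs(self.maxcc) > 1.0 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")
        lo, hi = self.lag_range
        if np.any((self.best_lag_frames < lo) | (self.best_lag_frames > hi)):
            raise ValueError("best lag outside the searched range")


@dataclass
class FunctionalRoi:
    """A 7x7 window on a putative inspiratory cell."""

    id: int
    center: tuple[int, int]
    half: int
    trace: np.ndarray
    maxcc: float
    best_lag_frames: int

    @property
    def window(self) -> tuple[slice, slice]:
        r, c = self.center
        return (slice(r - self.half, r + self.half + 1),
                slice(c - self.half, c + self.half + 1))


def normalized_xcorr_max(
    x: np.ndarray, y: np.ndarray, lag_range: tuple[int, int] = (0, 40)
) -> tuple[float, int]:
    """Maximum lagged Pearson correlation of ``y`` (fluorescence) vs ``x`` (LFP).

    For each lag L in ``lag_range`` the correlation is computed between
    ``y[L:]`` and ``x[:N-L]`` over the overlap, so positive lags mean the
    fluorescence trails the LFP. Ties resolve to the smallest lag; a
    zero-variance overlap contributes correlation 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    lo, hi = lag_range
    n = x.size
    if n <= hi + 10:
        raise ValueError("series too short for the requested lag range")
    best_cc, best_lag = -np.inf, lo
    for lag in range(lo, hi + 1):
        ys = y[lag:]
        xs = x[: n - lag] if lag > 0 else x
        xs_c = xs - xs.mean()
        ys_c = ys - ys.mean()
        denom = np.linalg.norm(xs_c) * np.linalg.norm(ys_c)
        if denom == 0:
            log.debug("zero-variance overlap at lag %d; correlation set to 0", lag)
            cc = 0.0
        else:
            cc = float(xs_c @ ys_c / denom)
        if cc > best_cc:
            best_cc, best_lag = cc, lag
    return best_cc, best_lag


def correlation_image(
    fm: FilteredMovie, ilfp: IntegratedLfp, lag_range: tuple[int, int] = (0, 40)
) -> CorrelationMap:
    """maxCC image: `normalized_xcorr_max` applied to every pixel.

    Vectorized per lag across all pixels; results are identical to the
    scalar routine (tests enforce this).
    """
    t, h, w = fm.data.shape
    if ilfp.values.size != t:
        raise ValueError("movie and integrated LFP length mismatch")
    lo, hi = lag_range
    n_lags = hi - lo + 1
    x = ilfp.values.astype(np.float64)
    # lagged LFP windows as one matrix: row L holds x shifted right by L,
    # so xmat @ y gives every S_xy(L) = sum_s x[s-L] y[s] in one matmul
    xmat = np.zeros((n_lags, t))
    for i, lag in enumerate(range(lo, hi + 1)):
        xmat[i, lag:] = x[: t - lag]
    csx = np.cumsum(x)
    csxx = np.cumsum(x * x)
    lens = t - np.arange(lo, hi + 1, dtype=float)
    sx = csx[(t - np.arange(lo, hi + 1)) - 1]
    sxx = csxx[(t - np.arange(lo, hi + 1)) - 1]
    var_x = sxx - sx * sx / lens

    n_pix = h * w
    best = np.full(n_pix, -np.inf)
    best_lag = np.full(n_pix, lo, dtype=int)
    flat32 = fm.data.reshape(t, n_pix)
    chunk = 4096
    for start in range(0, n_pix, chunk):
        y = flat32[:, start : start + chunk].astype(np.float64)
        csy = np.vstack([np.zeros((1, y.shape[1])), np.cumsum(y, axis=0)])
        csyy = np.vstack([np.zeros((1, y.shape[1])), np.cumsum(y * y, axis=0)])
        tot_y, tot_yy = csy[-1], csyy[-1]
        sxy = xmat @ y
        sy = tot_y[None, :] - csy[np.arange(lo, hi + 1)]
        syy = tot_yy[None, :] - csyy[np.arange(lo, hi + 1)]
        var_y = syy - sy * sy / lens[:, None]
        cov = sxy - sx[:, None] * sy / lens[:, None]
        denom2 = var_x[:, None] * var_y
        cc = np.where(denom2 > 0, cov / np.sqrt(np.maximum(denom2, 1e-300)), 0.0)
        np.clip(cc, -1.0, 1.0, out=cc)
        best[start : start + chunk] = cc.max(axis=0)
        best_lag[start : start + chunk] = lo + cc.argmax(axis=0)
    return CorrelationMap(
        maxcc=best.reshape(h, w),
        best_lag_frames=best_lag.reshape(h, w),
        lag_range=lag_range,
    )


def roi_trace(fm: FilteredMovie, center: tuple[int, int], half: int = 3) -> np.ndarray:
    """Per-frame unweighted mean of the (2*half+1)^2 window."""
    r, c = center
    return fm.data[:, r - half : r + half + 1, c - half : c + half + 1].mean(
        axis=(1, 2)
    )


def detect_rois(
    cmap: CorrelationMap,
    fm: FilteredMovie,
    threshold: float = 0.2,
    half: int = 3,
    min_area: int = 9,
) -> list[FunctionalRoi]:
    """Place non-overlapping 7x7 ROIs on suprathreshold correlation blobs.

    Connected components (8-connectivity) of maxcc > threshold with area
    >= ``min_area`` become candidates centred on their peak pixel;
    candidates whose window would clip the border are shifted inward by up
    to ``half`` pixels, else rejected. Candidates are accepted greedily by
    descending maxcc, rejecting any centre within Chebyshev distance
    < 2*half+1 of an accepted one.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    h, w = cmap.maxcc.shape
    labels = measure.label(cmap.maxcc > threshold, connectivity=2)
    candidates: list[tuple[float, tuple[int, int], int]] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        coords = region.coords
        vals = cmap.maxcc[coords[:, 0], coords[:, 1]]
        r, c = coords[np.argmax(vals)]
        r = int(np.clip(r, half, h - 1 - half))
        c = int(np.clip(c, half, w - 1 - half))
        peak = coords[np.argmax(vals)]
        if max(abs(r - peak[0]), abs(c - peak[1])) > half:
            log.info("component at %s rejected: cannot fit 7x7 window", tuple(peak))
            continue
        candidates.append((float(cmap.maxcc[r, c]), (r, c),
                           int(cmap.best_lag_frames[r, c])))
    candidates.sort(key=lambda item: (-item[0], item[1]))
    accepted: list[FunctionalRoi] = []
    side = 2 * half + 1
    for maxcc, (r, c), lag in candidates:
        if any(
            max(abs(r - roi.center[0]), abs(c - roi.center[1])) < side
            for roi in accepted
        ):
            continue
        accepted.append(
            FunctionalRoi(
                id=len(accepted),
                center=(r, c),
                half=half,
                trace=roi_trace(fm, (r, c), half),
                maxcc=maxcc,
                best_lag_frames=lag,
            )
        )
    return accepted
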