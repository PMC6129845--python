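"""Raw-data containers and file I/O.

Movies travel as multi-page TIFF with a JSON sidecar (pixel size, frame
rate, optional per-frame times); electrode traces and all result tables are
plain CSV. All times are seconds with origin at the first LFP sample;
image coordinates are 0-based (row, col) pixel indices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Movie",
    "SpectralStack",
    "LfpTrace",
    "read_movie",
    "write_movie",
    "read_lfp_csv",
    "write_lfp_csv",
    "read_spectral_stack",
    "write_spectral_stack",
    "write_results_tables",
]


@dataclass
class Movie:
    """A single-channel fluorescence movie.

    Parameters
    ----------
    data:
        Non-negative intensity, shape ``(frames, height, width)``.
    frame_times:
        Acquisition time of each frame in seconds, strictly increasing.
    pixel_size_um:
        Micrometres per pixel (square pixels assumed).
    sampling_rate_hz:
        Nominal frame rate; the median frame spacing must agree with it
        to within 10%.
    """

    data: np.ndarray
    frame_times: np.ndarray
    pixel_size_um: float
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie data must be frames x height x width")
        if self.data.shape[0] < 2:
            raise ValueError("frames >= 2 required")
        if self.frame_times.shape != (self.data.shape[0],):
            raise ValueError("frame_times length must equal frame count")
        dt = np.diff(self.frame_times)
        if np.any(dt <= 0):
            raise ValueError("frame_times must be strictly increasing")
        nominal = 1.0 / self.sampling_rate_hz
        med = float(np.median(dt))
        if abs(med - nominal) >= 0.1 * nominal:
            raise ValueError(
                f"median frame spacing {med:.4f}s inconsistent with nominal "
                f"rate {self.sampling_rate_hz:.3f} Hz"
            )
        if np.any(dt > 2.0 * med):
            warnings.warn(
                "irregular frame timing: at least one inter-frame gap "
                "exceeds twice the median spacing",
                stacklevel=2,
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SpectralStack:
    """Multispectral reference stack: excitations x emission bands x H x W."""

    data: np.ndarray
    excitation_nm: list[float]
    emission_band_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("stack must be n_ex x n_em x height x width")
        n_ex, n_em = self.data.shape[:2]
        if len(self.excitation_nm) != n_ex:
            raise ValueError("excitation_nm length mismatch")
        if len(self.emission_band_labels) != n_em:
            raise ValueError("emission_band_labels length mismatch")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def as_channel_matrix(self) -> np.ndarray:
        """Flatten to (channels, pixels), channel = (excitation, emission)."""
        n_ex, n_em, h, w = self.data.shape
        return self.data.reshape(n_ex * n_em, h * w)


@dataclass
class LfpTrace:
    """Raw local-field-potential trace plus optional frame triggers."""

    raw: np.ndarray
    raw_rate_hz: float
    frame_trigger_times: np.ndarray | None = None
    time: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 1:
            raise ValueError("raw trace must be one-dimensional")
        if self.raw.size < 1000:
            raise ValueError("LFP trace shorter than 1000 samples")
        self.time = np.arange(self.raw.size) / self.raw_rate_hz
        if self.frame_trigger_times is not None:
            t = np.asarray(self.frame_trigger_times, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("frame_trigger_times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.time[-1]:
                raise ValueError("frame_trigger_times outside the trace span")
            self.frame_trigger_times = t

    @property
    def duration_s(self) -> float:
        return self.raw.size / self.raw_rate_hz


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a Movie as multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.data, dtype=np.float32),
                     photometric="minisblack")
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "sampling_rate_hz": movie.sampling_rate_hz,
        "frame_times": movie.frame_times.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_movie(path: str | Path) -> Movie:
    """Read a multi-page TIFF movie and its JSON sidecar.

    The sidecar must provide ``pixel_size_um`` and ``sampling_rate_hz``;
    ``frame_times`` is optional (uniform times from 0 are assumed when
    absent, matching the trigger-free convention).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("pixel_size_um", "sampling_rate_hz"):
        if key not in meta:
            raise ValueError(f"sidecar missing required key {key!r}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] < 2:
        raise ValueError("frames >= 2 required")
    if "frame_times" in meta and meta["frame_times"] is not None:
        frame_times = np.asarray(meta["frame_times"], dtype=float)
    else:
        frame_times = np.arange(data.shape[0]) / meta["sampling_rate_hz"]
    return Movie(
        data=data,
        frame_times=frame_times,
        pixel_size_um=float(meta["pixel_size_um"]),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
    )


def write_spectral_stack(stack: SpectralStack, path: str | Path) -> Path:
    path = Path(path)
    n_ex, n_em, h, w = stack.data.shape
    tifffile.imwrite(
        path,
        np.asarray(stack.data, dtype=np.float32).reshape(n_ex * n_em, h, w),
        photometric="minisblack",
    )
    meta = {
        "n_excitations": n_ex,
        "n_emissions": n_em,
        "excitation_nm": list(stack.excitation_nm),
        "emission_band_labels": list(stack.emission_band_labels),
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_spectral_stack(path: str | Path) -> SpectralStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    flat = tifffile.imread(path)
    n_ex, n_em = meta["n_excitations"], meta["n_emissions"]
    data = flat.reshape(n_ex, n_em, *flat.shape[1:])
    return SpectralStack(
        data=data,
        excitation_nm=meta["excitation_nm"],
        emission_band_labels=meta["emission_band_labels"],
    )


def write_lfp_csv(lfp: LfpTrace, path: str | Path) -> Path:
    """Write (time_s, value[, trigger]) CSV; triggers become a 0/1 edge column."""
    path = Path(path)
    df = pd.DataFrame({"time_s": lfp.time, "value": lfp.raw})
    if lfp.frame_trigger_times is not None:
        trig = np.zeros(lfp.raw.size, dtype=int)
        idx = np.searchsorted(lfp.time, lfp.frame_trigger_times)
        trig[np.clip(idx, 0, lfp.raw.size - 1)] = 1
        df["trigger"] = trig
    df.to_csv(path, index=False)
    return path


def read_lfp_csv(path: str | Path) -> LfpTrace:
    """Read a two-column (time_s, value) CSV, optional 0/1 ``trigger`` column.

    The sampling rate is inferred as 1/median(diff(time)); rising edges of
    the trigger column give the frame times.
    """
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError("CSV must have columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 1000:
        raise ValueError("LFP trace shorter than 1000 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotonic time column")
    rate = 1.0 / float(np.median(np.diff(t)))
    triggers = None
    if "trigger" in df.columns:
        trig = df["trigger"].to_numpy()
        edges = np.flatnonzero((trig[1:] > 0.5) & (trig[:-1] <= 0.5)) + 1
        if trig[0] > 0.5:
            edges = np.concatenate([[0], edges])
        if edges.size:
            triggers = t[edges] - t[0]
    return LfpTrace(raw=df["value"].to_numpy(dtype=float), raw_rate_hz=rate,
                    frame_trigger_times=triggers)


def write_results_tables(
    cells: pd.DataFrame,
    activations: pd.DataFrame,
    composition: pd.DataFrame,
    out_dir: str | Path,
    stats: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the per-cell, per-activation, composition and stats CSV tables.

    ``composition`` is written exactly as built by
    :func:`prebotseq.cell_typing.composition_table` (counts row plus
    percentage row per slice, then a Total pair).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out_dir / "cells.csv",
        "activations": out_dir / "activations.csv",
        "composition": out_dir / "composition.csv",
    }
    cells.to_csv(paths["cells"], index=False)
    activations.to_csv(paths["activations"], index=False)
    composition.to_csv(paths["composition"], index=False)
    if stats is not None:
        paths["stats"] = out_dir / "tests.csv"
        stats.to_csv(paths["stats"], index=False)
    return paths
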