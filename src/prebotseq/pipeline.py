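"""End-to-end orchestration: simulate/load -> unmix -> condition -> ROIs ->
typing -> bursts -> sequence -> statistics.

A run is driven by a single validated config (YAML on disk, dataclass in
memory); every stage writes its artifacts into the run directory together
with a serialized copy of the config, so a run can be audited and
re-executed bit-identically for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation_sequence import build_cycles, detect_all_activations
from .burst_events import BurstEvent, detect_bursts, flag_sighs
from .cell_typing import (
    FIVE_TYPES,
    assign_cell_type,
    classify_regularity,
    composition_table,
    suggest_cutoff,
)
from .functional_roi import FunctionalRoi, correlation_image, detect_rois
from .group_stats import SliceData, anova_tukey, summarize, three_family_tests
from .io_formats import (
    LfpTrace,
    Movie,
    SpectralStack,
    read_lfp_csv,
    read_movie,
    read_spectral_stack,
    write_results_tables,
)
from .signal_conditioning import filter_movie, integrate_lfp, resample_to_frames
from .spectral_unmixing import fluorophore_flags, unmix
from .synthetic_data import default_paper_like_config, generate_recording

__all__ = ["PipelineConfig", "SliceSpec", "SliceResult", "run_pipeline", "run_slice"]

log = logging.getLogger(__name__)


@dataclass
class SliceSpec:
    """One slice: either simulated from a seed or loaded from files."""

    label: str
    seed: int | None = None
    movie_path: str | None = None
    lfp_path: str | None = None
    stack_path: str | None = None

    def validate(self) -> None:
        if self.seed is None and not (self.movie_path and self.lfp_path):
            raise ValueError(
                f"slice {self.label!r}: provide a seed (simulate) or input paths"
            )


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, with the published defaults."""

    slices: list[SliceSpec] = field(default_factory=list)
    band_hz: tuple[float, float] = (0.025, 1.5)
    filter_order: int = 3
    tau_s: float = 0.15
    lag_range: tuple[int, int] = (0, 40)
    maxcc_threshold: float = 0.2
    cutoff: float | None = None          # None -> data-driven per slice
    sd_factor: float = 0.8
    min_interval_s: float = 1.0
    sigh_factor: float = 2.0
    window_frames: int = 24
    inclusion: float = 0.5
    noise_k: float = 3.0
    bin_percent: int = 10
    seed: int = 1
    make_figures: bool = True
    #: overrides applied to the default synthetic config when simulating
    #: (e.g. {"n_bursts": 40, "frame_shape": [64, 64]})
    synth: dict | None = None

    def validate(self) -> None:
        if not 0 < self.maxcc_threshold < 1:
            raise ValueError("maxcc_threshold must be in (0, 1)")
        if self.cutoff is not None and not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")
        if not 0 < self.inclusion <= 1:
            raise ValueError("inclusion must be in (0, 1]")
        if self.sd_factor <= 0 or self.sigh_factor <= 0 or self.noise_k <= 0:
            raise ValueError("sd_factor, sigh_factor, noise_k must be positive")
        if self.window_frames < 1:
            raise ValueError("window_frames must be >= 1")
        lo, hi = self.lag_range
        if not 0 <= lo < hi:
            raise ValueError("lag_range must be 0 <= lo < hi")
        if not self.slices:
            raise ValueError("at least one slice required")
        for s in self.slices:
            s.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        slices = [SliceSpec(**s) for s in raw.pop("slices", [])]
        for key in ("band_hz", "lag_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(slices=slices, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["lag_range"] = list(self.lag_range)
        return d


@dataclass
class SliceResult:
    """Everything one slice contributes to group statistics."""

    label: str
    cells: pd.DataFrame
    activations: pd.DataFrame
    cycles: list
    bursts: list[BurstEvent]
    rois: list[FunctionalRoi]
    cutoff: float
    truth: object | None = None

    def as_slice_data(self) -> SliceData:
        classified = self.cells[self.cells.cell_type.isin(FIVE_TYPES)]
        return SliceData(
            label=self.label,
            cell_types=dict(zip(classified.cell_id, classified.cell_type)),
            activations=self.activations,
            cycles=self.cycles,
        )


def _synth_config(cfg: PipelineConfig, seed: int):
    base = default_paper_like_config(seed=seed)
    if not cfg.synth:
        return base
    overrides = dict(cfg.synth)
    for key in ("burst_interval_s", "frame_shape"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    for key in ("timing_offset_ms", "amp"):
        if key in overrides:
            overrides[key] = {k: tuple(v) for k, v in overrides[key].items()}
    return dataclasses.replace(base, **overrides)


def _load_inputs(
    cfg: PipelineConfig, spec: SliceSpec
) -> tuple[Movie, SpectralStack | None, LfpTrace, object | None]:
    if spec.seed is not None:
        return generate_recording(_synth_config(cfg, spec.seed))
    movie = read_movie(spec.movie_path)
    lfp = read_lfp_csv(spec.lfp_path)
    stack = read_spectral_stack(spec.stack_path) if spec.stack_path else None
    return movie, stack, lfp, None


def run_slice(cfg: PipelineConfig, spec: SliceSpec) -> SliceResult:
    """Run the full single-slice analysis and return its products."""
    movie, stack, lfp, truth = _load_inputs(cfg, spec)
    log.info("[%s] %d frames, %.0f s", spec.label, movie.n_frames,
             movie.frame_times[-1])

    integrated = integrate_lfp(lfp, tau_s=cfg.tau_s)
    ilfp = resample_to_frames(integrated, lfp, movie, tau_s=cfg.tau_s)
    fm = filter_movie(movie, band_hz=cfg.band_hz, order=cfg.filter_order)

    cmap = correlation_image(fm, ilfp, lag_range=cfg.lag_range)
    rois = detect_rois(cmap, fm, threshold=cfg.maxcc_threshold)
    log.info("[%s] %d ROIs above maxCC %.2f", spec.label, len(rois),
             cfg.maxcc_threshold)

    unmixed = unmix(stack, seed=cfg.seed) if stack is not None else None
    centers = np.array([r.center for r in rois]) if rois else np.zeros((0, 2), int)

    maxccs = np.array([r.maxcc for r in rois])
    cutoff = cfg.cutoff if cfg.cutoff is not None else suggest_cutoff(maxccs)

    rows = []
    for roi in rois:
        if unmixed is not None:
            glyt2, gad65 = fluorophore_flags(
                unmixed, roi.center, roi.half, all_centers=centers
            )
        else:
            glyt2 = gad65 = False
        reg = classify_regularity(roi.maxcc, cutoff)
        ctype = assign_cell_type(glyt2, gad65, reg)
        rows.append(
            {
                "cell_id": roi.id,
                "row": roi.center[0],
                "col": roi.center[1],
                "maxcc": roi.maxcc,
                "best_lag_frames": roi.best_lag_frames,
                "glyt2": glyt2,
                "gad65": gad65,
                "regularity": reg,
                "cell_type": ctype,
                "cutoff": cutoff,
            }
        )
    cells = pd.DataFrame(
        rows,
        columns=["cell_id", "row", "col", "maxcc", "best_lag_frames", "glyt2",
                 "gad65", "regularity", "cell_type", "cutoff"],
    )

    bursts = flag_sighs(
        detect_bursts(ilfp, sd_factor=cfg.sd_factor,
                      min_interval_s=cfg.min_interval_s),
        sigh_factor=cfg.sigh_factor,
    )
    traces = {roi.id: roi.trace for roi in rois}
    activations = detect_all_activations(
        traces, bursts, movie.sampling_rate_hz,
        window_frames=cfg.window_frames, noise_k=cfg.noise_k,
    )
    act_df = pd.DataFrame(
        [
            {
                "cell_id": a.cell_id,
                "burst_id": a.burst_id,
                "peak_frame": a.peak_frame,
                "timing_s": a.timing_s,
                "amplitude": a.peak_amplitude,
            }
            for a in activations
        ],
        columns=["cell_id", "burst_id", "peak_frame", "timing_s", "amplitude"],
    )
    n_classified = int(cells.cell_type.isin(FIVE_TYPES).sum())
    cycles = build_cycles(activations, n_classified, bursts,
                          inclusion=cfg.inclusion)
    return SliceResult(
        label=spec.label,
        cells=cells,
        activations=act_df,
        cycles=cycles,
        bursts=bursts,
        rois=rois,
        cutoff=cutoff,
        truth=truth,
    )


def _cycles_frame(label: str, cycles) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "slice": label,
                "burst_id": c.burst_id,
                "included": c.included,
                "order": "|".join(str(i) for i in c.order),
                "percent_ranks": "|".join(f"{r:.4f}" for r in c.percent_ranks),
            }
            for c in cycles
        ]
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage for every slice and the cross-slice statistics.

    Writes per-slice CSV artifacts, the composition table, the sequence
    summary, the test tables, figures, a provenance log and a
    machine-readable ``summary.json``. Returns the run directory.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))

    results: list[SliceResult] = []
    for spec in cfg.slices:
        try:
            res = run_slice(cfg, spec)
        except Exception as exc:
            raise RuntimeError(
                f"stage failure in slice {spec.label!r}: {exc}"
            ) from exc
        results.append(res)
        sdir = out / f"slice_{spec.label}"
        sdir.mkdir(exist_ok=True)
        res.cells.to_csv(sdir / "cells.csv", index=False)
        res.activations.to_csv(sdir / "activations.csv", index=False)
        _cycles_frame(spec.label, res.cycles).to_csv(sdir / "cycles.csv",
                                                     index=False)
        pd.DataFrame(
            [
                {
                    "peak_frame": b.peak_frame,
                    "peak_time_s": b.peak_time_s,
                    "amplitude": b.amplitude,
                    "is_sigh": b.is_sigh,
                    "accepted": b.accepted,
                }
                for b in res.bursts
            ]
        ).to_csv(sdir / "bursts.csv", index=False)

    composition = composition_table(
        {
            r.label: r.cells[r.cells.cell_type.isin(FIVE_TYPES)].cell_type.tolist()
            for r in results
        }
    )
    all_cells = pd.concat(
        [r.cells.assign(slice=r.label) for r in results], ignore_index=True
    )
    all_acts = pd.concat(
        [r.activations.assign(slice=r.label) for r in results], ignore_index=True
    )

    slice_data = [r.as_slice_data() for r in results]
    summary = summarize(slice_data)

    timing_groups = {
        t: np.array(
            [
                sd_
                for sd_ in (
                    _slice_type_mean(sdta, t) for sdta in slice_data
                )
                if not np.isnan(sd_)
            ]
        )
        for t in FIVE_TYPES
    }
    try:
        anova = anova_tukey(
            {t: v for t, v in timing_groups.items() if v.size >= 2}
        )
        anova_df = pd.DataFrame(
            [
                {
                    "test": r.test,
                    "groups": " vs ".join(r.groups) if r.test != "ANOVA" else "all",
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "significant": r.significant_at_0_05,
                }
                for r in anova
            ]
        )
    except ValueError as exc:
        log.warning("ANOVA skipped: %s", exc)
        anova_df = pd.DataFrame()
    ks_df = three_family_tests(slice_data)
    tests = pd.concat(
        [anova_df.assign(family="mean_timing_anova"),
         ks_df.rename(columns={"D": "statistic"})],
        ignore_index=True,
    )

    write_results_tables(all_cells, all_acts, composition, out, stats=tests)

    summary_tables = {
        "occupancy_mean": summary.occupancy_mean,
        "occupancy_se": summary.occupancy_se,
        "cumulative_mean": summary.type_cumulative_mean,
        "cumulative_se": summary.type_cumulative_se,
    }
    rows = []
    for name, df in summary_tables.items():
        d = df.copy()
        d.insert(0, "metric", name)
        d.insert(1, "cell_type", d.index)
        rows.append(d)
    pd.concat(rows, ignore_index=True).to_csv(out / "summary.csv", index=False)
    summary.leader_fractions.assign(cell_type=summary.leader_fractions.index).to_csv(
        out / "leader_fractions.csv", index=False
    )
    summary.early_fractions.assign(cell_type=summary.early_fractions.index).to_csv(
        out / "early_fractions.csv", index=False
    )
    summary.mean_timing.assign(cell_type=summary.mean_timing.index).to_csv(
        out / "mean_timing.csv", index=False
    )

    machine = {
        "version": __version__,
        "seed": cfg.seed,
        "n_slices": summary.n_slices,
        "cutoffs": {r.label: round(float(r.cutoff), 6) for r in results},
        "n_cells": {
            r.label: int(r.cells.cell_type.isin(FIVE_TYPES).sum()) for r in results
        },
        "n_accepted_bursts": {
            r.label: int(sum(b.accepted for b in r.bursts)) for r in results
        },
        "mean_timing_ms": {
            t: round(float(summary.mean_timing.loc[t, "mean_s"]) * 1000.0, 3)
            if not np.isnan(summary.mean_timing.loc[t, "mean_s"])
            else None
            for t in FIVE_TYPES
        },
        "leader_fraction": {
            t: round(float(summary.leader_fractions.loc[t, "mean"]), 6)
            if not np.isnan(summary.leader_fractions.loc[t, "mean"])
            else None
            for t in FIVE_TYPES
        },
    }
    (out / "summary.json").write_text(
        json.dumps(machine, indent=2, sort_keys=True, default=_json_default)
    )

    if cfg.make_figures:
        try:
            from .plots import plot_summary

            plot_summary(summary, out)
        except Exception as exc:  # plotting must never sink a run
            log.warning("figure generation failed: %s", exc)
    log.info("run complete: %s", out)
    return out


def _slice_type_mean(sd: SliceData, ctype: str) -> float:
    ids = [cid for cid, t in sd.cell_types.items() if t == ctype]
    sel = sd.activations[sd.activations.cell_id.isin(ids)]
    included = {c.burst_id for c in sd.cycles if c.included}
    sel = sel[sel.burst_id.isin(included)]
    return float(sel.timing_s.mean()) if len(sel) else float("nan")
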