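"""Scoring a pipeline run against synthetic ground truth.

Matching conventions: an ROI matches the nearest planted cell within a
Chebyshev distance of 2 px; a detected burst matches the nearest true
burst within 0.3 s. Timing recovery compares the recovered activation
timing of every matched (cell, burst) pair with the generator's true
calcium-peak offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import SliceResult
from .synthetic_data import GroundTruth

__all__ = ["RecoveryScore", "match_rois", "match_bursts", "score_slice",
           "pool_scores"]


@dataclass
class RecoveryScore:
    """Per-slice (or pooled) recovery metrics against ground truth."""

    n_true_rhythmic: int
    n_rois: int
    n_rois_matched: int
    n_regularity_correct: int
    n_regularity_scored: int
    n_type_correct: int
    sigh_jaccard: float
    burst_recall: float
    burst_precision: float
    timing_pairs: np.ndarray  # (n, 2): recovered, true (seconds)

    @property
    def roi_match_fraction(self) -> float:
        return self.n_rois_matched / self.n_true_rhythmic

    @property
    def regularity_accuracy(self) -> float:
        return self.n_regularity_correct / max(self.n_regularity_scored, 1)

    @property
    def type_accuracy(self) -> float:
        return self.n_type_correct / max(self.n_regularity_scored, 1)

    def timing_r(self) -> float:
        p = self.timing_pairs
        return float(np.corrcoef(p[:, 0], p[:, 1])[0, 1]) if len(p) > 2 else np.nan

    def timing_mae_frames(self, rate_hz: float = 10.0) -> float:
        p = self.timing_pairs
        return float(np.abs(p[:, 0] - p[:, 1]).mean() * rate_hz) if len(p) else np.nan


def match_rois(
    result: SliceResult, truth: GroundTruth, tol_px: int = 2
) -> dict[int, int]:
    """ROI id -> planted cell index for centres within ``tol_px`` (Chebyshev)."""
    mapping: dict[int, int] = {}
    if not len(truth.cell_types):
        return mapping
    for roi in result.rois:
        d = np.abs(truth.cell_centers - np.array(roi.center)).max(axis=1)
        if d.min() <= tol_px:
            mapping[roi.id] = int(d.argmin())
    return mapping


def match_bursts(
    result: SliceResult, truth: GroundTruth, tol_s: float = 0.3
) -> dict[int, int]:
    """Detected burst index -> true burst index within ``tol_s``."""
    mapping: dict[int, int] = {}
    for i, b in enumerate(result.bursts):
        d = np.abs(truth.burst_peak_times_s - b.peak_time_s)
        if d.min() <= tol_s:
            mapping[i] = int(d.argmin())
    return mapping


def score_slice(result: SliceResult, tol_px: int = 2) -> RecoveryScore:
    """Score one slice's pipeline products against its ground truth."""
    truth: GroundTruth = result.truth
    if truth is None:
        raise ValueError("slice has no ground truth (not simulated)")
    cellmap = match_rois(result, truth, tol_px)
    burstmap = match_bursts(result, truth)

    n_true_rhythmic = sum(1 for t in truth.cell_types if t != "NonRhythmic")
    matched_rhythmic = {
        rid: ci for rid, ci in cellmap.items()
        if truth.cell_types[ci] != "NonRhythmic"
    }

    reg_correct = reg_scored = type_correct = 0
    for _, row in result.cells.iterrows():
        ci = matched_rhythmic.get(row.cell_id)
        if ci is None:
            continue
        true_type = truth.cell_types[ci]
        reg_scored += 1
        true_reg = "Regular" if true_type.startswith("R-") else "Irregular"
        reg_correct += int(row.regularity == true_reg)
        type_correct += int(row.cell_type == true_type)

    # burst recall/precision and sigh agreement
    accepted = [i for i, b in enumerate(result.bursts) if b.accepted]
    true_nonsigh = set(np.flatnonzero(~truth.sigh_flags))
    hit = {burstmap[i] for i in accepted if i in burstmap}
    burst_recall = len(hit & true_nonsigh) / max(len(true_nonsigh), 1)
    burst_precision = (
        sum(1 for i in accepted if burstmap.get(i) in true_nonsigh)
        / max(len(accepted), 1)
    )
    det_sigh = {burstmap[i] for i, b in enumerate(result.bursts)
                if b.is_sigh and i in burstmap}
    true_sigh = set(np.flatnonzero(truth.sigh_flags))
    union = det_sigh | true_sigh
    sigh_jaccard = len(det_sigh & true_sigh) / len(union) if union else 1.0

    true_off = truth.true_offsets.set_index(["cell_id", "burst_id"]).offset_s
    pairs = []
    for _, a in result.activations.iterrows():
        ci = cellmap.get(a.cell_id)
        bi = burstmap.get(a.burst_id)
        if ci is None or bi is None:
            continue
        key = (ci, bi)
        if key in true_off.index:
            pairs.append((a.timing_s, float(true_off.loc[key])))
    return RecoveryScore(
        n_true_rhythmic=n_true_rhythmic,
        n_rois=len(result.rois),
        n_rois_matched=len(matched_rhythmic),
        n_regularity_correct=reg_correct,
        n_regularity_scored=reg_scored,
        n_type_correct=type_correct,
        sigh_jaccard=sigh_jaccard,
        burst_recall=burst_recall,
        burst_precision=burst_precision,
        timing_pairs=np.array(pairs) if pairs else np.zeros((0, 2)),
    )


def pool_scores(scores: list[RecoveryScore]) -> RecoveryScore:
    """Sum counts and concatenate timing pairs across slices."""
    return RecoveryScore(
        n_true_rhythmic=sum(s.n_true_rhythmic for s in scores),
        n_rois=sum(s.n_rois for s in scores),
        n_rois_matched=sum(s.n_rois_matched for s in scores),
        n_regularity_correct=sum(s.n_regularity_correct for s in scores),
        n_regularity_scored=sum(s.n_regularity_scored for s in scores),
        n_type_correct=sum(s.n_type_correct for s in scores),
        sigh_jaccard=float(np.mean([s.sigh_jaccard for s in scores])),
        burst_recall=float(np.mean([s.burst_recall for s in scores])),
        burst_precision=float(np.mean([s.burst_precision for s in scores])),
        timing_pairs=np.vstack([s.timing_pairs for s in scores]),
    )
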