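"""Five-way typing of detected cells and slice composition tables.

A cell's type combines two independent observations: reporter expression
(EGFP marks glycinergic cells, tdTomato marks GABAergic cells) and the
regular/irregular split of its LFP correlation (maxCC above or below a
per-experiment cutoff). Reporter x regularity combinations never observed
in slices map to ``Unclassified`` and are excluded from five-type
statistics but retained in outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .functional_roi import FunctionalRoi

__all__ = [
    "CellRecord",
    "FIVE_TYPES",
    "classify_regularity",
    "suggest_cutoff",
    "assign_cell_type",
    "composition_table",
]

log = logging.getLogger(__name__)

FIVE_TYPES = ("R-Ex", "R-Gly", "Irr-Ex", "Irr-Gly", "Irr-Cotrans")

# (glyt2_pos, gad65_pos, regularity) -> type; missing keys were never
# observed experimentally and fall through to Unclassified.
_TYPE_MAP = {
    (False, False, "Regular"): "R-Ex",
    (True, False, "Regular"): "R-Gly",
    (False, False, "Irregular"): "Irr-Ex",
    (True, False, "Irregular"): "Irr-Gly",
    (True, True, "Irregular"): "Irr-Cotrans",
}


@dataclass
class CellRecord:
    roi: FunctionalRoi
    glyt2_pos: bool
    gad65_pos: bool
    regularity: str
    cell_type: str
    cutoff_used: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff_used <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")
        expected = _TYPE_MAP.get(
            (self.glyt2_pos, self.gad65_pos, self.regularity), "Unclassified"
        )
        if self.cell_type != expected:
            raise ValueError(
                f"cell_type {self.cell_type!r} inconsistent with flags/regularity"
            )


def classify_regularity(maxcc: float, cutoff: float) -> str:
    """Regular iff maxcc strictly exceeds the cutoff."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    return "Regular" if maxcc > cutoff else "Irregular"


def suggest_cutoff(
    maxcc_values: np.ndarray, clamp: tuple[float, float] = (0.40, 0.70)
) -> float:
    """Data-driven regular/irregular cutoff.

    Maximizes the between-class variance of the detected-cell maxCC sample
    (Otsu's criterion, evaluated at every midpoint between sorted values)
    and clamps the result to a plausible range. Replaces the per-experiment
    manual tuning of the original workflow; always overridable.
    """
    v = np.sort(np.asarray(maxcc_values, dtype=float))
    if v.size < 6:
        raise ValueError(
            "fewer than 6 cells: choose the regular/irregular cutoff manually"
        )
    best_t, best_score = None, -np.inf
    for i in range(1, v.size):
        lo, hi = v[:i], v[i:]
        score = lo.size * hi.size * (hi.mean() - lo.mean()) ** 2
        if score > best_score:
            best_score = score
            best_t = 0.5 * (v[i - 1] + v[i])
    cutoff = float(best_t)
    clamped = float(np.clip(cutoff, *clamp))
    if clamped != cutoff:
        warnings.warn(
            f"Otsu cutoff {cutoff:.3f} outside {clamp}; clamped to {clamped:.2f}"
            " — likely a unimodal maxCC sample, consider a manual cutoff",
            stacklevel=2,
        )
    log.info("suggested maxCC cutoff %.3f (n=%d cells)", clamped, v.size)
    return clamped


def assign_cell_type(glyt2_pos: bool, gad65_pos: bool, regularity: str) -> str:
    """Map reporter flags + regularity to one of the five types.

    Combinations never observed in slices (GAD65-only cells, regular
    double-positives) return ``Unclassified`` with a warning.
    """
    key = (bool(glyt2_pos), bool(gad65_pos), regularity)
    if key not in _TYPE_MAP:
        warnings.warn(
            f"marker/regularity combination {key} not among the five observed "
            "types; labelled Unclassified", stacklevel=2,
        )
        return "Unclassified"
    return _TYPE_MAP[key]


def _round_half_up(x: float, decimals: int = 1) -> float:
    f = 10.0**decimals
    return float(np.floor(x * f + 0.5) / f)


def composition_table(cells_by_slice: dict[str, list[str]]) -> pd.DataFrame:
    """Per-slice composition of the five types, counts plus percentages.

    Layout mirrors the conventional composition table: one counts row and
    one percentage row per slice, then a Total pair summing over slices.
    Percentages are 100*count/row_total rounded half-up to one decimal
    (an empty slice reports 0.0% with a warning).
    """
    if not cells_by_slice:
        raise ValueError("at least one slice required")
    records = []
    totals = {t: 0 for t in FIVE_TYPES}
    for slice_label, types in cells_by_slice.items():
        counts = {t: sum(1 for x in types if x == t) for t in FIVE_TYPES}
        for t in FIVE_TYPES:
            totals[t] += counts[t]
        records.append((str(slice_label), counts))
    records.append(("Total", totals))

    rows = []
    for label, counts in records:
        row_total = sum(counts.values())
        rows.append(
            {"slice": label, "row": "count", **counts, "Total": row_total}
        )
        if row_total == 0:
            warnings.warn(f"slice {label!r} has no classified cells", stacklevel=2)
            pct = {t: 0.0 for t in FIVE_TYPES}
            pct_total = 0.0
        else:
            pct = {t: _round_half_up(100.0 * counts[t] / row_total) for t in FIVE_TYPES}
            pct_total = 100.0
        rows.append({"slice": label, "row": "percent", **pct, "Total": pct_total})
    return pd.DataFrame(rows, columns=["slice", "row", *FIVE_TYPES, "Total"])
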