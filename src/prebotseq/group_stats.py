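"""Cross-slice sequence summaries and statistical tests.

Every summary is computed per slice first and then averaged (mean ± SE,
n = slices), matching the slice-as-unit convention of the underlying
experiments: occupancy of each cell type per 10% rank bin, per-type
cumulative activation-probability curves, leader fractions, early-
activation fractions, and per-type mean activation timings. Group
comparisons use one-way ANOVA with Tukey HSD on per-slice summary values
and pairwise two-sample Kolmogorov-Smirnov tests on distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .activation_sequence import CycleRecord
from .cell_typing import FIVE_TYPES

__all__ = [
    "SliceData",
    "SequenceSummary",
    "TestResult",
    "summarize",
    "anova_tukey",
    "ks_pairwise",
    "three_family_tests",
]

RANK_BINS = np.arange(0.0, 100.1, 10.0)  # (0,10], (10,20], ..., (90,100]
EARLY_THRESHOLDS_S = (-0.5, 0.0)


@dataclass
class SliceData:
    """One slice's pipeline products needed for group statistics."""

    label: str
    cell_types: dict[int, str]            # cell_id -> five-type label
    activations: pd.DataFrame             # cell_id, burst_id, timing_s
    cycles: list[CycleRecord]

    def included_cycles(self) -> list[CycleRecord]:
        return [c for c in self.cycles if c.included]


@dataclass
class SequenceSummary:
    """Mean ± SE across slices of every sequence metric.

    DataFrames are indexed by cell type; occupancy and cumulative frames
    have one column per 10% rank bin (labelled by the bin's upper edge).
    """

    occupancy_mean: pd.DataFrame
    occupancy_se: pd.DataFrame
    type_cumulative_mean: pd.DataFrame
    type_cumulative_se: pd.DataFrame
    leader_fractions: pd.DataFrame        # columns mean, se
    early_fractions: pd.DataFrame         # rows type, columns per threshold
    mean_timing: pd.DataFrame             # columns mean_s, se_s
    n_slices: int


@dataclass
class TestResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant_at_0_05(self) -> bool:
        return self.p_value < 0.05


def _rank_bin(rank: float) -> int:
    """Bin index of a percent rank in (0, 100]: (0,10] -> 0 ... (90,100] -> 9."""
    return min(int(np.ceil(rank / 10.0)) - 1, 9)


def _per_slice_metrics(sl: SliceData) -> dict[str, object]:
    included = sl.included_cycles()
    if not included:
        raise ValueError(f"slice {sl.label!r} has no included cycles")
    timing = sl.activations.set_index(["cell_id", "burst_id"])["timing_s"]

    occ_counts = pd.DataFrame(0.0, index=list(FIVE_TYPES), columns=range(10))
    leaders = {t: 0 for t in FIVE_TYPES}
    early = {(t, thr): 0 for t in FIVE_TYPES for thr in EARLY_THRESHOLDS_S}
    timings: dict[str, list[float]] = {t: [] for t in FIVE_TYPES}

    for cyc in included:
        cycle_types = []
        for cell_id, rank in zip(cyc.order, cyc.percent_ranks):
            ctype = sl.cell_types.get(cell_id)
            cycle_types.append(ctype)
            if ctype is None:  # unclassified cells stay out of 5-type stats
                continue
            occ_counts.loc[ctype, _rank_bin(rank)] += 1
            timings[ctype].append(float(timing.loc[(cell_id, cyc.burst_id)]))
        # leader: first classified cell of the cycle
        for ctype in cycle_types:
            if ctype is not None:
                leaders[ctype] += 1
                break
        for thr in EARLY_THRESHOLDS_S:
            for t5 in FIVE_TYPES:
                hit = any(
                    sl.cell_types.get(cid) == t5
                    and float(timing.loc[(cid, cyc.burst_id)]) <= thr
                    for cid in cyc.order
                )
                if hit:
                    early[(t5, thr)] += 1

    n_cycles = len(included)
    bin_totals = occ_counts.sum(axis=0)
    occupancy = occ_counts.divide(bin_totals.replace(0, np.nan), axis=1)

    type_totals = occ_counts.sum(axis=1)
    cumulative = occ_counts.cumsum(axis=1).divide(
        type_totals.replace(0, np.nan), axis=0
    )

    leader_total = sum(leaders.values())
    leader_frac = {
        t: leaders[t] / leader_total if leader_total else np.nan for t in FIVE_TYPES
    }
    early_frac = {
        (t, thr): early[(t, thr)] / n_cycles
        for t in FIVE_TYPES
        for thr in EARLY_THRESHOLDS_S
    }
    mean_timing = {
        t: (np.mean(timings[t]) if timings[t] else np.nan) for t in FIVE_TYPES
    }
    pooled_ranks = {
        t: np.array(
            [
                r
                for cyc in included
                for cid, r in zip(cyc.order, cyc.percent_ranks)
                if sl.cell_types.get(cid) == t
            ]
        )
        for t in FIVE_TYPES
    }
    return {
        "occupancy": occupancy,
        "cumulative": cumulative,
        "leader_frac": leader_frac,
        "early_frac": early_frac,
        "mean_timing": mean_timing,
        "timings": {t: np.asarray(v) for t, v in timings.items()},
        "pooled_ranks": pooled_ranks,
    }


def _mean_se(frames: list[pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    arr = np.stack([f.to_numpy(dtype=float) for f in frames])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(arr, axis=0)
        n = np.sum(~np.isnan(arr), axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    tmpl = frames[0]
    return (
        pd.DataFrame(mean, index=tmpl.index, columns=tmpl.columns),
        pd.DataFrame(se, index=tmpl.index, columns=tmpl.columns),
    )


def summarize(slices: list[SliceData]) -> SequenceSummary:
    """Compute the full sequence summary, slice means first, then ± SE."""
    metrics = []
    for sl in slices:
        try:
            metrics.append(_per_slice_metrics(sl))
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
    if not metrics:
        raise ValueError("no slice with included cycles")

    occ_m, occ_se = _mean_se([m["occupancy"] for m in metrics])
    cum_m, cum_se = _mean_se([m["cumulative"] for m in metrics])

    lead = np.array([[m["leader_frac"][t] for m in metrics] for t in FIVE_TYPES])
    leader = pd.DataFrame(
        {
            "mean": np.nanmean(lead, axis=1),
            "se": np.nanstd(lead, axis=1, ddof=1) / np.sqrt(lead.shape[1])
            if lead.shape[1] > 1
            else np.nan,
        },
        index=list(FIVE_TYPES),
    )
    early_cols = {}
    for thr in EARLY_THRESHOLDS_S:
        vals = np.array(
            [[m["early_frac"][(t, thr)] for m in metrics] for t in FIVE_TYPES]
        )
        label = f"le_{thr:g}s"
        early_cols[f"{label}_mean"] = vals.mean(axis=1)
        early_cols[f"{label}_se"] = (
            vals.std(axis=1, ddof=1) / np.sqrt(vals.shape[1])
            if vals.shape[1] > 1
            else np.full(len(FIVE_TYPES), np.nan)
        )
    early = pd.DataFrame(early_cols, index=list(FIVE_TYPES))

    mt = np.array([[m["mean_timing"][t] for m in metrics] for t in FIVE_TYPES])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mt_mean = np.nanmean(mt, axis=1)
        mt_n = np.sum(~np.isnan(mt), axis=1)
        mt_sd = np.nanstd(mt, axis=1, ddof=1)
    mean_timing = pd.DataFrame(
        {
            "mean_s": mt_mean,
            "se_s": np.where(mt_n > 1, mt_sd / np.sqrt(np.maximum(mt_n, 1)), np.nan),
        },
        index=list(FIVE_TYPES),
    )
    bin_labels = [int(b) for b in RANK_BINS[1:]]
    for df in (occ_m, occ_se, cum_m, cum_se):
        df.columns = bin_labels
    return SequenceSummary(
        occupancy_mean=occ_m,
        occupancy_se=occ_se,
        type_cumulative_mean=cum_m,
        type_cumulative_se=cum_se,
        leader_fractions=leader,
        early_fractions=early,
        mean_timing=mean_timing,
        n_slices=len(metrics),
    )


def anova_tukey(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons.

    Groups with identical values everywhere (zero between- and
    within-group variance) yield F = 0, p = 1; zero within-group variance
    with distinct means is degenerate and raises.
    """
    names = [k for k, v in groups.items() if np.asarray(v).size >= 2]
    if len(names) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    grand = np.concatenate(samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    ss_between = sum(s.size * (s.mean() - grand.mean()) ** 2 for s in samples)
    if ss_between < 1e-30 and ss_within < 1e-30:
        results = [TestResult("ANOVA", tuple(names), 0.0, 1.0)]
    elif ss_within < 1e-30:
        raise ValueError("zero within-group variance everywhere: ANOVA degenerate")
    else:
        f, p = sps.f_oneway(*samples)
        results = [TestResult("ANOVA", tuple(names), float(f), float(p))]

    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if ss_within >= 1e-30:
        values = np.concatenate(samples)
        labels = np.concatenate([[k] * s.size for k, s in zip(names, samples)])
        tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
        pairs = list(combinations(tk.groupsunique, 2))
        for (g1, g2), diff, p in zip(pairs, tk.meandiffs, tk.pvalues):
            results.append(
                TestResult("TukeyHSD", (str(g1), str(g2)), float(diff),
                           float(np.clip(p, 0.0, 1.0)))
            )
    return results


def ks_pairwise(
    samples: dict[str, np.ndarray], min_n: int = 5
) -> list[TestResult]:
    """Two-sample KS test (asymptotic p) for every pair of types."""
    names = list(samples)
    results = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa = np.asarray(samples[a], dtype=float)
            xb = np.asarray(samples[b], dtype=float)
            if xa.size < min_n or xb.size < min_n:
                warnings.warn(
                    f"pair ({a}, {b}) skipped: sample below {min_n}", stacklevel=2
                )
                continue
            res = sps.ks_2samp(xa, xb, method="asymp")
            results.append(
                TestResult("KS", (a, b), float(res.statistic),
                           float(min(res.pvalue, 1.0)))
            )
    return results


def three_family_tests(slices: list[SliceData]) -> pd.DataFrame:
    """Pairwise KS tests in the three-family layout.

    Families: (1) pooled activation timings per type; (2) per-slice,
    per-bin occupancy shares per type; (3) pooled percent ranks per type
    (the cumulative activation-rate distributions). Raw p-values, no
    multiplicity correction, matching the reporting convention.
    """
    metrics = [_per_slice_metrics(sl) for sl in slices]
    timings = {
        t: np.concatenate([m["timings"][t] for m in metrics]) for t in FIVE_TYPES
    }
    occup = {
        t: np.concatenate(
            [m["occupancy"].loc[t].dropna().to_numpy() for m in metrics]
        )
        for t in FIVE_TYPES
    }
    ranks = {
        t: np.concatenate([m["pooled_ranks"][t] for m in metrics])
        for t in FIVE_TYPES
    }
    rows = []
    for family, samp in (
        ("activation_timing", timings),
        ("rank_occupancy", occup),
        ("sequence_rate", ranks),
    ):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for res in ks_pairwise(samp):
                rows.append(
                    {
                        "family": family,
                        "type_a": res.groups[0],
                        "type_b": res.groups[1],
                        "D": res.statistic,
                        "p_value": res.p_value,
                        "significant": res.significant_at_0_05,
                    }
                )
    return pd.DataFrame(rows)
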