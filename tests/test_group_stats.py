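import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prebotseq.activation_sequence import CycleRecord
from prebotseq.group_stats import (
    SliceData,
    anova_tukey,
    ks_pairwise,
    summarize,
    three_family_tests,
)


def _slice_one_cycle():
    """One cycle: Irr-Ex, Irr-Ex, R-Ex, R-Gly activated in that order."""
    cell_types = {0: "Irr-Ex", 1: "Irr-Ex", 2: "R-Ex", 3: "R-Gly"}
    acts = pd.DataFrame(
        {
            "cell_id": [0, 1, 2, 3],
            "burst_id": [0, 0, 0, 0],
            "timing_s": [-0.2, 0.0, 0.1, 0.3],
        }
    )
    cycles = [CycleRecord(0, True, [0, 1, 2, 3], [25.0, 50.0, 75.0, 100.0])]
    return SliceData("s", cell_types, acts, cycles)


class TestSummarize:
    def test_hand_counted_single_cycle(self):
        s = summarize([_slice_one_cycle()])
        assert s.n_slices == 1
        # leader is the first cell in the order: Irr-Ex
        assert s.leader_fractions.loc["Irr-Ex", "mean"] == 1.0
        assert s.leader_fractions.loc["R-Ex", "mean"] == 0.0
        # rank 25 falls in the (20,30] bin, sole occupant
        assert s.occupancy_mean.loc["Irr-Ex", 30] == 1.0
        assert s.occupancy_mean.loc["R-Ex", 80] == 1.0
        assert s.occupancy_mean.loc["R-Gly", 100] == 1.0
        # cumulative reaches 1 for every populated type
        assert s.type_cumulative_mean.loc["Irr-Ex", 100] == 1.0
        # mean timings match the raw activations
        assert s.mean_timing.loc["Irr-Ex", "mean_s"] == pytest.approx(-0.1)
        # early fractions: one Irr-Ex activation at or before t=0
        assert s.early_fractions.loc["Irr-Ex", "le_0s_mean"] == 1.0
        assert s.early_fractions.loc["R-Ex", "le_0s_mean"] == 0.0

    def test_single_type_occupies_all_populated_bins(self):
        cell_types = {i: "R-Ex" for i in range(4)}
        acts = pd.DataFrame(
            {"cell_id": [0, 1, 2, 3], "burst_id": 0, "timing_s": [0.1, 0.2, 0.3, 0.4]}
        )
        cycles = [CycleRecord(0, True, [0, 1, 2, 3], [25.0, 50.0, 75.0, 100.0])]
        s = summarize([SliceData("s", cell_types, acts, cycles)])
        occ = s.occupancy_mean.loc["R-Ex"].dropna()
        assert (occ == 1.0).all()

    def test_occupancy_conserved_across_types(self, default_results):
        """Within every populated bin the type shares sum to one, per slice."""
        from prebotseq.group_stats import _per_slice_metrics

        for res in default_results:
            m = _per_slice_metrics(res.as_slice_data())
            sums = m["occupancy"].sum(axis=0, skipna=True)
            populated = m["occupancy"].notna().any(axis=0)
            np.testing.assert_allclose(sums[populated], 1.0, atol=1e-9)

    def test_se_matches_direct_formula(self):
        slices = [_slice_one_cycle() for _ in range(3)]
        # perturb one slice's timing so SE is nonzero
        slices[1].activations.loc[0, "timing_s"] = -0.5
        s = summarize(slices)
        vals = [-0.1, (-0.5 + 0.0) / 2, -0.1]  # per-slice Irr-Ex means
        expect_se = np.std(vals, ddof=1) / np.sqrt(3)
        assert s.mean_timing.loc["Irr-Ex", "se_s"] == pytest.approx(expect_se)

    def test_leader_fractions_sum_to_one(self, default_results):
        s = summarize([r.as_slice_data() for r in default_results])
        assert s.leader_fractions["mean"].sum() == pytest.approx(1.0, abs=1e-9)


class TestAnova:
    def test_identical_groups_f_zero_p_one(self):
        res = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert res[0].statistic == 0.0
        assert res[0].p_value == 1.0

    def test_separated_groups_tiny_p(self, rng):
        res = anova_tukey(
            {
                "a": 0.0 + rng.normal(0, 1e-3, 3),
                "b": 10.0 + rng.normal(0, 1e-3, 3),
            }
        )
        assert res[0].p_value < 1e-6
        tukey = [r for r in res if r.test == "TukeyHSD"]
        assert len(tukey) == 1 and tukey[0].p_value < 0.01

    def test_degenerate_distinct_constants_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            anova_tukey({"a": [0.0, 0.0], "b": [1.0, 1.0]})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 2.0]})


class TestKs:
    def test_identical_samples(self):
        x = np.arange(10.0)
        res = ks_pairwise({"a": x, "b": x.copy()})
        assert res[0].statistic == 0.0
        assert res[0].p_value == 1.0

    def test_shifted_normals_rejected(self, rng):
        res = ks_pairwise(
            {"a": rng.normal(0, 1, 200), "b": rng.normal(3, 1, 200)}
        )
        assert res[0].p_value < 0.001

    def test_d_matches_brute_force_ecdf_gap(self, rng):
        """Oracle: D = max gap between the two ECDFs over the merged sample."""
        for _ in range(50):
            na, nb = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.uniform(-1, 1), 1, nb)
            res = ks_pairwise({"a": a, "b": b})[0]
            grid = np.concatenate([a, b])
            fa = np.searchsorted(np.sort(a), grid, side="right") / na
            fb = np.searchsorted(np.sort(b), grid, side="right") / nb
            assert res.statistic == pytest.approx(np.abs(fa - fb).max(), abs=1e-12)

    def test_small_sample_skipped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="skipped"):
            res = ks_pairwise({"a": rng.normal(0, 1, 3), "b": rng.normal(0, 1, 50)})
        assert res == []

    def test_null_calibration_no_inflation(self, rng):
        """Five same-distribution groups: the 10 pairwise tests reject ~ alpha."""
        reject = 0
        total = 0
        for _ in range(200):
            groups = {f"g{i}": rng.normal(0, 1, 60) for i in range(5)}
            for r in ks_pairwise(groups):
                total += 1
                reject += r.p_value < 0.05
        rate = reject / total
        assert 0.01 <= rate <= 0.10


class TestThreeFamilies:
    def test_layout_on_default_run(self, default_results):
        df = three_family_tests([r.as_slice_data() for r in default_results])
        assert set(df.family) == {"activation_timing", "rank_occupancy",
                                  "sequence_rate"}
        # 10 unordered pairs of the five types per family
        assert (df.groupby("family").size() == 10).all()
        assert df.p_value.between(0, 1).all()

    def test_timing_family_agrees_with_direct_ks(self, default_results):
        slice_data = [r.as_slice_data() for r in default_results]
        df = three_family_tests(slice_data)
        fam = df[df.family == "activation_timing"]
        row = fam[
            ((fam.type_a == "Irr-Ex") & (fam.type_b == "R-Ex"))
            | ((fam.type_a == "R-Ex") & (fam.type_b == "Irr-Ex"))
        ].iloc[0]
        pooled = {"Irr-Ex": [], "R-Ex": []}
        for sd in slice_data:
            inc = {c.burst_id for c in sd.cycles if c.included}
            for cid, t in sd.cell_types.items():
                if t in pooled:
                    sel = sd.activations[
                        (sd.activations.cell_id == cid)
                        & sd.activations.burst_id.isin(inc)
                    ]
                    pooled[t].extend(sel.timing_s)
        want = sps.ks_2samp(pooled["Irr-Ex"], pooled["R-Ex"], method="asymp")
        assert row.D == pytest.approx(want.statistic, abs=1e-12)
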