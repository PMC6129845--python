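import numpy as np
import pytest

from prebotseq.activation_sequence import (
    Activation,
    build_cycles,
    detect_activation,
    interburst_noise,
    timing_cumulative,
)
from prebotseq.burst_events import BurstEvent


def _burst(frame, rate=10.0):
    return BurstEvent(frame, frame / rate, 1.0)


def _transient_trace(n, peak_frame, amp=5.0):
    t = np.arange(n, dtype=float)
    tr = amp * np.exp(-((t - peak_frame) ** 2) / 8.0)
    return tr


class TestDetectActivation:
    def test_planted_peak_three_frames_late(self):
        trace = _transient_trace(200, 103)
        act = detect_activation(trace, _burst(100), 10.0, noise_sigma=0.1)
        assert act is not None
        assert act.timing_s == pytest.approx(0.3)

    def test_flat_trace_gives_none(self):
        assert detect_activation(np.zeros(200), _burst(100), 10.0, 0.1) is None

    def test_subthreshold_peak_rejected(self):
        trace = _transient_trace(200, 100, amp=0.2)
        assert detect_activation(trace, _burst(100), 10.0,
                                 noise_sigma=0.1, noise_k=3.0) is None

    def test_edge_window_truncated_with_warning(self):
        trace = _transient_trace(100, 5)
        with pytest.warns(UserWarning, match="truncated"):
            act = detect_activation(trace, _burst(10), 10.0, 0.01)
        assert act is not None

    def test_all_peaks_before_lfp_give_negative_timing(self):
        """Sign convention: calcium leading the burst peak means timing < 0."""
        bursts = [_burst(f) for f in (100, 200, 300)]
        trace = sum(_transient_trace(400, f - 5) for f in (100, 200, 300))
        for b in bursts:
            act = detect_activation(trace, b, 10.0, 0.01)
            assert act is not None and act.timing_s < 0


class TestInterburstNoise:
    def test_pure_noise_level_recovered(self, rng):
        trace = rng.normal(0, 0.5, 2000)
        sigma = interburst_noise(trace, [_burst(500), _burst(1500)])
        assert sigma == pytest.approx(0.5, rel=0.15)

    def test_burst_windows_excluded(self, rng):
        trace = rng.normal(0, 0.5, 2000)
        trace[480:520] += 50.0  # giant transient inside the burst window
        sigma = interburst_noise(trace, [_burst(500)])
        assert sigma == pytest.approx(0.5, rel=0.15)


class TestBuildCycles:
    @staticmethod
    def _acts(burst_id, timings, start_cell=0):
        return [
            Activation(start_cell + i, burst_id, 0, t, 1.0)
            for i, t in enumerate(timings)
        ]

    def test_half_rule_excludes_sparse_cycle(self):
        bursts = [_burst(100)]
        acts = self._acts(0, [0.1, 0.2, 0.3, 0.4])
        cycles = build_cycles(acts, n_inspiratory_cells=10, bursts=bursts)
        assert not cycles[0].included

    def test_percent_ranks_quarters(self):
        bursts = [_burst(100)]
        acts = self._acts(0, [-0.2, 0.0, 0.1, 0.4])
        cycles = build_cycles(acts, n_inspiratory_cells=4, bursts=bursts)
        assert cycles[0].included
        assert cycles[0].percent_ranks == [25.0, 50.0, 75.0, 100.0]

    def test_order_sorted_by_timing_ties_by_id(self):
        bursts = [_burst(100)]
        acts = [
            Activation(3, 0, 0, 0.2, 1.0),
            Activation(1, 0, 0, 0.2, 1.0),
            Activation(2, 0, 0, -0.1, 1.0),
        ]
        cycles = build_cycles(acts, 3, bursts)
        assert cycles[0].order == [2, 1, 3]

    def test_inclusion_monotonicity(self):
        bursts = [_burst(f) for f in (100, 200, 300)]
        acts = (
            self._acts(0, [0.1] * 6)
            + self._acts(1, [0.1] * 4)
            + self._acts(2, [0.1] * 2)
        )
        counts = []
        for inc in (0.2, 0.4, 0.6, 0.8):
            cycles = build_cycles(acts, 10, bursts, inclusion=inc)
            counts.append(sum(c.included for c in cycles))
        assert counts == sorted(counts, reverse=True)

    def test_no_accepted_bursts_raises(self):
        sigh = BurstEvent(100, 10.0, 5.0, is_sigh=True, accepted=False)
        with pytest.raises(ValueError, match="accepted"):
            build_cycles([], 5, [sigh])

    def test_rank_invariants_on_small_run(self, small_run):
        for cyc in small_run.cycles:
            if not cyc.included:
                continue
            assert len(cyc.percent_ranks) == len(cyc.order)
            assert cyc.percent_ranks[-1] == 100.0
            assert min(cyc.percent_ranks) > 0


class TestTimingCumulative:
    def test_point_mass_is_step(self):
        grid = np.array([-1.0, -0.1, 0.0, 0.5])
        out = timing_cumulative({"R-Ex": np.zeros(5)}, grid)
        np.testing.assert_allclose(out["R-Ex"], [0, 0, 1, 1])

    def test_three_point_sample(self):
        out = timing_cumulative({"a": np.array([-0.5, 0.0, 0.5])},
                                np.array([0.0]))
        assert out["a"][0] == pytest.approx(2 / 3)

    def test_monotone_and_reaches_one(self, small_run):
        acts = small_run.activations
        grid = np.linspace(-2.5, 2.5, 101)
        out = timing_cumulative({"all": acts.timing_s.to_numpy()}, grid)
        cdf = out["all"]
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == 1.0

    def test_empty_type_warns_and_omits(self):
        with pytest.warns(UserWarning, match="omitted"):
            out = timing_cumulative({"x": np.array([])}, np.array([0.0]))
        assert "x" not in out
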