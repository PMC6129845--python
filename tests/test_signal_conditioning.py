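import numpy as np
import pytest

from prebotseq.io_formats import LfpTrace, Movie
from prebotseq.signal_conditioning import (
    _spatial_mean_3x3,
    filter_movie,
    integrate_lfp,
    resample_to_frames,
)

RATE = 10_000.0


def _lfp(values, rate=RATE, triggers=None):
    return LfpTrace(raw=np.asarray(values, float), raw_rate_hz=rate,
                    frame_trigger_times=triggers)


def _movie(data, rate=10.0):
    data = np.asarray(data, np.float32)
    return Movie(data, np.arange(data.shape[0]) / rate, 1.0, rate)


class TestIntegrateLfp:
    def test_zero_in_zero_out(self):
        out = integrate_lfp(_lfp(np.zeros(100_000)))
        assert np.all(out == 0)

    def test_step_response_closed_form(self):
        tau = 0.15
        a = 3.0
        x = np.zeros(100_000)
        x[10_000:] = a
        out = integrate_lfp(_lfp(x), tau_s=tau)
        at_tau = out[10_000 + int(tau * RATE)]
        assert at_tau == pytest.approx(a * (1 - np.exp(-1)), rel=0.01)

    def test_square_wave_steady_state_equals_rectified_mean(self):
        a = 2.0
        t = np.arange(200_000) / RATE
        x = a * np.sign(np.sin(2 * np.pi * 1000 * t))
        out = integrate_lfp(_lfp(x), tau_s=0.15)
        assert out[-1] == pytest.approx(a, rel=0.02)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            integrate_lfp(_lfp(np.zeros(100_000)), tau_s=0.0)

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50_000)
        assert np.allclose(
            integrate_lfp(_lfp(3 * x)), 3 * integrate_lfp(_lfp(x)), rtol=1e-10
        )


class TestResampleToFrames:
    def _movie_for(self, duration_s, rate=10.0):
        n = int(duration_s * rate)
        return _movie(np.zeros((n, 2, 2)), rate)

    def test_dc_passes_within_a_tenth_percent(self):
        c = 4.2
        lfp = _lfp(np.full(600_000, c))
        movie = self._movie_for(50)
        out = resample_to_frames(np.full(600_000, c), lfp, movie)
        assert np.all(np.abs(out.values - c) <= 1e-3 * c)

    def test_slow_sine_survives_decimation(self):
        t = np.arange(600_000) / RATE
        x = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
        lfp = _lfp(x)
        movie = self._movie_for(50)
        out = resample_to_frames(x, lfp, movie)
        spec = np.abs(np.fft.rfft(out.values - out.values.mean()))
        freqs = np.fft.rfftfreq(out.values.size, 1 / 10.0)
        assert freqs[spec.argmax()] == pytest.approx(0.2, abs=0.03)

    def test_fast_component_attenuated_40db(self):
        t = np.arange(600_000) / RATE
        hf = 0.2 * np.sin(2 * np.pi * 40 * t)
        x = 1.0 + hf
        lfp = _lfp(x)
        movie = self._movie_for(50)
        out = resample_to_frames(x, lfp, movie)
        # amplitude of any residual oscillation vs the input 40 Hz amplitude
        resid = out.values - out.values.mean()
        atten_db = 20 * np.log10(0.2 / max(np.abs(resid).max(), 1e-12))
        assert atten_db >= 40

    def test_frames_outside_span_rejected(self):
        lfp = _lfp(np.ones(100_000))  # 10 s
        movie = self._movie_for(50)  # 50 s of frames
        with pytest.raises(ValueError, match="span"):
            resample_to_frames(np.ones(100_000), lfp, movie)


class TestFilterMovie:
    def test_constant_movie_maps_to_zero(self):
        m = _movie(np.full((600, 8, 8), 7.0))
        out = filter_movie(m)
        assert np.abs(out.data).max() < 1e-6 * 7.0

    def test_spatial_kernel_definition(self):
        frames = np.zeros((1, 9, 9), np.float32)
        frames[0, 4, 4] = 9.0
        sm = _spatial_mean_3x3(frames)
        assert np.allclose(sm[0, 3:6, 3:6], 1.0)
        assert sm[0, 0, 0] == 0.0

    def test_spatial_kernel_shrinks_at_border(self):
        frames = np.full((1, 5, 5), 4.0, np.float32)
        sm = _spatial_mean_3x3(frames)
        # averaging available neighbours only: constant stays constant
        assert np.allclose(sm, 4.0)

    def test_zero_phase_peak_preserved(self):
        rate = 10.0
        n = 1200
        t = np.arange(n) / rate
        sig = np.sin(2 * np.pi * 0.3 * t)
        m = _movie(np.tile(sig[:, None, None], (1, 4, 4)) + 2.0, rate)
        out = filter_movie(m)
        mid = slice(200, 1000)  # away from edges
        in_peaks = np.flatnonzero(
            (sig[1:-1] > sig[:-2]) & (sig[1:-1] >= sig[2:])
        ) + 1
        trace = out.data[:, 2, 2]
        for p in in_peaks:
            if mid.start < p < mid.stop:
                w = trace[p - 3 : p + 4]
                assert np.argmax(w) == 3  # local peak at the same frame

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        m = _movie(rng.uniform(0, 10, (3000, 4, 4)))
        fwd = filter_movie(m).data
        mrev = _movie(m.data[::-1])
        rev = filter_movie(mrev).data[::-1]
        scale = np.abs(fwd).max()
        assert np.abs(fwd - rev).max() <= 1e-6 * scale

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, (700, 4, 4))
        y = rng.uniform(0, 10, (700, 4, 4))
        fa = filter_movie(_movie(2 * x + 3 * y)).data
        fb = 2 * filter_movie(_movie(x)).data + 3 * filter_movie(_movie(y)).data
        assert np.abs(fa - fb).max() <= 1e-4 * np.abs(fa).max()

    def test_band_validation(self):
        m = _movie(np.ones((100, 4, 4)))
        with pytest.raises(ValueError, match="Nyquist"):
            filter_movie(m, band_hz=(0.025, 6.0))

    def test_per_pixel_mean_removed(self, small_recording):
        movie, *_ = small_recording
        out = filter_movie(movie)
        resid = np.abs(out.data.mean(axis=0, dtype=np.float64)).max()
        assert resid < 1e-6 * out.data.std(dtype=np.float64)
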