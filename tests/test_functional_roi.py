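import numpy as np
import pytest

from prebotseq.functional_roi import (
    CorrelationMap,
    correlation_image,
    detect_rois,
    normalized_xcorr_max,
)
from prebotseq.signal_conditioning import FilteredMovie, IntegratedLfp


def _brute_force_xcorr(x, y, lag_range):
    """Independent oracle: per-lag Pearson via np.corrcoef, explicit loops."""
    n = len(x)
    best_cc, best_lag = -np.inf, lag_range[0]
    for lag in range(lag_range[0], lag_range[1] + 1):
        xs = x[: n - lag] if lag else x
        ys = y[lag:]
        if np.std(xs) == 0 or np.std(ys) == 0:
            cc = 0.0
        else:
            cc = float(np.corrcoef(xs, ys)[0, 1])
        if cc > best_cc:
            best_cc, best_lag = cc, lag
    return best_cc, best_lag


def _fm(data, rate=10.0):
    data = np.asarray(data, np.float32)
    data = data - data.mean(axis=0, keepdims=True)
    return FilteredMovie(data, np.arange(data.shape[0]) / rate, (0.025, 1.5), 3, rate)


def _ilfp(values, rate=10.0):
    values = np.asarray(values, float)
    return IntegratedLfp(values, np.arange(values.size) / rate, 0.15,
                         float(np.std(values)), rate)


def test_self_correlation_is_one_at_lag_zero(rng):
    x = rng.normal(0, 1, 200)
    cc, lag = normalized_xcorr_max(x, x, (0, 20))
    assert cc == pytest.approx(1.0, abs=1e-12)
    assert lag == 0


def test_known_shift_recovered(rng):
    t = np.arange(400)
    x = np.exp(-(((t % 50) - 10.0) ** 2) / 18.0)  # periodic bumps
    y = np.roll(x, 7)
    cc, lag = normalized_xcorr_max(x, y, (0, 40))
    assert lag == 7
    assert cc > 0.99


def test_matches_brute_force_oracle_on_random_series(rng):
    for _ in range(50):
        n = int(rng.integers(60, 120))
        hi = int(rng.integers(5, 20))
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        got = normalized_xcorr_max(x, y, (0, hi))
        want = _brute_force_xcorr(x, y, (0, hi))
        assert got[1] == want[1]
        assert got[0] == pytest.approx(want[0], abs=1e-12)


def test_null_distribution_stays_below_detection_threshold(rng):
    """Independent noise rarely reaches maxCC 0.2 at N=1000, lags 0-40."""
    n, trials = 1000, 500
    x = rng.normal(0, 1, (trials, n))
    y = rng.normal(0, 1, (trials, n))
    maxcc = np.full(trials, -np.inf)
    for lag in range(0, 41):
        xs = x[:, : n - lag] if lag else x
        ys = y[:, lag:]
        xs_c = xs - xs.mean(axis=1, keepdims=True)
        ys_c = ys - ys.mean(axis=1, keepdims=True)
        cc = (xs_c * ys_c).sum(axis=1) / (
            np.linalg.norm(xs_c, axis=1) * np.linalg.norm(ys_c, axis=1)
        )
        maxcc = np.maximum(maxcc, cc)
    assert np.mean(maxcc < 0.2) >= 0.95


def test_zero_variance_overlap_yields_zero():
    x = np.ones(100)
    y = np.arange(100.0)
    cc, lag = normalized_xcorr_max(x, y, (0, 5))
    assert cc == 0.0


def test_correlation_image_agrees_with_scalar(rng):
    data = rng.uniform(0, 5, (120, 6, 6))
    lfp = rng.uniform(0, 2, 120)
    fm = _fm(data)
    cmap = correlation_image(fm, _ilfp(lfp), (0, 15))
    for r in range(6):
        for c in range(6):
            cc, lag = normalized_xcorr_max(
                _ilfp(lfp).values, fm.data[:, r, c].astype(float), (0, 15)
            )
            assert cmap.maxcc[r, c] == pytest.approx(cc, abs=1e-9)
            assert cmap.best_lag_frames[r, c] == lag


def test_zero_movie_gives_zero_map():
    fm = _fm(np.zeros((100, 5, 5)))
    cmap = correlation_image(fm, _ilfp(np.random.default_rng(0).uniform(0, 1, 100)),
                             (0, 10))
    assert np.all(cmap.maxcc == 0)


def test_map_scale_invariance(rng):
    data = rng.uniform(0, 5, (150, 5, 5))
    lfp = rng.uniform(0, 2, 150)
    m1 = correlation_image(_fm(data), _ilfp(lfp), (0, 10))
    m5 = correlation_image(_fm(data * 5), _ilfp(lfp), (0, 10))
    np.testing.assert_allclose(m1.maxcc, m5.maxcc, atol=1e-6)
    # near-tied lags may flip within float tolerance; demand near-total agreement
    assert (m1.best_lag_frames == m5.best_lag_frames).mean() >= 0.95


def _disk_movie(rng, n=400, h=24, w=24, center=(12, 12), radius=3):
    """Movie with one disk carrying LFP-locked transients."""
    t = np.arange(n) / 10.0
    lfp = np.clip(np.sin(2 * np.pi * 0.25 * t), 0, None) ** 3
    sig = np.convolve(lfp, np.exp(-np.arange(30) / 8.0))[:n]
    data = rng.normal(0, 0.3, (n, h, w))
    yy, xx = np.mgrid[:h, :w]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    data[:, disk] += 3 * sig[:, None]
    return _fm(data), _ilfp(lfp), disk


def test_lfp_locked_disk_lights_up(rng):
    fm, ilfp, disk = _disk_movie(rng)
    cmap = correlation_image(fm, ilfp, (0, 40))
    assert cmap.maxcc[disk].min() > 0.5
    assert np.median(cmap.maxcc[~disk]) < 0.2


def test_detect_rois_empty_map():
    zeros = CorrelationMap(np.zeros((20, 20)), np.zeros((20, 20), int), (0, 40))
    fm = _fm(np.zeros((100, 20, 20)))
    assert detect_rois(zeros, fm) == []


def test_detect_rois_threshold_monotonicity(rng):
    fm, ilfp, _ = _disk_movie(rng)
    cmap = correlation_image(fm, ilfp, (0, 40))
    counts = [len(detect_rois(cmap, fm, threshold=thr))
              for thr in (0.1, 0.2, 0.4, 0.6, 0.8)]
    assert counts == sorted(counts, reverse=True)


def test_two_close_cells_yield_one_roi(rng):
    """Two planted cells 4 px apart violate the 7x7 non-overlap rule."""
    n, h, w = 400, 24, 24
    t = np.arange(n) / 10.0
    lfp = np.clip(np.sin(2 * np.pi * 0.25 * t), 0, None) ** 3
    sig = np.convolve(lfp, np.exp(-np.arange(30) / 8.0))[:n]
    data = rng.normal(0, 0.3, (n, h, w))
    for cy, cx in ((12, 10), (12, 14)):
        yy, xx = np.mgrid[:h, :w]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= 4
        data[:, disk] += 3 * sig[:, None]
    fm = _fm(data)
    cmap = correlation_image(fm, _ilfp(lfp), (0, 40))
    rois = detect_rois(cmap, fm)
    assert len(rois) == 1


def test_roi_recovery_on_small_recording(small_run):
    """Most planted rhythmic cells get an ROI within 2 px of their centre."""
    from prebotseq.benchmark import match_rois

    truth = small_run.truth
    n_rhythmic = sum(1 for t in truth.cell_types if t != "NonRhythmic")
    mapping = match_rois(small_run, truth)
    rhythmic_hits = {ci for ci in mapping.values()
                     if truth.cell_types[ci] != "NonRhythmic"}
    assert len(rhythmic_hits) >= 0.7 * n_rhythmic
    # every ROI trace correlates with the LFP at or above the threshold
    assert min(r.maxcc for r in small_run.rois) >= 0.2


def test_roi_windows_inside_image(small_run):
    for roi in small_run.rois:
        r, c = roi.center
        assert 3 <= r <= 60 and 3 <= c <= 60
        assert roi.trace.size == small_run.rois[0].trace.size
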