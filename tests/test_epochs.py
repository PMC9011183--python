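import numpy as np
import pytest

from pupilresp import epochs as ep
from pupilresp import preprocess as pp
from pupilresp.simulate import SimConfig, simulate_recording

from conftest import make_events, make_recording


def constant_trace(value=4.0, n_windows=400, subject="test"):
    return pp.CleanTrace(subject, 100 * np.arange(n_windows), np.full(n_windows, value),
                         np.full(n_windows, 50))


class TestEpoch:
    def test_one_row_per_event(self):
        trace = constant_trace(n_windows=1200)
        ev = make_events(2000 + 4000 * np.arange(26))
        es = ep.epoch(trace, ev)
        assert es.n_trials == 26

    def test_constant_trace_gives_constant_epochs(self):
        es = ep.epoch(constant_trace(4.2), make_events([2000, 6000]))
        assert np.allclose(es.epochs, 4.2)
        assert es.epochs.shape == (2, 30)

    def test_grid_contains_bin_at_onset(self):
        # a step exactly at onset must land in the relative-time-0 bin
        pupil = np.full(3000, 4.0)
        pupil[1000:] = 5.0  # step at 2000 ms (sample grid, dt=2)
        trace = pp.preprocess_pipeline(make_recording(pupil))
        es = ep.epoch(trace, make_events([2000]))
        assert 0 in es.times
        i0 = np.where(es.times == 0)[0][0]
        assert es.epochs[0, i0 - 1] == pytest.approx(4.0)
        assert es.epochs[0, i0] == pytest.approx(5.0)

    def test_event_near_edge_dropped_with_warning(self):
        trace = constant_trace(n_windows=50)
        with pytest.warns(UserWarning, match="edge"):
            es = ep.epoch(trace, make_events([200, 2500]))
        assert es.n_trials == 1


class TestBaseline:
    def test_constant_baseline_subtracted(self):
        es = ep.epoch(constant_trace(4.0), make_events([2000]))
        out = ep.baseline_correct(es)
        assert out.baseline_mean[0] == pytest.approx(4.0)
        assert np.allclose(out.epochs, 0.0)

    def test_window_spans_ten_bins(self):
        es = ep.epoch(constant_trace(), make_events([2000]))
        assert es.window_mask(ep.BASELINE_START_MS, ep.BASELINE_END_MS).sum() == 10

    def test_missing_aware_baseline_mean(self):
        es = ep.epoch(constant_trace(), make_events([2000]))
        es.epochs[0, :] = np.nan
        m = es.window_mask(-800, 200)
        idx = np.where(m)[0]
        es.epochs[0, idx[0]] = 4.0
        es.epochs[0, idx[1]] = 4.2
        out = ep.baseline_correct(es)
        assert out.baseline_mean[0] == pytest.approx(4.1)

    def test_baseline_window_mean_is_zero_after_correction(self, rng):
        es = ep.epoch(constant_trace(), make_events(2000 + 4000 * np.arange(5)))
        es.epochs[:] = rng.normal(4.0, 0.3, es.epochs.shape)
        out = ep.baseline_correct(es)
        m = out.window_mask(-800, 200)
        assert np.allclose(out.epochs[:, m].mean(axis=1), 0.0, atol=1e-12)


class TestExclusion:
    def _es(self, n=20):
        es = ep.epoch(constant_trace(n_windows=100 + 41 * n), make_events(2000 + 4000 * np.arange(n)))
        return ep.baseline_correct(es)

    def test_fully_missing_stimulus_window_excluded(self):
        es = self._es(4)
        es.epochs[1, es.window_mask(0, 1000)] = np.nan
        kept, frac = ep.exclude_invalid_trials(es)
        assert kept.n_trials == 3
        assert frac == pytest.approx(0.25)

    def test_single_surviving_bin_retains_trial(self):
        es = self._es(4)
        m = es.window_mask(0, 1000)
        es.epochs[1, m] = np.nan
        es.epochs[1, np.where(m)[0][5]] = 0.1
        kept, frac = ep.exclude_invalid_trials(es)
        assert kept.n_trials == 4 and frac == 0.0

    def test_reported_fraction(self):
        es = self._es(20)
        for i in (3, 8, 15):
            es.epochs[i, es.window_mask(0, 1000)] = np.nan
        _, frac = ep.exclude_invalid_trials(es)
        assert frac == pytest.approx(0.15)

    def test_all_excluded_warns(self):
        es = self._es(3)
        es.epochs[:, es.window_mask(0, 1000)] = np.nan
        with pytest.warns(UserWarning, match="all"):
            kept, frac = ep.exclude_invalid_trials(es)
        assert kept.n_trials == 0 and frac == 1.0


class TestConditionAverageAndPeaks:
    def test_identical_trials_average_to_one_trial(self):
        es = ep.epoch(constant_trace(4.4), make_events([2000, 6000]))
        assert np.allclose(ep.condition_average(es), es.epochs[0])

    def test_hand_mean_and_missing_awareness(self):
        es = ep.epoch(constant_trace(), make_events([2000, 6000]))
        es.epochs[0, :] = 0.1
        es.epochs[1, :] = 0.3
        assert np.allclose(ep.condition_average(es), 0.2)
        es.epochs[0, 3] = np.nan
        assert ep.condition_average(es)[3] == pytest.approx(0.3)

    def test_peak_polarities(self):
        times = np.arange(-1000, 2000, 100)
        flat = np.zeros(30)
        assert ep.peak_response(flat, times, "constriction") == 0.0
        assert ep.peak_response(flat, times, "dilation") == 0.0
        dip = flat.copy()
        dip[15] = -0.35
        assert ep.peak_response(dip, times, "constriction") == pytest.approx(-0.35)
        rise = flat.copy()
        rise[15] = 0.2
        assert ep.peak_response(rise, times, "dilation") == pytest.approx(0.2)

    def test_peak_ignores_pre_search_window(self):
        times = np.arange(-1000, 2000, 100)
        tr = np.zeros(30)
        tr[times < 200] = -9.9  # outside the search window
        tr[20] = -0.1
        assert ep.peak_response(tr, times, "constriction") == pytest.approx(-0.1)

    def test_empty_search_window_flagged(self):
        times = np.arange(-1000, 2000, 100)
        tr = np.full(30, np.nan)
        with pytest.warns(UserWarning, match="search window"):
            assert np.isnan(ep.peak_response(tr, times, "constriction"))

    def test_peak_magnitude_monotone_in_injected_amplitude(self):
        peaks = []
        for amp in (-0.1, -0.2, -0.4, -0.8):
            cfg = SimConfig(seed=11, trials={"sun": 5}, amplitudes={"sun": amp},
                            noise_sd=0.0, hippus_amp=0.0, trial_amp_sd=0.0,
                            blink_rate_per_min=0.0)
            rec, ev, _ = simulate_recording(cfg)
            trace = pp.preprocess_pipeline(rec)
            es = ep.baseline_correct(ep.epoch(trace, ev))
            peaks.append(ep.peak_response(ep.condition_average(es), es.times, "constriction"))
        assert all(a > b for a, b in zip(peaks, peaks[1:]))


class TestNormalizeAndResting:
    def test_ratio(self):
        out = ep.normalize_by_plr({"sun": -0.3, "bright": -0.6})
        assert out["sun"] == pytest.approx(-0.5)
        assert out["bright"] == pytest.approx(-1.0)

    def test_scale_invariance(self, rng):
        peaks = {"sun": -0.31, "scrambled": -0.19, "bright": -0.62}
        for c in rng.uniform(0.2, 5.0, 5):
            scaled = ep.normalize_by_plr({k: c * v for k, v in peaks.items()})
            base = ep.normalize_by_plr(peaks)
            assert scaled == pytest.approx(base)

    def test_zero_light_response_flagged(self):
        with pytest.warns(UserWarning, match="light-response"):
            assert ep.normalize_by_plr({"sun": -0.3, "bright": 0.0}) == {}

    def test_resting_diameter_is_mean_of_trial_baselines(self):
        es1 = ep.baseline_correct(ep.epoch(constant_trace(3.7), make_events([2000])))
        es2 = ep.baseline_correct(ep.epoch(constant_trace(3.9), make_events([2000])))
        assert ep.resting_diameter([es1, es2]) == pytest.approx(3.8)
        assert ep.resting_diameter([es1]) == pytest.approx(3.7)
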