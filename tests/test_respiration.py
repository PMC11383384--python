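import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import chirp

import sniffsync as ss
from sniffsync.respiration import RespirationFrequencySeries
from sniffsync.synthetic import StateSchedule
from sniffsync.vigilance import Hypnogram

FS = 400.0


def _series(values, shift=0.05):
    values = np.asarray(values, dtype=float)
    centers = 0.5 + np.arange(values.size) * shift
    return RespirationFrequencySeries(centers, values, 1.0, shift)


class TestFrequencyEstimator:
    @pytest.mark.parametrize("f0", [2.5, 5.0])
    def test_pure_sinusoid(self, f0):
        t = np.arange(int(10 * FS)) / FS
        est = ss.estimate_frequency(np.sin(2 * np.pi * f0 * t), FS)
        assert np.nanmax(np.abs(est.dominant_frequency - f0)) < 0.05

    def test_sinusoid_grid_error_below_lag_quantum(self):
        """Wherever the 1-s window holds at least 2.5 cycles (2.5-13 Hz) the
        error stays under one autocorrelation lag quantum; below that the
        prescribed detrending interacts with the partial cycle and only a
        0.1 Hz absolute bound holds."""
        t = np.arange(int(6 * FS)) / FS
        for f0 in np.arange(1.5, 13.01, 0.5):
            est = ss.estimate_frequency(np.sin(2 * np.pi * f0 * t), FS)
            err = np.nanmax(np.abs(est.dominant_frequency - f0))
            if f0 >= 2.5:
                lag = FS / f0
                quantum = FS / (lag - 1) - FS / lag  # Hz per one-sample lag step
                assert err < quantum, f0
            else:
                assert err < 0.1, f0

    def test_chirp_tracking(self):
        """Rolling estimates track a 4->10 Hz linear chirp within 0.5 Hz."""
        t = np.arange(int(10 * FS)) / FS
        x = chirp(t, f0=4.0, f1=10.0, t1=10.0, method="linear")
        est = ss.estimate_frequency(x, FS)
        truth = 4.0 + (10.0 - 4.0) * est.window_centers / 10.0
        ok = np.isfinite(est.dominant_frequency)
        assert np.mean(np.abs(est.dominant_frequency[ok] - truth[ok])) < 0.5

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_amplitude_invariance(self, scale):
        """Standardization makes the estimate scale-invariant (to float
        rounding in the standardization itself)."""
        t = np.arange(int(3 * FS)) / FS
        x = np.sin(2 * np.pi * 6.0 * t) + 0.1 * np.sin(2 * np.pi * 12.0 * t)
        a = ss.estimate_frequency(x, FS).dominant_frequency
        b = ss.estimate_frequency(scale * x, FS).dominant_frequency
        assert np.allclose(a, b, atol=1e-6, equal_nan=True)

    def test_constant_window_yields_missing(self):
        x = np.ones(int(3 * FS))
        est = ss.estimate_frequency(x, FS)
        assert np.all(np.isnan(est.dominant_frequency))


class TestInhalationPeaks:
    def test_sine_troughs(self):
        t = np.arange(int(10 * FS)) / FS
        pk = ss.detect_inhalation_peaks(np.sin(2 * np.pi * 5 * t), FS)
        inner = pk.peak_times[(pk.peak_times > 1) & (pk.peak_times < 9)]
        offs = (inner - 0.15) % 0.2
        assert np.minimum(offs, 0.2 - offs).max() < 0.005

    def test_noisy_generator_recovery(self):
        """>=95% of truth inhalation times matched within +-5 ms."""
        sched = StateSchedule.constant("wake", 60.0)
        resp, truth = ss.generate_respiration(sched, None, FS, seed=2)
        rng = np.random.default_rng(0)
        noisy = resp + 0.1 * rng.standard_normal(resp.size)
        pk = ss.detect_inhalation_peaks(noisy, FS)
        d = np.abs(truth.inhalation_times[:, None] - pk.peak_times[None, :]).min(axis=1)
        assert np.mean(d <= 0.005) >= 0.95

    def test_white_noise_yields_near_empty_train(self):
        rng = np.random.default_rng(1)
        pk = ss.detect_inhalation_peaks(rng.standard_normal(int(30 * FS)), FS)
        assert len(pk) <= 5

    def test_flat_signal_empty(self):
        assert len(ss.detect_inhalation_peaks(np.zeros(int(5 * FS)), FS)) == 0


class TestRelativeError:
    def test_identical_series_zero(self):
        x = _series(np.full(50, 5.0))
        summary = ss.relative_error(x, x)
        assert summary.population_mean == 0.0
        assert summary.population_sd == 0.0

    def test_printed_formula_arithmetic(self):
        th = _series(np.full(50, 5.2))
        fl = _series(np.full(50, 5.0))
        summary = ss.relative_error(th, fl)
        assert summary.per_trial_mean_error[0] == pytest.approx(0.04)

    def test_population_stats_mirror_construction(self):
        """21 trials with per-trial error eps ~ N(0.016, 0.009) recover the
        construction's mean and SD."""
        rng = np.random.default_rng(42)
        eps = rng.normal(0.016, 0.009, size=21)
        flow = [_series(np.full(40, 5.0)) for _ in eps]
        thor = [_series(np.full(40, 5.0 * (1 + e))) for e in eps]
        summary = ss.relative_error(thor, flow)
        assert summary.population_mean == pytest.approx(eps.mean(), abs=1e-12)
        assert summary.population_sd == pytest.approx(eps.std(ddof=1), abs=1e-12)
        assert summary.population_mean == pytest.approx(0.016, abs=0.006)
        assert summary.population_sd == pytest.approx(0.009, abs=0.005)

    def test_missing_windows_excluded_and_counted(self):
        th = _series([5.0, 5.0, 5.0, 5.0])
        fl = _series([5.0, np.nan, 5.0, 5.0])
        summary = ss.relative_error(th, fl)
        assert summary.n_excluded_windows == 1


class TestPeakLag:
    def test_identical_trains(self):
        train = ss.InhalationPeakTrain(np.arange(30) * 0.2)
        res = ss.peak_lag(train, train)
        assert res["mean"] == 0.0 and res["sd"] == 0.0

    def test_sixty_ms_shift_sign_convention(self):
        """Thoracic 60 ms after flow: mean lag is -0.060 s (flow precedes)."""
        flow = ss.InhalationPeakTrain(np.arange(30) * 0.2 + 1.0)
        thor = ss.InhalationPeakTrain(flow.peak_times + 0.060)
        res = ss.peak_lag(flow, thor)
        assert res["mean"] == pytest.approx(-0.060, abs=1e-12)

    def test_missing_thoracic_peaks_unpaired(self):
        flow = ss.InhalationPeakTrain(np.arange(30) * 0.2 + 1.0)
        keep = np.arange(30) % 3 != 2
        thor = ss.InhalationPeakTrain(flow.peak_times[keep] + 0.06)
        res = ss.peak_lag(flow, thor)
        assert res["n_unpaired_flow"] == 10
        assert len(res["lags"]) == 20

    def test_disjoint_trains_error(self):
        a = ss.InhalationPeakTrain(np.arange(10) * 0.2)
        b = ss.InhalationPeakTrain(np.arange(10) * 0.2 + 100.0)
        with pytest.raises(ValueError, match="not concurrent"):
            ss.peak_lag(a, b)


class TestBoutTrials:
    def test_short_baseline_discarded(self):
        freq = _series(np.full(200, 6.0))
        bouts = ss.EventTrack([ss.Event("exploration_bout", 2.0, 4.0)])
        trials = ss.extract_bout_trials(freq, bouts)
        assert trials.n_trials == 0 and trials.n_discarded == 1

    def test_baseline_and_exploration_means(self):
        centers = 0.5 + np.arange(300) * 0.05
        vals = np.where((centers >= 8.0) & (centers < 10.0), 11.0, 6.0)
        freq = RespirationFrequencySeries(centers, vals, 1.0, 0.05)
        bouts = ss.EventTrack([ss.Event("exploration_bout", 8.0, 10.0)])
        trials = ss.extract_bout_trials(freq, bouts)
        assert trials.baseline_frequency[0] == pytest.approx(6.0)
        assert trials.exploration_frequency[0] == pytest.approx(11.0)
        assert trials.exploration_frequency[0] - trials.baseline_frequency[0] == \
            pytest.approx(5.0)

    def test_generator_bout_effect_recovered(self):
        """Injected +3 Hz sniff increase over 50 trials, paired test significant."""
        from scipy import stats

        plan = [(10.0 + 10.0 * k, 1.5) for k in range(50)]
        cfg = ss.SessionConfig(duration_s=520.0, seed=21, bout_plan=plan,
                               bout_increment_hz=3.0)
        sess, _ = ss.generate_session(cfg)
        freq = ss.estimate_frequency(sess.record.channel("Resp"), FS)
        trials = ss.extract_bout_trials(freq, sess.events)
        assert trials.n_trials == 50
        delta = trials.exploration_frequency - trials.baseline_frequency
        assert delta.mean() == pytest.approx(3.0, abs=0.3)
        p = stats.ttest_rel(trials.exploration_frequency,
                            trials.baseline_frequency).pvalue
        assert p < 0.05


class TestIntersniff:
    def test_constant_train_all_nrem(self):
        hyp = Hypnogram(np.arange(12) * 5.0, np.array(["NREM"] * 12, dtype=object))
        peaks = ss.InhalationPeakTrain(np.arange(1.0, 59.0, 0.2))
        dist = ss.intersniff_stats(peaks, hyp)
        assert np.allclose(dist.intervals["NREM"], 0.2)
        assert dist.mean_frequency["NREM"] == pytest.approx(5.0)

    def test_boundary_interval_assigned_to_earlier_peak_state(self):
        labels = np.array(["wake"] * 2 + ["NREM"] * 2, dtype=object)
        hyp = Hypnogram(np.arange(4) * 5.0, labels)
        # interval straddling the 10 s boundary: earlier peak in wake
        peaks = ss.InhalationPeakTrain(np.array([9.8, 10.2, 10.4]))
        dist = ss.intersniff_stats(peaks, hyp)
        assert np.allclose(dist.intervals["wake"], [0.4])
        assert np.allclose(dist.intervals["NREM"], [0.2])

    def test_generator_state_frequencies_recovered(self, sleep_session):
        """Per-state mean rates recovered within +-0.3 Hz of the generator's
        own intersniff truth (the reciprocal-of-mean-interval definition;
        under cycle jitter this is the harmonic mean of cycle rates, a
        little below the planted wake 7 / NREM 3 / REM 3.3 Hz centers)."""
        sess, truth = sleep_session
        rec = sess.record
        hyp = ss.score_states(
            np.vstack([rec.channel("EEG1"), rec.channel("EEG2")]),
            rec.channel("EMG"), FS,
        )
        peaks = ss.detect_inhalation_peaks(rec.channel("Resp"), FS)
        dist = ss.intersniff_stats(peaks, hyp)
        # truth reference: same statistic from the exact inhalation times
        tt = truth.respiration.inhalation_times
        states = truth.respiration.states[(tt[:-1] * FS).astype(int)]
        for state in ("wake", "NREM", "REM"):
            iv = np.diff(tt)[states == state]
            expected = 1.0 / iv.mean()
            assert dist.mean_frequency[state] == pytest.approx(expected, abs=0.3)
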