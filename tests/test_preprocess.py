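"""Preprocessing: z-score fitting/leakage, CAR, notch cascade response,
artifact screening, and trial windowing."""

import hashlib

import numpy as np
import pytest

from scbam.core import Recording, make_event_table, make_grid_montage
from scbam.exceptions import FlaggedChannelError, InvalidArgumentError
from scbam.preprocess import (
    apply_car,
    apply_normalizer,
    apply_notch_cascade,
    detect_artifacts,
    fit_normalizer,
    reject_run,
    window_trials,
)


def _rec(signal, fs=600.0, run_id=1):
    n_ch = signal.shape[0]
    return Recording(signal, fs, make_grid_montage(1, n_ch, 8.6), run_id=run_id)


class TestNormalizer:
    def test_two_point_channel_stats(self):
        rec = _rec(np.array([[1.0, 3.0]]))
        stats = fit_normalizer([rec])
        assert stats.mean[0] == pytest.approx(2.0)
        assert stats.sd[0] == pytest.approx(1.0)
        test = apply_normalizer(_rec(np.array([[5.0]])), stats)
        assert test.signal[0, 0] == pytest.approx(3.0)

    def test_training_data_normalizes_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        recs = [_rec(rng.normal(3.0, 2.0, size=(4, 500))) for _ in range(3)]
        stats = fit_normalizer(recs)
        z = np.concatenate([apply_normalizer(r, stats).signal for r in recs], axis=1)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_constant_channel_flagged_with_index(self):
        sig = np.random.default_rng(1).normal(size=(3, 100))
        sig[1] = 7.0
        with pytest.raises(FlaggedChannelError) as err:
            fit_normalizer([_rec(sig)])
        assert err.value.channels == [1]

    def test_stats_independent_of_test_runs(self):
        """No leakage: the fitted statistics hash identically no matter
        what the test-run data look like."""
        rng = np.random.default_rng(2)
        train = [_rec(rng.normal(size=(4, 300)))]
        stats = fit_normalizer(train)
        digest = hashlib.sha256(stats.mean.tobytes() + stats.sd.tobytes()).hexdigest()
        _ = _rec(rng.normal(size=(4, 300)) * 100)  # unrelated test data
        stats2 = fit_normalizer(train)
        digest2 = hashlib.sha256(stats2.mean.tobytes() + stats2.sd.tobytes()).hexdigest()
        assert digest == digest2


class TestCAR:
    def test_common_mode_removed(self):
        rec = _rec(np.full((4, 50), 3.7))
        np.testing.assert_allclose(apply_car(rec).signal, 0.0)

    def test_two_channel_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([5.0, 0.0, -1.0])
        out = apply_car(_rec(np.vstack([a, b]))).signal
        np.testing.assert_allclose(out[0], (a - b) / 2)
        np.testing.assert_allclose(out[1], (b - a) / 2)

    def test_column_means_vanish(self):
        rec = _rec(np.random.default_rng(3).normal(size=(4, 100)))
        out = apply_car(rec).signal
        assert np.abs(out.mean(axis=0)).max() < 1e-12

    def test_idempotent(self):
        rec = _rec(np.random.default_rng(4).normal(size=(5, 200)))
        once = apply_car(rec).signal
        twice = apply_car(apply_car(rec)).signal
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(InvalidArgumentError):
            apply_car(_rec(np.zeros((1, 10))))


class TestNotchCascade:
    fs = 600.0
    t = np.arange(int(10 * fs)) / fs

    def _sine(self, f):
        return _rec(np.tile(np.sin(2 * np.pi * f * self.t), (2, 1)), fs=self.fs)

    @pytest.mark.parametrize("f", [60.0, 120.0, 180.0, 240.0])
    def test_notch_frequencies_attenuated(self, f):
        out = apply_notch_cascade(self._sine(f)).signal
        # >= 40 dB attenuation (RMS of unit sinusoid is 1/sqrt(2))
        assert np.sqrt(np.mean(out[0, 600:-600] ** 2)) < 0.01 / np.sqrt(2) * np.sqrt(2)

    def test_passband_preserved(self):
        out = apply_notch_cascade(self._sine(10.0)).signal
        rms = np.sqrt(np.mean(out[0, 600:-600] ** 2))
        assert rms == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 3000))
        y1 = apply_notch_cascade(_rec(3.0 * x, fs=self.fs)).signal
        y2 = 3.0 * apply_notch_cascade(_rec(x, fs=self.fs)).signal
        np.testing.assert_allclose(y1, y2, atol=1e-9)

    def test_harmonic_at_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            apply_notch_cascade(self._sine(10.0), line_hz=150.0, n_harmonics=2)


class TestArtifactScreening:
    def test_single_spike_flags_only_its_channel(self):
        rng = np.random.default_rng(6)
        sig = rng.normal(size=(16, 6000))
        sig[3, 1234] = 12.0  # 12 sigma spike
        flags = detect_artifacts(_rec(sig))
        bad = flags.loc[flags["flagged"], "channel"].unique()
        np.testing.assert_array_equal(bad, [3])
        # one bad channel of 16 (6.25%) stays under the 10% rule
        assert not reject_run(flags, 16, channel_frac=0.10)

    def test_many_bad_channels_reject_run(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(size=(20, 6000))
        for ch in range(3):  # 3/20 = 15% > 10%
            sig[ch, 100 + ch] = 15.0
        flags = detect_artifacts(_rec(sig))
        assert reject_run(flags, 20, channel_frac=0.10)

    def test_clean_run_kept(self):
        import pandas as pd

        empty = pd.DataFrame(columns=["channel", "segment", "start_sample",
                                      "max_abs_z", "flagged"])
        assert not reject_run(empty, 256)

    def test_threshold_boundary_fraction(self):
        """30 bad channels out of 256 (11.7%) exceed the 10% rule."""
        rng = np.random.default_rng(8)
        sig = rng.normal(size=(256, 3000))
        for ch in range(30):
            sig[ch, 50] = 20.0
        flags = detect_artifacts(_rec(sig))
        assert reject_run(flags, 256, channel_frac=0.10)


class TestWindowing:
    def _run_with_trials(self, durations, n_samples=20000):
        sig = np.arange(2 * n_samples, dtype=float).reshape(2, n_samples)
        onsets = np.cumsum([100] + [d + 100 for d in durations[:-1]])
        events = make_event_table(onsets, durations, [1] * len(durations),
                                  np.arange(1, len(durations) + 1))
        return _rec(sig), events

    def test_standard_trial_yields_nine_windows(self):
        rec, events = self._run_with_trials([3000])
        ws = window_trials(rec, events, 600, 300)
        assert ws.n_windows == 9
        assert (ws.labels == 1).all()
        assert (ws.trial_ids == 1).all()

    def test_exact_fit_single_window(self):
        rec, events = self._run_with_trials([600])
        assert window_trials(rec, events, 600, 300).n_windows == 1

    def test_window_onsets_enumerated(self):
        rec, events = self._run_with_trials([1200])
        ws = window_trials(rec, events, 600, 300)
        assert ws.n_windows == 3
        onset = events["onset_sample"].iloc[0]
        # first sample of each window matches onsets 0, 300, 600 into the trial
        np.testing.assert_allclose(
            ws.data[:, 0, 0], rec.signal[0, [onset, onset + 300, onset + 600]])

    def test_window_longer_than_trial_rejected(self):
        rec, events = self._run_with_trials([500])
        with pytest.raises(InvalidArgumentError):
            window_trials(rec, events, 600, 300)

    def test_windows_inherit_labels_and_trials(self):
        rec, events = self._run_with_trials([3000, 3000])
        events["label"] = [2, 5]
        ws = window_trials(rec, events, 600, 300)
        assert ws.n_windows == 18
        assert set(ws.labels[:9]) == {2} and set(ws.labels[9:]) == {5}
        assert len(set(ws.trial_ids)) == 2
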