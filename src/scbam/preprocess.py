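"""Preprocessing: z-score normalization, CAR, notch cascade, artifact
rejection, and trial windowing.

Every fitted statistic (the per-channel z-score mean/SD) comes from
training runs only and is applied unchanged to test runs. Filters are
applied zero-phase (forward-backward), which doubles the effective
filter order; this is an offline pipeline, so the zero phase delay is
worth the extra roll-off.

Processing order follows the acquisition narrative: z-score, then common
average reference, then the notch cascade. Epochs use 0-based half-open
sample intervals [onset, onset + duration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import Recording, validate_events
from .exceptions import FlaggedChannelError, InvalidArgumentError

__all__ = [
    "NormalizerStats",
    "WindowSet",
    "fit_normalizer",
    "apply_normalizer",
    "apply_car",
    "apply_notch_cascade",
    "detect_artifacts",
    "reject_run",
    "window_trials",
    "preprocess_run",
]


@dataclass(frozen=True)
class NormalizerStats:
    """Per-channel mean and SD estimated from the training runs."""

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class WindowSet:
    """Fixed-length analysis windows cut from task trials.

    ``data`` is windows x channels x window_len; every window carries the
    label and trial_id of its parent trial plus the run it came from.
    """

    data: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    run_ids: np.ndarray
    window_len: int
    step: int
    split_tag: str = ""

    def __post_init__(self):
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.trial_ids) == len(self.run_ids) == n):
            raise InvalidArgumentError("window metadata lengths must match data")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    def subset(self, mask, split_tag: str | None = None) -> "WindowSet":
        mask = np.asarray(mask)
        return WindowSet(
            self.data[mask], self.labels[mask], self.trial_ids[mask],
            self.run_ids[mask], self.window_len, self.step,
            self.split_tag if split_tag is None else split_tag,
        )


def fit_normalizer(recordings_train) -> NormalizerStats:
    """Estimate per-channel mean/SD over the concatenated training runs."""
    recs = list(recordings_train)
    if not recs:
        raise InvalidArgumentError("training list must be nonempty")
    signal = np.concatenate([r.signal for r in recs], axis=1)
    mean = signal.mean(axis=1)
    sd = signal.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise FlaggedChannelError(bad.tolist())
    return NormalizerStats(mean, sd)


def apply_normalizer(rec: Recording, stats: NormalizerStats) -> Recording:
    z = (rec.signal - stats.mean[:, None]) / stats.sd[:, None]
    return rec.copy_with(z)


def apply_car(rec: Recording) -> Recording:
    """Common average reference: subtract the instantaneous cross-channel mean."""
    if rec.n_channels < 2:
        raise InvalidArgumentError("CAR needs at least 2 channels")
    return rec.copy_with(rec.signal - rec.signal.mean(axis=0, keepdims=True))


def _notch_sos(line_hz: float, n_harmonics: int, order: int,
               half_width_hz: float, fs: float) -> list:
    freqs = [line_hz * k for k in range(1, n_harmonics + 1)]
    for f in freqs:
        if f + half_width_hz >= fs / 2:
            raise InvalidArgumentError(
                f"notch at {f} Hz reaches Nyquist ({fs / 2} Hz)"
            )
    return [
        sps.butter(order, [f - half_width_hz, f + half_width_hz],
                   btype="bandstop", fs=fs, output="sos")
        for f in freqs
    ]


def apply_notch_cascade(rec: Recording, line_hz: float = 60.0,
                        n_harmonics: int = 4, order: int = 4,
                        half_width_hz: float = 1.0) -> Recording:
    """Butterworth band-stop cascade at the line frequency and harmonics.

    Default removes 60/120/180/240 Hz with a +-1 Hz stop band each.
    ``order`` is the Butterworth design order per notch; zero-phase
    application squares the magnitude response.
    """
    x = rec.signal
    for sos in _notch_sos(line_hz, n_harmonics, order, half_width_hz, rec.fs):
        x = sps.sosfiltfilt(sos, x, axis=1)
    return rec.copy_with(x)


def detect_artifacts(rec: Recording, z_thresh: float = 6.0,
                     segment_s: float = 1.0) -> pd.DataFrame:
    """Flag (channel, segment) cells whose peak |z| exceeds the threshold.

    The run is cut into non-overlapping segments of ``segment_s`` seconds;
    each channel is z-scored against its own run-wide mean/SD and a segment
    is flagged when its largest absolute z-score exceeds ``z_thresh``.
    Returns a table with columns channel, segment, start_sample, max_abs_z,
    flagged.
    """
    seg_n = int(round(segment_s * rec.fs))
    if seg_n < 1:
        raise InvalidArgumentError("segment must contain at least 1 sample")
    mu = rec.signal.mean(axis=1, keepdims=True)
    sd = rec.signal.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = np.abs((rec.signal - mu) / sd)
    n_seg = rec.n_samples // seg_n
    rows = []
    for s in range(n_seg):
        block = z[:, s * seg_n:(s + 1) * seg_n].max(axis=1)
        for ch in range(rec.n_channels):
            rows.append((ch, s, s * seg_n, block[ch], block[ch] > z_thresh))
    return pd.DataFrame(
        rows, columns=["channel", "segment", "start_sample", "max_abs_z", "flagged"]
    )


def reject_run(flags: pd.DataFrame, n_channels: int,
               channel_frac: float = 0.10) -> bool:
    """True if the run should be rejected: a channel is bad when it has at
    least one flagged segment, and the run is dropped when more than
    ``channel_frac`` of channels are bad."""
    if len(flags) == 0:
        return False
    bad_channels = flags.loc[flags["flagged"], "channel"].nunique()
    return bad_channels / n_channels > channel_frac


def window_trials(rec: Recording, events: pd.DataFrame,
                  window_len: int = 600, step: int = 300,
                  split_tag: str = "") -> WindowSet:
    """Cut each trial into overlapping fixed-length windows.

    A 3000-sample (5 s at 600 Hz) trial with 600-sample windows and a 300
    sample step yields floor((3000 - 600)/300) + 1 = 9 windows, each
    inheriting the trial's label and trial_id.
    """
    if step < 1:
        raise InvalidArgumentError("step must be >= 1")
    validate_events(events, rec.n_samples)
    data, labels, trial_ids = [], [], []
    for row in events.itertuples(index=False):
        dur = int(row.duration_samples)
        if window_len > dur:
            raise InvalidArgumentError(
                f"window_len {window_len} exceeds trial duration {dur}"
            )
        n_win = (dur - window_len) // step + 1
        for k in range(n_win):
            start = int(row.onset_sample) + k * step
            data.append(rec.signal[:, start:start + window_len])
            labels.append(int(row.label))
            trial_ids.append(int(row.trial_id))
    data = np.stack(data) if data else np.empty((0, rec.n_channels, window_len))
    return WindowSet(
        data, np.asarray(labels, dtype=int), np.asarray(trial_ids, dtype=int),
        np.full(len(labels), rec.run_id, dtype=int), window_len, step, split_tag,
    )


def preprocess_run(rec: Recording, stats: NormalizerStats,
                   line_hz: float = 60.0, n_harmonics: int = 4,
                   notch_order: int = 4, half_width_hz: float = 1.0) -> Recording:
    """z-score -> CAR -> notch cascade, with pre-fitted normalizer stats."""
    rec = apply_normalizer(rec, stats)
    rec = apply_car(rec)
    return apply_notch_cascade(rec, line_hz, n_harmonics, notch_order, half_width_hz)
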