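"""Synthetic ultra-high-density EEG with controllable finger-class separability.

The generator emulates a cued finger-extension session recorded with a
dense electrode grid (default 16 x 16 electrodes at 8.6 mm pitch, 600 Hz):
each run opens with a 30 s baseline, then alternates rests of 3-4 s with
5 s task periods, five cues per finger per run in pseudo-random order.

Signal model per channel: 1/f-shaped Gaussian background noise, plus one
band-limited oscillator per finger class mixed through a Gaussian spatial
patch on the grid whose envelope rises by ``effect_size`` during that
class's task periods (an event-related synchronisation), plus coherent
line noise at 60 Hz and its harmonics, plus sparse high-amplitude
artifact spikes. With ``effect_size = 0`` the class-conditional signal
distributions are identical, so any downstream decoder is at chance.
Adjacent class patches are adjacent on the grid, so misclassifications
concentrate among neighbouring fingers as in real recordings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    EVENT_COLUMNS,
    Montage,
    Recording,
    make_event_table,
    make_grid_montage,
    validate_events,
)
from .exceptions import FormatError, InvalidArgumentError

__all__ = [
    "SimSpec",
    "make_grid_montage",
    "default_source_centers",
    "simulate_run",
    "simulate_session",
    "write_fixture",
    "read_fixture",
    "events_to_tsv",
]

#: canonical per-class source bands (Hz): mu, beta, low gamma, high gamma,
#: super-high gamma — one rhythm per finger so classes separate in both the
#: spatial and the spectral axis of the feature map.
DEFAULT_SOURCE_BANDS = ((8.0, 12.0), (12.0, 30.0), (30.0, 50.0),
                        (75.0, 115.0), (125.0, 150.0))


def default_source_centers(n_rows: int, n_cols: int, n_classes: int):
    """Per-class patch centers in (row, col) grid units.

    Adjacent classes occupy adjacent grid cells along the middle row when
    the grid is wide enough; on small grids the centers are spread evenly
    over the grid diagonal instead.
    """
    if n_cols >= n_classes:
        r = (n_rows - 1) / 2.0
        c0 = (n_cols - n_classes) / 2.0
        return [(r, c0 + k) for k in range(n_classes)]
    t = (np.arange(n_classes) + 1.0) / (n_classes + 1.0)
    return [(ti * (n_rows - 1), ti * (n_cols - 1)) for ti in t]


@dataclass
class SimSpec:
    """Parameters of one simulated recording session."""

    n_subjects: int = 1
    n_runs: int = 10
    trials_per_run: int = 25
    task_s: float = 5.0
    rest_s_range: tuple = (3.0, 4.0)
    baseline_s: float = 30.0
    fs: float = 600.0
    n_classes: int = 5
    effect_size: float = 1.0
    source_bands: tuple = DEFAULT_SOURCE_BANDS
    source_centers: list | None = None  # (row, col) grid units; None = default
    patch_sigma_mm: float = 10.0
    source_amp: float = 0.5  # oscillator SD at patch center, rest-state
    line_hz: float = 60.0
    n_line_harmonics: int = 4
    line_amp: float = 0.5
    artifact_rate: float = 5e-5  # probability per channel-second
    artifact_amp: float = 20.0  # in units of noise_sd
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self, montage: Montage) -> None:
        if self.trials_per_run % self.n_classes != 0:
            raise InvalidArgumentError(
                "trials_per_run must be divisible by n_classes (balanced cueing)"
            )
        if self.effect_size < 0:
            raise InvalidArgumentError("effect_size must be >= 0")
        if len(self.source_bands) < self.n_classes:
            raise InvalidArgumentError("need a source band per class")
        max_edge = max(hi for _, hi in self.source_bands[: self.n_classes])
        if self.fs <= 2 * max_edge:
            raise InvalidArgumentError(
                f"band edge {max_edge} Hz at or above Nyquist ({self.fs / 2} Hz)"
            )
        if self.rest_s_range[0] > self.rest_s_range[1] or self.rest_s_range[0] < 0:
            raise InvalidArgumentError("invalid rest_s_range")


def _pink_noise(rng, n_channels: int, n_samples: int, sd: float) -> np.ndarray:
    """Gaussian noise with 1/f power spectrum, per-channel SD = sd."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** -0.5  # amplitude ~ f^-1/2 gives power ~ 1/f
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return sd * x / std


def _band_limited_oscillator(rng, n_samples: int, band, fs: float) -> np.ndarray:
    """Unit-SD band-limited Gaussian process."""
    lo, hi = band
    if hi >= fs / 2:
        raise InvalidArgumentError(f"band edge {hi} Hz >= Nyquist {fs / 2} Hz")
    x = rng.standard_normal(n_samples)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    s = y.std()
    return y / s if s > 0 else y


def _run_schedule(spec: SimSpec, rng):
    """Sample the cue order and rest durations; return (labels, onsets, n_samples).

    The recording length is exactly baseline + sum(rests) + sum(tasks) in
    samples, so the event bookkeeping closes without rounding slack.
    """
    reps = spec.trials_per_run // spec.n_classes
    labels = np.repeat(np.arange(1, spec.n_classes + 1), reps)
    rng.shuffle(labels)
    task_n = int(round(spec.task_s * spec.fs))
    rest_n = np.round(
        rng.uniform(spec.rest_s_range[0], spec.rest_s_range[1], spec.trials_per_run)
        * spec.fs
    ).astype(int)
    onsets = np.empty(spec.trials_per_run, dtype=int)
    cursor = int(round(spec.baseline_s * spec.fs))
    for i in range(spec.trials_per_run):
        cursor += rest_n[i]
        onsets[i] = cursor
        cursor += task_n
    return labels, onsets, task_n, cursor


def simulate_run(spec: SimSpec, montage: Montage | None = None,
                 run_index: int = 0, subject_id: str = "sim"):
    """Simulate one run; returns (Recording, EventTable).

    Deterministic given (spec.seed, run_index, subject_id): each run draws
    from an independent child stream of the session seed.
    """
    if montage is None:
        montage = make_grid_montage(16, 16, 8.6)
    spec.validate(montage)
    if run_index < 0 or run_index >= spec.n_runs:
        raise InvalidArgumentError("run_index out of range")
    sub_key = zlib.crc32(subject_id.encode()) % (2 ** 31)
    rng = np.random.default_rng([spec.seed, sub_key, run_index])

    labels, onsets, task_n, n_samples = _run_schedule(spec, rng)
    n_ch = montage.n_channels
    x = _pink_noise(rng, n_ch, n_samples, spec.noise_sd)

    centers = spec.source_centers
    if centers is None:
        centers = default_source_centers(montage.n_rows, montage.n_cols,
                                         spec.n_classes)
    t_idx = np.arange(n_samples)
    for c in range(spec.n_classes):
        osc = _band_limited_oscillator(rng, n_samples, spec.source_bands[c], spec.fs)
        env = np.ones(n_samples)
        for onset, lab in zip(onsets, labels):
            if lab == c + 1:
                env[onset:onset + task_n] = 1.0 + spec.effect_size
        row, col = centers[c]
        center_xy = np.array([col * montage.pitch_mm, -row * montage.pitch_mm])
        d2 = np.sum((montage.coords - center_xy) ** 2, axis=1)
        weights = np.exp(-d2 / (2.0 * spec.patch_sigma_mm ** 2))
        x += spec.source_amp * weights[:, None] * (env * osc)[None, :]

    if spec.line_amp > 0:
        t = t_idx / spec.fs
        for k in range(1, spec.n_line_harmonics + 1):
            f_k = spec.line_hz * k
            if f_k >= spec.fs / 2:
                break
            phase = rng.uniform(0, 2 * np.pi)
            x += (spec.line_amp / k) * np.sin(2 * np.pi * f_k * t + phase)[None, :]

    if spec.artifact_rate > 0:
        duration_s = n_samples / spec.fs
        n_art = rng.poisson(spec.artifact_rate * n_ch * duration_s)
        width = max(int(0.05 * spec.fs), 3)  # ~50 ms transient
        bump = np.hanning(width)
        for _ in range(n_art):
            ch = rng.integers(0, n_ch)
            start = rng.integers(0, max(n_samples - width, 1))
            sign = rng.choice([-1.0, 1.0])
            x[ch, start:start + width] += sign * spec.artifact_amp * spec.noise_sd * bump

    events = make_event_table(
        onsets, np.full(spec.trials_per_run, task_n), labels,
        run_index * spec.trials_per_run + np.arange(1, spec.trials_per_run + 1),
    )
    rec = Recording(x, spec.fs, montage, run_id=run_index + 1, subject_id=subject_id)
    return rec, events


def simulate_session(spec: SimSpec, montage: Montage | None = None,
                     subject_id: str = "sim"):
    """Simulate all runs of one subject; returns list of (Recording, EventTable)."""
    if montage is None:
        montage = make_grid_montage(16, 16, 8.6)
    return [simulate_run(spec, montage, r, subject_id) for r in range(spec.n_runs)]


# ---------------------------------------------------------------------------
# HDF5 fixture I/O
#
# Layout: /signal (channels x samples, float64), /events (n x 4 int64 in
# EVENT_COLUMNS order); root attrs: fs, pitch_mm, n_rows, n_cols, run_id,
# subject_id, origin_label. Round trips are bit-exact.
# ---------------------------------------------------------------------------

def write_fixture(recording: Recording, events: pd.DataFrame, path) -> None:
    validate_events(events, recording.n_samples)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=recording.signal)
        f.create_dataset("events", data=events[EVENT_COLUMNS].to_numpy(np.int64))
        f.attrs["fs"] = recording.fs
        f.attrs["pitch_mm"] = recording.montage.pitch_mm
        f.attrs["n_rows"] = recording.montage.n_rows
        f.attrs["n_cols"] = recording.montage.n_cols
        f.attrs["run_id"] = recording.run_id
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["origin_label"] = recording.montage.origin_label


def read_fixture(path):
    """Read a single-run fixture; returns (Recording, EventTable)."""
    with h5py.File(path, "r") as f:
        for key in ("signal", "events"):
            if key not in f:
                raise FormatError(f"fixture missing dataset '/{key}'")
        for attr in ("fs", "pitch_mm", "n_rows", "n_cols"):
            if attr not in f.attrs:
                raise FormatError(f"fixture missing attribute {attr!r}")
        signal = f["signal"][()]
        raw_events = f["events"][()]
        if raw_events.ndim != 2 or raw_events.shape[1] != len(EVENT_COLUMNS):
            raise FormatError("dataset '/events' must have 4 columns")
        montage = make_grid_montage(
            int(f.attrs["n_rows"]), int(f.attrs["n_cols"]), float(f.attrs["pitch_mm"]),
            origin_label=str(f.attrs.get("origin_label", "Cz")),
        )
        rec = Recording(
            signal, float(f.attrs["fs"]), montage,
            run_id=int(f.attrs.get("run_id", 0)),
            subject_id=str(f.attrs.get("subject_id", "sim")),
        )
    events = pd.DataFrame(raw_events, columns=EVENT_COLUMNS)
    try:
        validate_events(events, rec.n_samples)
    except InvalidArgumentError as err:
        raise FormatError(f"invalid events table: {err}") from err
    return rec, events


def events_to_tsv(events: pd.DataFrame, fs: float, path) -> None:
    """Export events in BIDS-style TSV (onset, duration in seconds, trial_type)."""
    out = pd.DataFrame({
        "onset": events["onset_sample"] / fs,
        "duration": events["duration_samples"] / fs,
        "trial_type": events["label"].map(lambda c: f"finger_{c}"),
    })
    out.to_csv(path, sep="\t", index=False)
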