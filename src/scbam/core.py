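"""Core containers shared by the generator and the processing stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

EVENT_COLUMNS = ["onset_sample", "duration_samples", "label", "trial_id"]


@dataclass(frozen=True)
class Montage:
    """Regular electrode grid.

    Electrodes are ordered row-major; ``coords`` holds per-electrode
    (x, y) positions in millimetres, x increasing with column and y
    decreasing with row (grids attached sequentially downward from the
    origin electrode).
    """

    n_rows: int
    n_cols: int
    pitch_mm: float
    coords: np.ndarray
    origin_label: str = "Cz"

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols


def make_grid_montage(n_rows: int, n_cols: int, pitch_mm: float,
                      origin_label: str = "Cz") -> Montage:
    """Build a regular grid montage with the given inter-electrode pitch."""
    if n_rows < 1 or n_cols < 1:
        raise InvalidArgumentError("grid dimensions must be >= 1")
    if pitch_mm <= 0:
        raise InvalidArgumentError("pitch must be positive")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack([
        cols.ravel() * float(pitch_mm),
        -rows.ravel() * float(pitch_mm),
    ])
    return Montage(int(n_rows), int(n_cols), float(pitch_mm), coords, origin_label)


@dataclass
class Recording:
    """Continuous multichannel signal with montage and identity."""

    signal: np.ndarray  # channels x samples, microvolt scale
    fs: float
    montage: Montage
    run_id: int = 0
    subject_id: str = "sim"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise InvalidArgumentError("signal must be channels x samples")
        if self.montage is not None and self.signal.shape[0] != self.montage.n_channels:
            raise InvalidArgumentError(
                f"channel count {self.signal.shape[0]} does not match montage "
                f"({self.montage.n_channels})"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def copy_with(self, signal: np.ndarray) -> "Recording":
        return Recording(signal, self.fs, self.montage, self.run_id, self.subject_id)


def make_event_table(onsets, durations, labels, trial_ids) -> pd.DataFrame:
    """Assemble a trial event table (one row per cued extension)."""
    df = pd.DataFrame({
        "onset_sample": np.asarray(onsets, dtype=np.int64),
        "duration_samples": np.asarray(durations, dtype=np.int64),
        "label": np.asarray(labels, dtype=np.int64),
        "trial_id": np.asarray(trial_ids, dtype=np.int64),
    })
    return df


def validate_events(events: pd.DataFrame, n_samples: int | None = None,
                    n_classes: int = 5) -> None:
    """Check event-table invariants; raise InvalidArgumentError on violation."""
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise InvalidArgumentError(f"event table missing column {col!r}")
    if len(events) and events["trial_id"].duplicated().any():
        raise InvalidArgumentError("trial_id values must be unique")
    if len(events) and not events["label"].between(1, n_classes).all():
        raise InvalidArgumentError(f"labels must lie in 1..{n_classes}")
    if n_samples is not None and len(events):
        ends = events["onset_sample"] + events["duration_samples"]
        if (events["onset_sample"] < 0).any() or (ends > n_samples).any():
            raise InvalidArgumentError("event extends beyond signal end")
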