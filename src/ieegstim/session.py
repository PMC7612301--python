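"""Session-level containers: multichannel recording plus stimulation events.

A :class:`SessionRecording` bundles everything one stimulation session
carries: the raw multichannel signal (microvolts), the stimulation event
table, electrode coordinates, the subject's brain-surface point cloud and
session metadata. Event tables are plain :class:`pandas.DataFrame` objects
with the columns in :data:`EVENT_COLUMNS`; time is expressed in seconds from
the first sample, and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

EVENT_COLUMNS = ("onset", "duration", "amplitude", "frequency", "anode", "cathode")

#: Nyquist must clear the gamma upper edge (55 Hz).
MIN_SAMPLING_RATE = 110.0


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check an event table: required columns, increasing onsets, positive durations."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event table missing columns: {missing}")
    if len(events) == 0:
        return events
    onsets = events["onset"].to_numpy(float)
    durations = events["duration"].to_numpy(float)
    if not np.all(np.diff(onsets) > 0):
        raise ValidationError("event onsets must be strictly increasing")
    if not np.all(durations > 0):
        raise ValidationError("event durations must be positive")
    offsets = onsets + durations
    if np.any(onsets[1:] < offsets[:-1]):
        raise ValidationError("consecutive events overlap")
    return events


@dataclass
class SessionRecording:
    """One stimulation session: signals, events and metadata.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sampling_rate
        Sampling frequency in Hz; must exceed twice the 55 Hz gamma edge.
    channel_labels
        One label per signal row.
    channel_coords
        ``(n_channels, 3)`` electrode positions in millimetres.
    events
        Stimulation event table (see :data:`EVENT_COLUMNS`).
    brain_surface
        ``(n_points, 3)`` point cloud of the brain surface in millimetres.
    start_timestamp
        Session start, seconds since the epoch.
    """

    signals: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    events: pd.DataFrame
    subject_id: str = "S000"
    session_id: str = "sess0"
    task_label: str = "task"
    start_timestamp: float = 0.0
    channel_coords: np.ndarray | None = None
    brain_surface: np.ndarray | None = None
    stim_channels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValidationError("signals must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValidationError("one channel label per signal row required")
        if not np.all(np.isfinite(self.signals)):
            raise ValidationError("signals contain non-finite values")
        if self.sampling_rate <= MIN_SAMPLING_RATE:
            raise ValidationError(
                f"sampling_rate must exceed {MIN_SAMPLING_RATE} Hz to resolve gamma"
            )
        validate_events(self.events)
        labels = set(self.channel_labels)
        for col in ("anode", "cathode"):
            unknown = set(self.events[col]) - labels if len(self.events) else set()
            if unknown:
                raise ValidationError(f"unknown {col} labels in events: {sorted(unknown)}")
        if len(self.events):
            ends = self.events["onset"] + self.events["duration"]
            if float(ends.max()) > self.duration:
                raise ValidationError("events extend beyond the recorded signal")
        if not self.stim_channels and len(self.events):
            self.stim_channels = tuple(
                sorted(set(self.events["anode"]) | set(self.events["cathode"]))
            )

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError as exc:
            raise ValidationError(f"unknown channel label {label!r}") from exc
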