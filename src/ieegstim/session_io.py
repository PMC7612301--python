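"""Reading and writing sessions and derived tables.

Signals travel as plain EDF (16-bit, one-second data records, per-channel
physical range set to the observed min/max so quantisation error is
minimal); events as a tab-separated table; metadata, surface points and run
manifests as JSON; derived tables as CSV. Reading goes through MNE's native
EDF reader; writing uses a small EDF encoder implemented here.

The exact sample count is recorded in the metadata JSON so the final,
zero-padded EDF record can be trimmed on read, making the round trip
lossless up to 16-bit quantisation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .session import EVENT_COLUMNS, SessionRecording

EVENT_TSV_COLUMNS = (
    "onset_s",
    "duration_s",
    "amplitude_mA",
    "frequency_Hz",
    "anode",
    "cathode",
)


# ---------------------------------------------------------------------------
# EDF encoding


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    signals: np.ndarray,
    sampling_rate: float,
    channel_labels: tuple[str, ...],
) -> None:
    """Write microvolt signals as a plain EDF file.

    Uses one-second data records; the signal is zero-padded to a whole
    number of records (callers record the true sample count elsewhere).
    """
    signals = np.asarray(signals, dtype=np.float64)
    n_ch, n_samples = signals.shape
    fs = int(round(sampling_rate))
    if abs(sampling_rate - fs) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    n_records = int(np.ceil(n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samples] = signals

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _ascii_field("0", 8)  # version
    header += _ascii_field("X X X X", 80)  # patient id (anonymised)
    header += _ascii_field("Startdate X X X X", 80)  # recording id
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(256 * (1 + n_ch), 8)  # header bytes
    header += _ascii_field("", 44)  # reserved
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)  # record duration, s
    header += _ascii_field(n_ch, 4)
    for ch in channel_labels:
        header += _ascii_field(ch, 16)
    header += b"".join(_ascii_field("iEEG", 80) for _ in range(n_ch))
    header += b"".join(_ascii_field("uV", 8) for _ in range(n_ch))
    for v in phys_min:
        header += _ascii_field(f"{v:.2f}"[:8], 8)
    for v in phys_max:
        header += _ascii_field(f"{v:.2f}"[:8], 8)
    header += b"".join(_ascii_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_ascii_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_ascii_field("", 80) for _ in range(n_ch))  # prefilter
    header += b"".join(_ascii_field(fs, 8) for _ in range(n_ch))
    header += b"".join(_ascii_field("", 32) for _ in range(n_ch))  # reserved

    # re-read the printed physical range so digital scaling matches the header
    pmin = np.array([float(f"{v:.2f}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.2f}"[:8]) for v in phys_max])
    scale = (dig_max - dig_min) / (pmax - pmin)
    digital = np.clip(
        np.round((padded - pmin[:, None]) * scale[:, None] + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read an EDF file; returns (signals in µV, sampling rate, labels)."""
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of ValueError/OSError
        raise FormatError(f"unreadable EDF file {path}: {exc}") from exc
    signals = raw.get_data() * 1e6  # volts -> microvolts
    return signals, float(raw.info["sfreq"]), tuple(raw.ch_names)


# ---------------------------------------------------------------------------
# session round trip


def write_session(
    recording: SessionRecording,
    signal_path: str | Path,
    events_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write one session as EDF + events TSV + metadata JSON."""
    write_edf(
        signal_path, recording.signals, recording.sampling_rate, recording.channel_labels
    )
    events = recording.events.rename(
        columns=dict(zip(EVENT_COLUMNS, EVENT_TSV_COLUMNS))
    )
    events.to_csv(events_path, sep="\t", index=False)
    meta = {
        "subject_id": recording.subject_id,
        "session_id": recording.session_id,
        "task_label": recording.task_label,
        "start_timestamp": recording.start_timestamp,
        "n_samples": recording.n_samples,
        "sampling_rate": recording.sampling_rate,
        "channel_labels": list(recording.channel_labels),
        "channel_coords": None
        if recording.channel_coords is None
        else np.asarray(recording.channel_coords).tolist(),
        "brain_surface": None
        if recording.brain_surface is None
        else np.asarray(recording.brain_surface).tolist(),
        "stim_channels": list(recording.stim_channels),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_session(
    signal_path: str | Path,
    events_path: str | Path,
    meta_path: str | Path,
) -> SessionRecording:
    """Read and validate a session written by :func:`write_session`.

    Channel labels in the event table are resolved against the EDF labels;
    the sampling rate comes from the EDF header.
    """
    signals, fs, labels = read_edf(signal_path)
    try:
        meta = json.loads(Path(meta_path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unparsable metadata JSON {meta_path}: {exc}") from exc
    try:
        events = pd.read_csv(events_path, sep="\t")
    except Exception as exc:
        raise FormatError(f"unparsable event table {events_path}: {exc}") from exc
    missing = [c for c in EVENT_TSV_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table missing columns {missing}")
    events = events.rename(columns=dict(zip(EVENT_TSV_COLUMNS, EVENT_COLUMNS)))

    n_samples = int(meta.get("n_samples", signals.shape[1]))
    signals = signals[:, :n_samples]
    coords = meta.get("channel_coords")
    surface = meta.get("brain_surface")
    return SessionRecording(
        signals=signals,
        sampling_rate=fs,
        channel_labels=labels,
        events=events,
        subject_id=meta.get("subject_id", "S000"),
        session_id=meta.get("session_id", "sess0"),
        task_label=meta.get("task_label", "task"),
        start_timestamp=float(meta.get("start_timestamp", 0.0)),
        channel_coords=None if coords is None else np.asarray(coords, float),
        brain_surface=None if surface is None else np.asarray(surface, float),
        stim_channels=tuple(meta.get("stim_channels", ())),
    )


# ---------------------------------------------------------------------------
# derived tables


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write derived tables as CSV plus a JSON run manifest.

    ``tables`` maps a table name to a DataFrame; an empty frame yields a
    header-only CSV. The manifest records the software version and whatever
    the caller supplies (config hash, seed, ...).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory {out}: {exc}") from exc
    written: dict[str, Path] = {}
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        written[name] = path
    from . import __version__

    manifest_data = {"software_version": __version__, **(manifest or {})}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest_data, indent=1, default=str))
    written["manifest"] = manifest_path
    return written
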