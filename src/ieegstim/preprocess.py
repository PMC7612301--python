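"""Segment extraction, detrending, artifact-channel exclusion and re-referencing.

The analysis works on 1-second pre/post windows around every stimulation
trial: pre ends 50 ms before stimulation onset, post starts 50 ms after
stimulation offset. Matching pseudo-trials are placed inside baseline
epochs — inter-stimulus intervals at least 20 s long, trimmed 5 s away from
stimulation on each side — in groups of three, mimicking the grouped trial
timing of the session, so stimulation and baseline contribute comparable
numbers of pairs.

Channels showing a repeated post-stimulation voltage deflection are
excluded; the remaining channels are common-average re-referenced, with the
stimulation channels excluded from the average but still re-referenced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .errors import ProcessingError, ValidationError
from .session import SessionRecording

logger = logging.getLogger(__name__)

SEGMENT_LENGTH = 1.0  # s
EVENT_BUFFER = 0.05  # s between a segment and the stimulation event
MIN_BASELINE_INTERVAL = 20.0  # s, minimum inter-stimulus interval
BASELINE_GUARD = 5.0  # s trimmed from each side of a baseline interval
GROUP_GAP = 10.0  # s; offset-to-onset gaps < 10 s keep trials in one group


class BaselineEpoch(NamedTuple):
    """A stimulation-free interval ``[start, end)`` in seconds."""

    start: float
    end: float

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class Segment:
    """A 1-s multichannel window.

    ``pair_id`` links each ``pre`` to its ``post``; ``group_id`` indexes the
    trial (or pseudo-trial) triple the window belongs to.
    """

    samples: np.ndarray  # channels x n, microvolts
    channel_labels: tuple[str, ...]
    role: str  # "pre" | "post"
    condition: str  # "stimulation" | "baseline"
    pair_id: int
    group_id: int

    def __post_init__(self) -> None:
        if self.role not in ("pre", "post"):
            raise ValidationError(f"invalid segment role {self.role!r}")
        if self.condition not in ("stimulation", "baseline"):
            raise ValidationError(f"invalid segment condition {self.condition!r}")


@dataclass
class ChannelMask:
    """Per-channel validity after artifact screening."""

    valid: dict[str, bool]
    reasons: dict[str, str]

    def valid_labels(self) -> list[str]:
        return [ch for ch, ok in self.valid.items() if ok]

    def excluded_labels(self) -> list[str]:
        return [ch for ch, ok in self.valid.items() if not ok]


def find_baseline_epochs(
    events: pd.DataFrame, recording_duration: float
) -> list[BaselineEpoch]:
    """Baseline epochs: inter-stimulus intervals >= 20 s, trimmed 5 s per side.

    The recording edges count as interval boundaries (with the same guard),
    so a stimulation-free recording yields one epoch ``[5, duration - 5)``.
    """
    if len(events) == 0:
        bounds = [(0.0, recording_duration)]
    else:
        onsets = events["onset"].to_numpy(float)
        offsets = onsets + events["duration"].to_numpy(float)
        bounds = [(0.0, onsets[0])]
        bounds += [(offsets[i], onsets[i + 1]) for i in range(len(events) - 1)]
        bounds.append((offsets[-1], recording_duration))
    epochs = []
    for start, end in bounds:
        if end - start >= MIN_BASELINE_INTERVAL:
            epochs.append(BaselineEpoch(start + BASELINE_GUARD, end - BASELINE_GUARD))
    return epochs


def _slice(recording: SessionRecording, start: float) -> np.ndarray:
    """Extract a 1-s window starting at `start` seconds (half-open)."""
    fs = recording.sampling_rate
    i0 = int(round(start * fs))
    return recording.signals[:, i0 : i0 + int(round(fs))]


def assign_groups(events: pd.DataFrame) -> np.ndarray:
    """Group ids: consecutive trials with offset-to-onset gap < 10 s share a group."""
    if len(events) == 0:
        return np.array([], dtype=int)
    onsets = events["onset"].to_numpy(float)
    offsets = onsets + events["duration"].to_numpy(float)
    gaps = onsets[1:] - offsets[:-1]
    return np.concatenate([[0], np.cumsum(gaps >= GROUP_GAP)]).astype(int)


def extract_stim_segments(recording: SessionRecording) -> list[Segment]:
    """Pre/post 1-s segments around each stimulation event.

    pre = ``[onset - 1.05, onset - 0.05)``, post = ``[offset + 0.05,
    offset + 1.05)``. Events too close to the recording edges are skipped
    with a warning rather than zero-padded.
    """
    events = recording.events
    groups = assign_groups(events)
    segments: list[Segment] = []
    span = SEGMENT_LENGTH + EVENT_BUFFER
    for i, row in enumerate(events.itertuples(index=False)):
        onset = float(row.onset)
        offset = onset + float(row.duration)
        if onset - span < 0 or offset + span > recording.duration:
            logger.warning("trial %d too close to recording edge; skipped", i)
            continue
        common = dict(
            channel_labels=recording.channel_labels,
            condition="stimulation",
            pair_id=i,
            group_id=int(groups[i]),
        )
        segments.append(
            Segment(samples=_slice(recording, onset - span).copy(), role="pre", **common)
        )
        segments.append(
            Segment(
                samples=_slice(recording, offset + EVENT_BUFFER).copy(),
                role="post",
                **common,
            )
        )
    return segments


def median_intra_group_gap(events: pd.DataFrame) -> float:
    """Median offset-to-onset gap between consecutive same-group trials."""
    if len(events) < 2:
        return 3.0
    onsets = events["onset"].to_numpy(float)
    offsets = onsets + events["duration"].to_numpy(float)
    gaps = onsets[1:] - offsets[:-1]
    within = gaps[gaps < GROUP_GAP]
    return float(np.median(within)) if within.size else 3.0


def extract_baseline_segments(
    recording: SessionRecording,
    epochs: Sequence[BaselineEpoch],
    stim_duration: float | None = None,
    group_size: int = 3,
    max_pairs: int | None = None,
) -> list[Segment]:
    """Baseline pre/post pseudo-trial segments mimicking the stimulation timing.

    Within each epoch pseudo-trials are laid out from the epoch start in
    groups of ``group_size``, with the pre/post windows separated exactly as
    around real trials (the pseudo-event lasts ``stim_duration``) and an
    intra-group spacing equal to the session's median intra-group trial gap.
    Extraction stops once the number of baseline pairs reaches the number of
    stimulation pairs (or ``max_pairs``), or when epochs run out.
    """
    if not epochs:
        raise ValidationError("no baseline epochs available")
    events = recording.events
    if stim_duration is None:
        if len(events) == 0:
            raise ValidationError("stim_duration required when session has no events")
        stim_duration = float(events["duration"].median())
    if max_pairs is None:
        max_pairs = len(events) if len(events) else 60
    spacing = median_intra_group_gap(events)
    span = SEGMENT_LENGTH + EVENT_BUFFER
    footprint = 2 * span + stim_duration  # pre + buffers + pseudo-event + post

    segments: list[Segment] = []
    pair_id = 0
    group_id = 0
    for epoch in epochs:
        if pair_id >= max_pairs:
            break
        t = epoch.start + span  # pseudo-onset of the first trial in the epoch
        in_group = 0
        while pair_id < max_pairs:
            pseudo_onset = t
            pseudo_offset = pseudo_onset + stim_duration
            if pseudo_offset + span > epoch.end:
                break
            common = dict(
                channel_labels=recording.channel_labels,
                condition="baseline",
                pair_id=pair_id,
                group_id=group_id,
            )
            segments.append(
                Segment(
                    samples=_slice(recording, pseudo_onset - span).copy(),
                    role="pre",
                    **common,
                )
            )
            segments.append(
                Segment(
                    samples=_slice(recording, pseudo_offset + EVENT_BUFFER).copy(),
                    role="post",
                    **common,
                )
            )
            pair_id += 1
            in_group += 1
            if in_group == group_size:
                group_id += 1
                in_group = 0
            t = pseudo_offset + spacing
        if in_group:
            group_id += 1
    return segments


def detrend_and_center(segment: Segment) -> Segment:
    """Remove each channel's least-squares line over time (centres and detrends).

    This is an orthogonal projection, hence idempotent.
    """
    detrended = scipy.signal.detrend(segment.samples, axis=-1, type="linear")
    return replace(segment, samples=detrended)


def _bonferroni_t_threshold(n_channels: int, n_trials: int, alpha: float = 0.05) -> float:
    return float(scipy.stats.t.ppf(1 - alpha / (2 * n_channels), df=n_trials - 1))


def detect_artifact_channels(
    stim_segments: Iterable[Segment],
    t1: float | None = None,
    t2_mult: float = 5.0,
    slope_alpha: float = 0.05,
    sampling_rate: float | None = None,
) -> ChannelMask:
    """Flag channels with repeated post-stimulation voltage deflections.

    Works on *raw* (not yet detrended) stimulation segments. A channel is
    excluded if either criterion holds:

    1. the paired t-statistic, across trials, of mean voltage over the first
       half of the post segment vs the second half of the pre segment exceeds
       ``t1`` in magnitude (default: Bonferroni-corrected two-sided critical
       value at alpha = 0.05 across channels);
    2. the trial-averaged post signal's second half has a linear-regression
       slope significantly different from zero (p < ``slope_alpha``) whose
       fitted line trends back toward the pre-segment mean voltage from a
       displacement exceeding ``t2_mult`` standard deviations of the
       trial-averaged pre signal.

    With fewer than 10 trial pairs every channel is kept and a warning logged.
    """
    segments = list(stim_segments)
    pre = [s for s in segments if s.role == "pre"]
    post = [s for s in segments if s.role == "post"]
    if not pre:
        raise ValidationError("no stimulation segments supplied")
    labels = pre[0].channel_labels
    n_trials = len(pre)
    if n_trials < 10:
        logger.warning(
            "only %d stimulation pairs; artifact screening skipped", n_trials
        )
        return ChannelMask({ch: True for ch in labels}, {})

    pre_arr = np.stack([s.samples for s in sorted(pre, key=lambda s: s.pair_id)])
    post_arr = np.stack([s.samples for s in sorted(post, key=lambda s: s.pair_id)])
    n = pre_arr.shape[-1]
    half = n // 2

    if t1 is None:
        t1 = _bonferroni_t_threshold(len(labels), n_trials)

    # criterion 1: paired t across trials, first half of post vs second half of pre
    post_first = post_arr[..., :half].mean(axis=-1)  # trials x channels
    pre_second = pre_arr[..., half:].mean(axis=-1)
    tstat = scipy.stats.ttest_rel(post_first, pre_second, axis=0).statistic

    # criterion 2: slow return of the trial-averaged post signal's second half
    avg_post = post_arr.mean(axis=0)  # channels x n
    avg_pre = pre_arr.mean(axis=0)
    pre_mean = avg_pre.mean(axis=-1)
    pre_sd = avg_pre.std(axis=-1, ddof=1)
    second = avg_post[:, half:]
    t_axis = np.arange(second.shape[-1]) / (sampling_rate or float(n))

    valid: dict[str, bool] = {}
    reasons: dict[str, str] = {}
    for c, ch in enumerate(labels):
        flagged = False
        if np.isfinite(tstat[c]) and abs(float(tstat[c])) > t1:
            flagged = True
            reasons[ch] = "paired-t deflection"
        else:
            res = scipy.stats.linregress(t_axis, second[c])
            displacement = res.intercept - pre_mean[c]
            returning = res.slope * displacement < 0  # heading back to pre level
            if (
                res.pvalue < slope_alpha
                and returning
                and abs(displacement) > t2_mult * pre_sd[c]
            ):
                flagged = True
                reasons[ch] = "slow return"
        valid[ch] = not flagged
    return ChannelMask(valid, reasons)


def common_average_rereference(
    segments: Iterable[Segment],
    mask: ChannelMask,
    stim_channels: Sequence[str] = (),
) -> list[Segment]:
    """Subtract the mean over valid, non-stimulation channels at every sample.

    Stimulation channels do not contribute to the average but receive it;
    artifact channels are dropped from the output entirely.
    """
    segments = list(segments)
    if not segments:
        return []
    labels = segments[0].channel_labels
    stim = set(stim_channels)
    keep_idx = [i for i, ch in enumerate(labels) if mask.valid.get(ch, True)]
    ref_idx = [
        i for i, ch in enumerate(labels) if mask.valid.get(ch, True) and ch not in stim
    ]
    if len(ref_idx) < 2:
        raise ProcessingError(
            "common average needs >= 2 valid non-stimulation channels"
        )
    kept_labels = tuple(labels[i] for i in keep_idx)
    out = []
    for seg in segments:
        car = seg.samples[ref_idx].mean(axis=0, keepdims=True)
        out.append(
            replace(seg, samples=seg.samples[keep_idx] - car, channel_labels=kept_labels)
        )
    return out
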