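"""Segment arithmetic, baseline epochs, detrending, artifacts, re-referencing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import events_frame
from ieegstim import preprocess as pp
from ieegstim.errors import ProcessingError
from ieegstim.session import SessionRecording
from ieegstim.synth import GeneratorConfig, generate_session


def make_recording(onsets, duration=0.5, total=None, n_channels=4, fs=500.0, seed=0):
    events = events_frame(onsets, duration=duration, anode="C1", cathode="C2")
    total = total or (max(onsets) + duration + 30 if onsets else 60)
    rng = np.random.default_rng(seed)
    return SessionRecording(
        signals=rng.standard_normal((n_channels, int(total * fs))),
        sampling_rate=fs,
        channel_labels=tuple(f"C{i+1}" for i in range(n_channels)),
        events=events,
    )


class TestBaselineEpochs:
    def test_thirty_second_interval_trimmed_to_twenty(self):
        # stimulation ends at t=100, next starts at t=130 -> epoch [105, 125)
        events = events_frame([99.5, 130.0], duration=0.5, anode="A", cathode="B")
        epochs = pp.find_baseline_epochs(events, 300.0)
        assert (105.0, 125.0) in [(e.start, e.end) for e in epochs]

    def test_interval_below_threshold_yields_no_epoch(self):
        events = events_frame([99.5, 119.9], duration=0.5, anode="A", cathode="B")
        inner = [
            e
            for e in pp.find_baseline_epochs(events, 125.0)
            if e.start > 100 and e.end < 120
        ]
        assert inner == []

    def test_no_events_gives_full_guarded_epoch(self):
        epochs = pp.find_baseline_epochs(events_frame([]), 100.0)
        assert [(e.start, e.end) for e in epochs] == [(5.0, 95.0)]

    def test_epochs_keep_guard_distance_from_events(self, null_session):
        epochs = pp.find_baseline_epochs(null_session.events, null_session.duration)
        onsets = null_session.events["onset"].to_numpy()
        offsets = onsets + null_session.events["duration"].to_numpy()
        for e in epochs:
            assert np.all((offsets + 5.0 <= e.start) | (onsets - 5.0 >= e.end))


class TestStimSegments:
    def test_window_arithmetic(self):
        rec = make_recording([50.0], duration=0.5, total=90)
        segs = pp.extract_stim_segments(rec)
        pre = next(s for s in segs if s.role == "pre")
        post = next(s for s in segs if s.role == "post")
        fs = rec.sampling_rate
        # pre [48.95, 49.95), post [50.55, 51.55)
        np.testing.assert_array_equal(
            pre.samples, rec.signals[:, int(48.95 * fs) : int(49.95 * fs)]
        )
        np.testing.assert_array_equal(
            post.samples, rec.signals[:, int(50.55 * fs) : int(51.55 * fs)]
        )
        assert pre.samples.shape[-1] == int(fs)

    def test_every_trial_yields_one_pair(self, null_session):
        segs = pp.extract_stim_segments(null_session)
        n_events = len(null_session.events)
        assert len(segs) == 2 * n_events
        pair_ids = {s.pair_id for s in segs}
        assert len(pair_ids) == n_events
        for pid in pair_ids:
            roles = sorted(s.role for s in segs if s.pair_id == pid)
            assert roles == ["post", "pre"]

    def test_grouping_rule(self):
        # three events 4 s apart then one 40 s later -> groups (0, 0, 0, 1)
        rec = make_recording([10.0, 14.0, 18.0, 58.0], total=100)
        segs = pp.extract_stim_segments(rec)
        by_pair = {s.pair_id: s.group_id for s in segs}
        assert [by_pair[i] for i in range(4)] == [0, 0, 0, 1]

    def test_edge_trial_skipped(self, caplog):
        rec = make_recording([0.5, 30.0], total=60)
        with caplog.at_level("WARNING"):
            segs = pp.extract_stim_segments(rec)
        assert {s.pair_id for s in segs} == {1}

    def test_segments_avoid_stimulation_interval(self, null_session):
        """No extracted window overlaps [onset - 0.05, offset + 0.05)."""
        fs = null_session.sampling_rate
        events = null_session.events
        segs = pp.extract_stim_segments(null_session)
        for s in segs:
            row = events.iloc[s.pair_id]
            if s.role == "pre":
                end = (row["onset"] - 0.05) * fs
                assert int(round(end)) - s.samples.shape[-1] >= 0
            else:
                start = (row["onset"] + row["duration"] + 0.05) * fs
                assert int(round(start)) + s.samples.shape[-1] <= null_session.n_samples


class TestBaselineSegments:
    def test_pre_post_interval_matches_stimulation(self):
        rec = make_recording([200.0], duration=0.5, total=400)
        epochs = [pp.BaselineEpoch(10.0, 150.0)]
        segs = pp.extract_baseline_segments(rec, epochs, stim_duration=0.5, max_pairs=3)
        pre = next(s for s in segs if s.role == "pre" and s.pair_id == 0)
        post = next(s for s in segs if s.role == "post" and s.pair_id == 0)
        # pre/post window starts differ by 1 s window + 0.1 s buffers + 0.5 s event
        assert post.samples.shape == pre.samples.shape

    def test_short_epoch_fits_one_long_stim_pair(self):
        # 12 s epoch, 4.6 s pseudo-event: footprint 6.7 s -> exactly one pair
        rec = make_recording([200.0], duration=0.5, total=400)
        segs = pp.extract_baseline_segments(
            rec, [pp.BaselineEpoch(20.0, 32.0)], stim_duration=4.6, max_pairs=10
        )
        assert len(segs) == 2  # one pre + one post

    def test_never_more_baseline_than_stim_pairs(self, null_session):
        epochs = pp.find_baseline_epochs(null_session.events, null_session.duration)
        segs = pp.extract_baseline_segments(null_session, epochs)
        assert len(segs) // 2 <= len(null_session.events)

    def test_groups_of_three(self, null_session):
        epochs = pp.find_baseline_epochs(null_session.events, null_session.duration)
        segs = pp.extract_baseline_segments(null_session, epochs)
        pre = [s for s in segs if s.role == "pre"]
        counts = pd.Series([s.group_id for s in pre]).value_counts()
        assert counts.max() <= 3


class TestDetrend:
    def test_pure_line_removed_exactly(self):
        t = np.linspace(0, 1, 500)
        seg = pp.Segment(
            samples=(3.0 + 2.0 * t)[None, :],
            channel_labels=("a",),
            role="pre",
            condition="baseline",
            pair_id=0,
            group_id=0,
        )
        out = pp.detrend_and_center(seg)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-10)

    def test_sinusoid_keeps_its_detrended_self(self):
        t = np.linspace(0, 1, 500)
        wave = np.sin(2 * np.pi * 3 * t)
        seg = pp.Segment(
            samples=(5.0 - 1.5 * t + wave)[None, :],
            channel_labels=("a",),
            role="pre",
            condition="baseline",
            pair_id=0,
            group_id=0,
        )
        out = pp.detrend_and_center(seg)
        # closed-form least squares of the sinusoid alone
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.lstsq(X, wave, rcond=None)[0]
        np.testing.assert_allclose(out.samples[0], wave - X @ beta, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_projection(self, seed):
        rng = np.random.default_rng(seed)
        seg = pp.Segment(
            samples=rng.standard_normal((3, 200)),
            channel_labels=("a", "b", "c"),
            role="pre",
            condition="baseline",
            pair_id=0,
            group_id=0,
        )
        once = pp.detrend_and_center(seg)
        twice = pp.detrend_and_center(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-9)
        assert np.abs(once.samples.mean(axis=-1)).max() < 1e-9


class TestArtifactDetection:
    def test_injected_artifact_channel_flagged(self):
        rec = generate_session(
            GeneratorConfig(n_channels=8, artifact_channels=("CH08",), rng_seed=11)
        )
        segs = pp.extract_stim_segments(rec)
        mask = pp.detect_artifact_channels(segs, sampling_rate=rec.sampling_rate)
        assert not mask.valid["CH08"]

    def test_false_positive_rate_bounded(self):
        """Stationary-noise channels survive screening in >= 95% of cases."""
        flags = []
        for seed in range(6):
            rec = generate_session(
                GeneratorConfig(n_channels=8, n_trials=30, rng_seed=100 + seed)
            )
            segs = pp.extract_stim_segments(rec)
            mask = pp.detect_artifact_channels(segs, sampling_rate=rec.sampling_rate)
            flags += [not v for v in mask.valid.values()]
        assert np.mean(flags) <= 0.05

    def test_all_zero_channel_not_flagged(self):
        rec = make_recording(list(np.arange(12) * 8.0 + 20.0), total=200, seed=1)
        rec.signals[2] = 0.0
        segs = pp.extract_stim_segments(rec)
        mask = pp.detect_artifact_channels(segs, sampling_rate=rec.sampling_rate)
        assert mask.valid["C3"]

    def test_too_few_trials_keeps_everything(self, caplog):
        rec = make_recording([30.0, 40.0], total=80)
        segs = pp.extract_stim_segments(rec)
        with caplog.at_level("WARNING"):
            mask = pp.detect_artifact_channels(segs)
        assert all(mask.valid.values())


class TestCommonAverage:
    def _segment(self, data, labels):
        return pp.Segment(
            samples=np.asarray(data, float),
            channel_labels=labels,
            role="pre",
            condition="stimulation",
            pair_id=0,
            group_id=0,
        )

    def test_mean_over_reference_channels_is_zero(self, rng):
        seg = self._segment(rng.standard_normal((5, 100)), tuple("abcde"))
        mask = pp.ChannelMask({ch: True for ch in "abcde"}, {})
        (out,) = pp.common_average_rereference([seg], mask, stim_channels=("a",))
        ref = [out.channel_labels.index(ch) for ch in "bcde"]
        np.testing.assert_allclose(out.samples[ref].mean(axis=0), 0.0, atol=1e-12)

    def test_two_channels_become_symmetric(self):
        seg = self._segment([[3.0] * 10, [1.0] * 10], ("a", "b"))
        mask = pp.ChannelMask({"a": True, "b": True}, {})
        (out,) = pp.common_average_rereference([seg], mask)
        np.testing.assert_allclose(out.samples[0], 1.0)  # (a-b)/2
        np.testing.assert_allclose(out.samples[1], -1.0)

    def test_stim_channel_receives_but_does_not_contribute(self):
        seg = self._segment([[10.0] * 4, [2.0] * 4, [4.0] * 4], ("s", "a", "b"))
        mask = pp.ChannelMask({"s": True, "a": True, "b": True}, {})
        (out,) = pp.common_average_rereference([seg], mask, stim_channels=("s",))
        np.testing.assert_allclose(out.samples[0], 10.0 - 3.0)  # v - m, m = mean(a, b)

    def test_artifact_channels_dropped(self):
        seg = self._segment(np.ones((3, 5)), ("a", "b", "c"))
        mask = pp.ChannelMask({"a": False, "b": True, "c": True}, {"a": "artifact"})
        (out,) = pp.common_average_rereference([seg], mask)
        assert out.channel_labels == ("b", "c")

    def test_too_few_reference_channels_raises(self):
        seg = self._segment(np.ones((2, 5)), ("s", "a"))
        mask = pp.ChannelMask({"s": True, "a": True}, {})
        with pytest.raises(ProcessingError):
            pp.common_average_rereference([seg], mask, stim_channels=("s",))
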