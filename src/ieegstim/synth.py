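"""Seeded synthetic stimulation sessions.

The generator emulates the structure the analysis assumes in RAM-style
recordings: ~60 stimulation trials organised in groups of three, long
inter-group gaps that leave baseline epochs of at least 20 s, biphasic-train
stimulation parameters (0.25-3.5 mA; 10/25/50/100/200 Hz; 0.5 s, or 4.6 s
only at 50 Hz), and multichannel background activity with a realistic 1/f
spectral slope plus a low-amplitude alpha oscillator.

Band-limited stimulation effects are injected by scaling the band-passed
component of the 1-s post-stimulation window by the square root of the
configured power factor (so band power scales by the factor), with 50 ms
cosine ramps to avoid edge artifacts. Artifact channels receive an additive
500 µV deflection at stimulation offset that decays exponentially with a
0.8 s time constant — triggering both artifact-screening criteria by
construction.

Two faster modes bypass signal synthesis: :func:`generate_session_pair`
couples two sessions' effect maps on the log scale (``log f2 = k log f1 +
noise``), and :func:`generate_effect_tables` draws paired zero-mean normal
effect vectors directly, as in the study's null simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from .errors import SchedulingError, ValidationError
from .session import SessionRecording
from .spectral import BAND_NAMES, CANONICAL_BANDS

ALLOWED_FREQUENCIES = (10.0, 25.0, 50.0, 100.0, 200.0)
ALLOWED_DURATIONS = (0.5, 4.6)
AMPLITUDE_RANGE = (0.25, 3.5)

#: Trial-count distribution of a typical session (median 60, SD 13.9),
#: clipped at the 18-trial minimum-session criterion.
TRIAL_COUNT_MEAN = 60.0
TRIAL_COUNT_SD = 13.9
TRIAL_COUNT_MIN = 18

ARTIFACT_STEP_UV = 500.0
ARTIFACT_TAU = 0.8  # s
RAMP = 0.05  # s cosine ramp on injected components

_BAND_EDGES = {b.name: (b.low, b.high) for b in CANONICAL_BANDS}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic stimulation session.

    ``effect_map`` maps ``(channel_label, band_name)`` to a multiplicative
    post-stimulation band-power factor (1.0 = no effect). ``n_trials=None``
    samples the trial count from the session-size distribution
    (round(N(60, 13.9)), clipped at 18).
    """

    n_channels: int = 16
    sampling_rate: float = 500.0
    n_trials: int | None = 60
    trial_group_size: int = 3
    intra_group_gap: tuple[float, float] = (3.0, 6.0)
    inter_group_gap: tuple[float, float] = (30.0, 36.0)
    stim_amplitude: float = 1.0
    stim_frequency: float = 50.0
    stim_duration: float = 0.5
    effect_map: dict[tuple[str, str], float] = field(default_factory=dict)
    cross_session_scale: float = 1.0
    effect_noise_sd: float = 0.0
    artifact_channels: tuple[str, ...] = ()
    rng_seed: int = 0
    max_duration: float = 7200.0
    background_sd: float = 50.0  # µV
    alpha_amplitude: float = 10.0  # µV, 10 Hz background oscillator
    subject_id: str = "SYN01"
    task_label: str = "task_a"

    def __post_init__(self) -> None:
        if self.n_channels < 4:
            raise ValidationError("need at least 4 channels")
        if self.sampling_rate <= 110.0:
            raise ValidationError("sampling_rate must resolve the 55 Hz gamma edge")
        if self.stim_frequency not in ALLOWED_FREQUENCIES:
            raise ValidationError(
                f"stim_frequency must be one of {ALLOWED_FREQUENCIES}"
            )
        if self.stim_duration not in ALLOWED_DURATIONS:
            raise ValidationError(f"stim_duration must be one of {ALLOWED_DURATIONS}")
        if self.stim_duration == 4.6 and self.stim_frequency != 50.0:
            raise ValidationError("4.6 s stimulation requires 50 Hz frequency")
        if not AMPLITUDE_RANGE[0] <= self.stim_amplitude <= AMPLITUDE_RANGE[1]:
            raise ValidationError(f"stim_amplitude must lie in {AMPLITUDE_RANGE}")
        for name, gap in (("intra", self.intra_group_gap), ("inter", self.inter_group_gap)):
            if not (0 < gap[0] <= gap[1]):
                raise ValidationError(f"{name}_group_gap must be positive and ordered")
        if self.inter_group_gap[1] <= 30.0:
            raise ValidationError(
                "inter_group_gap upper bound must exceed 30 s so baseline epochs exist"
            )
        if self.n_trials is not None and self.n_trials < 1:
            raise ValidationError("n_trials must be positive")
        for (ch, band), factor in self.effect_map.items():
            if band not in BAND_NAMES:
                raise ValidationError(f"unknown band {band!r} in effect_map")
            if factor <= 0:
                raise ValidationError("effect-map factors must be positive")
        if self.effect_noise_sd < 0:
            raise ValidationError("effect_noise_sd must be >= 0")
        if self.cross_session_scale == 0:
            raise ValidationError("cross_session_scale must be nonzero")


def channel_label(i: int) -> str:
    return f"CH{i + 1:02d}"


def _draw_n_trials(config: GeneratorConfig, rng: np.random.Generator) -> int:
    if config.n_trials is not None:
        return config.n_trials
    n = int(round(rng.normal(TRIAL_COUNT_MEAN, TRIAL_COUNT_SD)))
    return max(n, TRIAL_COUNT_MIN)


def _schedule_events(
    config: GeneratorConfig, rng: np.random.Generator, n_trials: int
) -> pd.DataFrame:
    """Lay out trial onsets in groups of ``trial_group_size``."""
    onsets = []
    t = 40.0  # head room for the leading baseline epoch and pre windows
    for i in range(n_trials):
        onsets.append(t)
        end = t + config.stim_duration
        if (i + 1) % config.trial_group_size == 0:
            gap = rng.uniform(*config.inter_group_gap)
        else:
            gap = rng.uniform(*config.intra_group_gap)
        t = end + gap
    total = onsets[-1] + config.stim_duration + 40.0
    if total > config.max_duration:
        raise SchedulingError(
            f"session timeline of {total:.0f} s exceeds max_duration "
            f"{config.max_duration:.0f} s"
        )
    labels = [channel_label(i) for i in range(config.n_channels)]
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": config.stim_duration,
            "amplitude": config.stim_amplitude,
            "frequency": config.stim_frequency,
            "anode": labels[0],
            "cathode": labels[1],
        }
    )


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-sloped Gaussian noise (unit variance)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _background(
    config: GeneratorConfig, rng: np.random.Generator, n_samples: int
) -> np.ndarray:
    t = np.arange(n_samples) / config.sampling_rate
    signals = np.empty((config.n_channels, n_samples))
    for c in range(config.n_channels):
        x = config.background_sd * _pink_noise(rng, n_samples, config.sampling_rate)
        phase = rng.uniform(0, 2 * np.pi)
        x += config.alpha_amplitude * np.sin(2 * np.pi * 10.0 * t + phase)
        signals[c] = x
    return signals


def _cosine_ramp_envelope(n: int, fs: float) -> np.ndarray:
    env = np.ones(n)
    nr = min(int(round(RAMP * fs)), n // 2)
    if nr > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = ramp
        env[-nr:] = ramp[::-1]
    return env


def _inject_effects(
    signals: np.ndarray,
    config: GeneratorConfig,
    events: pd.DataFrame,
    effect_map: dict[tuple[str, str], float],
) -> None:
    """Scale band-passed power of post windows in place per the effect map."""
    if not effect_map:
        return
    fs = config.sampling_rate
    n_seg = int(round(fs))
    pad = int(round(0.5 * fs))
    env = _cosine_ramp_envelope(n_seg, fs)
    labels = [channel_label(i) for i in range(config.n_channels)]
    sos_cache: dict[str, np.ndarray] = {}
    for (ch, band), factor in effect_map.items():
        if ch not in labels:
            raise ValidationError(f"effect_map channel {ch!r} not in session")
        ci = labels.index(ch)
        if band not in sos_cache:
            low, high = _BAND_EDGES[band]
            sos_cache[band] = scipy.signal.butter(
                4, [low, high], btype="bandpass", fs=fs, output="sos"
            )
        gain = np.sqrt(factor) - 1.0
        for row in events.itertuples(index=False):
            offset = float(row.onset) + float(row.duration)
            i0 = int(round((offset + 0.05) * fs))
            a, b = max(i0 - pad, 0), min(i0 + n_seg + pad, signals.shape[1])
            comp = scipy.signal.sosfiltfilt(sos_cache[band], signals[ci, a:b])
            comp = comp[i0 - a : i0 - a + n_seg]
            signals[ci, i0 : i0 + n_seg] += gain * comp * env


def _inject_artifacts(
    signals: np.ndarray, config: GeneratorConfig, events: pd.DataFrame
) -> None:
    fs = config.sampling_rate
    n_decay = int(round(6 * ARTIFACT_TAU * fs))
    t = np.arange(n_decay) / fs
    kernel = ARTIFACT_STEP_UV * np.exp(-t / ARTIFACT_TAU)
    labels = [channel_label(i) for i in range(config.n_channels)]
    for ch in config.artifact_channels:
        if ch not in labels:
            raise ValidationError(f"artifact channel {ch!r} not in session")
        ci = labels.index(ch)
        for row in events.itertuples(index=False):
            i0 = int(round((float(row.onset) + float(row.duration)) * fs))
            i1 = min(i0 + n_decay, signals.shape[1])
            signals[ci, i0:i1] += kernel[: i1 - i0]


def _electrode_geometry(
    rng: np.random.Generator, n_channels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Electrode coordinates inside, and a surface shell around, a 60 mm sphere."""
    coords = rng.uniform(-35.0, 35.0, size=(n_channels, 3))
    i = np.arange(200)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1 - 2 * (i + 0.5) / 200
    r = np.sqrt(1 - z**2)
    surface = 60.0 * np.column_stack(
        [r * np.cos(golden * i), r * np.sin(golden * i), z]
    )
    return coords, surface


def generate_session(
    config: GeneratorConfig,
    session_id: str = "sess0",
    start_timestamp: float = 1.5e9,
    _effect_map: dict[tuple[str, str], float] | None = None,
    _geometry: tuple[np.ndarray, np.ndarray] | None = None,
) -> SessionRecording:
    """Generate one synthetic stimulation session.

    Identical config and seed give bit-identical output. The underscore
    parameters let :func:`generate_session_pair` share geometry and override
    the effect map for the second session.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_trials = _draw_n_trials(config, rng)
    events = _schedule_events(config, rng, n_trials)
    duration = float(np.ceil(events["onset"].iloc[-1] + config.stim_duration + 40.0))
    n_samples = int(round(duration * config.sampling_rate))

    signals = _background(config, rng, n_samples)
    effect_map = config.effect_map if _effect_map is None else _effect_map
    _inject_effects(signals, config, events, effect_map)
    _inject_artifacts(signals, config, events)

    geom_rng = np.random.default_rng((config.rng_seed, 0x9E0))
    coords, surface = _geometry if _geometry is not None else _electrode_geometry(
        geom_rng, config.n_channels
    )
    labels = tuple(channel_label(i) for i in range(config.n_channels))
    return SessionRecording(
        signals=signals,
        sampling_rate=config.sampling_rate,
        channel_labels=labels,
        events=events,
        subject_id=config.subject_id,
        session_id=session_id,
        task_label=config.task_label,
        start_timestamp=start_timestamp,
        channel_coords=coords,
        brain_surface=surface,
    )


def perturb_effect_map(
    effect_map: dict[tuple[str, str], float],
    k: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> dict[tuple[str, str], float]:
    """Second-session effect map: ``log f2 = k * log f1 + N(0, noise_sd)``.

    Factors are multiplicative band-power scalings and must stay positive,
    so the proportional cross-session coupling acts on the log scale.
    """
    out = {}
    for key, factor in effect_map.items():
        out[key] = float(np.exp(k * np.log(factor) + rng.normal(0.0, noise_sd)))
    return out


def generate_session_pair(
    config: GeneratorConfig,
    session_ids: tuple[str, str] = ("sess0", "sess1"),
    start_timestamps: tuple[float, float] = (1.5e9, 1.5e9 + 86_400.0),
    task_labels: tuple[str, str] | None = None,
) -> tuple[SessionRecording, SessionRecording]:
    """Two sessions sharing subject, geometry and stimulation location.

    Session 2's effect map is session 1's scaled by ``cross_session_scale``
    (on the log-factor scale) plus independent ``effect_noise_sd`` noise; its
    signal noise is an independent realisation.
    """
    seeds = np.random.SeedSequence(config.rng_seed).spawn(3)
    pair_rng = np.random.default_rng(seeds[2])
    map2 = perturb_effect_map(
        config.effect_map, config.cross_session_scale, config.effect_noise_sd, pair_rng
    )
    geom_rng = np.random.default_rng((config.rng_seed, 0x9E0))
    geometry = _electrode_geometry(geom_rng, config.n_channels)
    tasks = task_labels or (config.task_label, config.task_label)
    cfg1 = replace(config, rng_seed=int(seeds[0].generate_state(1)[0] % 2**31))
    cfg2 = replace(
        config,
        rng_seed=int(seeds[1].generate_state(1)[0] % 2**31),
        task_label=tasks[1],
    )
    s1 = generate_session(
        cfg1, session_ids[0], start_timestamps[0], _geometry=geometry
    )
    s2 = generate_session(
        cfg2, session_ids[1], start_timestamps[1], _effect_map=map2, _geometry=geometry
    )
    return s1, s2


def generate_effect_tables(
    n_pairs: int,
    n_combinations: int,
    effect_sd: float = 1.0,
    rng_seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Paired null effect-value vectors, bypassing signal processing.

    Each pair is two independent vectors of length ``n_combinations`` drawn
    from N(0, ``effect_sd``) — the study's null simulation, with the SD
    matched to the baseline effect scale (z-statistics, so SD 1 by default).
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    if n_combinations < 3:
        raise ValidationError("n_combinations must be >= 3")
    if effect_sd < 0:
        raise ValidationError("effect_sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    return [
        (
            rng.normal(0.0, effect_sd, n_combinations),
            rng.normal(0.0, effect_sd, n_combinations),
        )
        for _ in range(n_pairs)
    ]
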