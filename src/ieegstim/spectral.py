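"""Welch band power in the five canonical iEEG bands.

Each 1-s segment is turned into a power spectral density with Welch's
method — window length half the segment, overlap a quarter of the segment,
so a 1-s segment yields three half-second windows on a 2 Hz frequency
grid — and the PSD is integrated over delta (2-4), theta (4-8), alpha
(8-12), beta (12-25) and gamma (25-55 Hz), then natural-log transformed.
Band edges are half-open ``[low, high)`` so shared edges are unambiguous.

The window taper (Hamming by default) and the log base are fixed choices
here; both cancel in the paired pre/post statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .errors import ValidationError
from .preprocess import Segment

#: Floor applied to integrated band power before taking the log, guarding
#: degenerate (all-zero) segments against -inf.
POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"band {self.name}: low must be < high")


#: The five canonical bands, contiguous and non-overlapping over 2-55 Hz.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 25.0),
    BandDefinition("gamma", 25.0, 55.0),
)

BAND_NAMES = tuple(b.name for b in CANONICAL_BANDS)


def welch_psd(
    x: np.ndarray, sampling_rate: float, window: str = "hamming"
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of one-second series (last axis = time).

    Window length is half the segment (0.5 s) and the overlap a quarter of
    the segment (0.25 s), giving three windows and a 2 Hz frequency grid.

    Parameters
    ----------
    x
        Array whose last axis holds exactly ``sampling_rate`` samples (1 s).
    sampling_rate
        Sampling frequency in Hz.
    window
        Taper passed to :func:`scipy.signal.welch`.

    Returns
    -------
    frequencies, psd
        Frequency grid (Hz) and density (µV²/Hz) with the same leading
        shape as ``x``.
    """
    x = np.asarray(x, dtype=np.float64)
    n = int(round(sampling_rate))
    if x.shape[-1] != n:
        raise ValidationError(
            f"expected {n} samples (1 s at {sampling_rate} Hz), got {x.shape[-1]}"
        )
    nperseg = n // 2
    noverlap = n // 4
    freqs, psd = scipy.signal.welch(
        x,
        fs=sampling_rate,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def band_power(
    frequencies: np.ndarray,
    psd: np.ndarray,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
) -> dict[str, np.ndarray | float]:
    """Integrate a PSD over each band and return natural-log band power.

    The integral is trapezoidal over the grid points spanning
    ``[low, high]`` — both bounds enter the quadrature (the shared edge is a
    set of measure zero, and including it makes contiguous band integrals
    add up exactly to the integral over their union). A band covered by
    fewer than two grid points is a validation error. Results are floored
    at :data:`POWER_FLOOR` before the log so silent segments stay finite.
    """
    frequencies = np.asarray(frequencies, dtype=np.float64)
    psd = np.asarray(psd, dtype=np.float64)
    out: dict[str, np.ndarray | float] = {}
    for band in bands:
        sel = (frequencies >= band.low) & (frequencies <= band.high)
        if int(sel.sum()) < 2:
            raise ValidationError(
                f"frequency grid too coarse for band {band.name} "
                f"[{band.low}, {band.high})"
            )
        power = np.trapezoid(psd[..., sel], frequencies[sel], axis=-1)
        value = np.log(np.maximum(power, POWER_FLOOR))
        out[band.name] = float(value) if np.ndim(value) == 0 else value
    return out


def band_power_table(
    segments: Iterable[Segment],
    sampling_rate: float,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    window: str = "hamming",
    session_id: str | None = None,
) -> pd.DataFrame:
    """Log band power for every (segment, channel, band).

    Returns a long-format frame with columns ``pair_id, role, condition,
    channel, band, log_power`` (plus ``session`` when given), one row per
    segment x channel x band.
    """
    segments = list(segments)
    rows: list[pd.DataFrame] = []
    for seg in segments:
        freqs, psd = welch_psd(seg.samples, sampling_rate, window=window)
        powers = band_power(freqs, psd, bands)
        for band_name, values in powers.items():
            frame = pd.DataFrame(
                {
                    "pair_id": seg.pair_id,
                    "role": seg.role,
                    "condition": seg.condition,
                    "channel": list(seg.channel_labels),
                    "band": band_name,
                    "log_power": np.atleast_1d(values),
                }
            )
            rows.append(frame)
    if not rows:
        return pd.DataFrame(
            columns=["pair_id", "role", "condition", "channel", "band", "log_power"]
        )
    table = pd.concat(rows, ignore_index=True)
    if session_id is not None:
        table.insert(0, "session", session_id)
    return table
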