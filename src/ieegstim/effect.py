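"""The stimulation-effect statistic U and session-level summaries.

The effect of stimulation on band power, per channel and band, is the
z-statistic U of the Wilcoxon signed-rank test on paired pre/post log band
powers (normal approximation with mid-rank tie handling). Positive U means
band power increased from pre to post. The same statistic applied to
baseline pseudo-trial pairs quantifies spontaneous band-power fluctuation.

Session-level summaries follow the study's box-plot conventions: "adjacent
values" are the most extreme data within 1.5 x IQR of the quartiles, and
extrema comparisons report the fraction of sessions whose stimulation
min/max effect exceeds the baseline distribution's adjacent values, plus a
paired t-test with Cohen's d for paired samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ProcessingError, ValidationError
from .spectral import BAND_NAMES

#: Minimum usable pre/post pairs (after discarding zero differences) for the
#: normal approximation; cells below are flagged missing (NaN).
MIN_PAIRS = 10

#: Cap reported in place of an infinite paired-t statistic (zero-variance
#: differences with nonzero mean).
T_CAP = 1e6


def wilcoxon_z(
    differences: np.ndarray, continuity_correction: bool = False
) -> float:
    """Signed-rank z statistic of paired differences.

    Zero differences are discarded (classical Wilcoxon, as MATLAB's
    ``signrank``); ties get mid-ranks with the usual variance correction
    ``sum(t^3 - t) / 48``. Returns NaN when fewer than :data:`MIN_PAIRS`
    nonzero differences remain, and 0.0 when all differences are zero.
    """
    d = np.asarray(differences, dtype=np.float64)
    if d.ndim != 1:
        raise ValidationError("differences must be 1-D")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0
    if n < MIN_PAIRS:
        return float("nan")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 0.0
    dev = w_plus - mean
    if continuity_correction and dev != 0:
        dev = np.sign(dev) * max(abs(dev) - 0.5, 0.0)
    return float(dev / np.sqrt(var))


def effect_U(
    pre_log_powers: np.ndarray,
    post_log_powers: np.ndarray,
    continuity_correction: bool = False,
) -> float:
    """Effect statistic U for one (channel, band) cell.

    ``U = wilcoxon_z(post - pre)``; positive when band power increases.
    """
    pre = np.asarray(pre_log_powers, dtype=np.float64)
    post = np.asarray(post_log_powers, dtype=np.float64)
    if pre.shape != post.shape:
        raise ValidationError("pre and post must be paired (equal length)")
    return wilcoxon_z(post - pre, continuity_correction=continuity_correction)


@dataclass
class EffectMatrix:
    """U per channel x band for one session and condition.

    ``U`` is a channels-by-bands DataFrame (NaN = unusable cell); ``n_pairs``
    counts the pre/post pairs behind each cell.
    """

    U: pd.DataFrame
    n_pairs: pd.DataFrame
    condition: str
    session_id: str = "sess0"

    @property
    def channels(self) -> list[str]:
        return list(self.U.index)

    def valid_channels(self) -> list[str]:
        """Channels with at least one usable cell."""
        return list(self.U.index[~self.U.isna().all(axis=1)])

    def values_flat(self) -> np.ndarray:
        return self.U.to_numpy(float).ravel()


def session_effect(
    band_power_table: pd.DataFrame,
    condition: str,
    session_id: str = "sess0",
    continuity_correction: bool = False,
) -> EffectMatrix:
    """Compute U for every (channel, band) of one condition.

    ``band_power_table`` is the long-format output of
    :func:`ieegstim.spectral.band_power_table`. Pairs missing either role
    are dropped (logged via the pair count).
    """
    sub = band_power_table[band_power_table["condition"] == condition]
    if sub.empty:
        raise ValidationError(f"no rows for condition {condition!r}")
    wide = sub.pivot_table(
        index=["channel", "band", "pair_id"],
        columns="role",
        values="log_power",
        aggfunc="first",
    )
    if "pre" not in wide.columns or "post" not in wide.columns:
        raise ValidationError("table must contain both pre and post segments")
    wide = wide.dropna(subset=["pre", "post"])
    channels = sorted(sub["channel"].unique())
    bands = [b for b in BAND_NAMES if b in set(sub["band"])]
    U = pd.DataFrame(np.nan, index=channels, columns=bands)
    n_pairs = pd.DataFrame(0, index=channels, columns=bands)
    for (ch, band), cell in wide.groupby(level=["channel", "band"]):
        diffs = cell["post"].to_numpy() - cell["pre"].to_numpy()
        U.loc[ch, band] = wilcoxon_z(diffs, continuity_correction)
        n_pairs.loc[ch, band] = len(cell)
    return EffectMatrix(U=U, n_pairs=n_pairs, condition=condition, session_id=session_id)


@dataclass
class SessionExtrema:
    """Min/max U across channels, per band and overall, for one condition."""

    min_by_band: dict[str, float]
    max_by_band: dict[str, float]
    overall_min: float
    overall_max: float
    condition: str
    session_id: str = "sess0"


def session_extrema(effect: EffectMatrix) -> SessionExtrema:
    """Extreme effect values of a session (NaN cells ignored)."""
    values = effect.U.to_numpy(float)
    with np.errstate(all="ignore"):
        min_by_band = {
            b: float(np.nanmin(effect.U[b])) for b in effect.U.columns
        }
        max_by_band = {
            b: float(np.nanmax(effect.U[b])) for b in effect.U.columns
        }
        overall_min = float(np.nanmin(values))
        overall_max = float(np.nanmax(values))
    return SessionExtrema(
        min_by_band=min_by_band,
        max_by_band=max_by_band,
        overall_min=overall_min,
        overall_max=overall_max,
        condition=effect.condition,
        session_id=effect.session_id,
    )


def adjacent_values(x: np.ndarray) -> tuple[float, float]:
    """Lower/upper adjacent values: the most extreme data that are not
    outliers under the 1.5 x IQR rule."""
    x = np.asarray(x, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValidationError("no finite values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return float(x[x >= lo_fence].min()), float(x[x <= hi_fence].max())


def cohens_d_paired(differences: np.ndarray) -> float:
    d = np.asarray(differences, dtype=np.float64)
    sd = d.std(ddof=1)
    return float(d.mean() / sd) if sd > 0 else 0.0


def extrema_comparison(
    stim: list[SessionExtrema], base: list[SessionExtrema]
) -> dict[str, dict[str, float]]:
    """Compare stimulation extrema to baseline extrema across sessions.

    ``stim`` and ``base`` must be paired (same sessions, both conditions).
    For minima and maxima separately, reports the baseline distribution's
    adjacent values, the fraction of sessions whose stimulation extremum is
    more extreme, and the paired t-test (p-value and Cohen's d) on the
    per-session stimulation - baseline differences.
    """
    if len(stim) != len(base):
        raise ValidationError("stim and base lists must be paired")
    if len(stim) < 3:
        raise ProcessingError("need at least 3 sessions for extrema comparison")
    out: dict[str, dict[str, float]] = {}
    for side in ("min", "max"):
        s = np.array([getattr(e, f"overall_{side}") for e in stim])
        b = np.array([getattr(e, f"overall_{side}") for e in base])
        lo_adj, hi_adj = adjacent_values(b)
        if side == "max":
            exceed = float(np.mean(s > hi_adj))
        else:
            exceed = float(np.mean(s < lo_adj))
        diffs = s - b
        if np.allclose(diffs, 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = scipy.stats.ttest_rel(s, b)
        out[side] = {
            "baseline_lower_adjacent": lo_adj,
            "baseline_upper_adjacent": hi_adj,
            "exceedance_fraction": exceed,
            "t_statistic": float(t_stat),
            "p_value": float(p),
            "effect_size": cohens_d_paired(diffs),
        }
    return out


def pair_effect_difference(
    U1: EffectMatrix, U2: EffectMatrix
) -> tuple[float, bool]:
    """|t| of a paired t-test on |U| across common valid cells of two sessions.

    Returns ``(abs_t, capped)``; ``capped`` marks the degenerate
    zero-variance case, where the statistic is reported as :data:`T_CAP`.
    """
    common = U1.U.index.intersection(U2.U.index)
    a = U1.U.loc[common].to_numpy(float).ravel()
    b = U2.U.loc[common].to_numpy(float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ProcessingError("fewer than 3 common valid cells")
    diffs = np.abs(a[ok]) - np.abs(b[ok])
    if np.allclose(diffs, diffs[0]):
        if abs(diffs[0]) < 1e-12:
            return 0.0, False
        return T_CAP, True
    t_stat = scipy.stats.ttest_rel(np.abs(a[ok]), np.abs(b[ok])).statistic
    if not np.isfinite(t_stat):
        return T_CAP, True
    return float(abs(t_stat)), False
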