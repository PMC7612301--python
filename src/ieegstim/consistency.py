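"""Cross-session consistency of stimulation effect.

Two sessions' effect values, paired by (channel, band) over the
intersection of valid channels, form a point cloud (s1, s2). Agreement of
the form ``S1 = k S2`` (zero intercept) is measured by the *zero-centred*
Pearson correlation

    r0 = sum(s1 * s2) / sqrt(sum(s1^2) * sum(s2^2)),

i.e. cosine similarity, and the consistency coefficient is its Fisher
transform atanh(r0). The *consistency curve* repeats this while an
exclusion circle at the origin grows in radius steps of 0.2, removing
weak-effect cells; enlargement stops just before the circle would cover 98%
of the points (or leave fewer than 3). The curve's signed value of largest
magnitude is the pair's *maximum consistency coefficient*.

Baseline pseudo-effect pairs processed identically yield, per radius, a
95% two-sided band whose upper envelope is the reference a genuine
stimulation consistency has to beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .effect import EffectMatrix
from .errors import ValidationError

RADIUS_STEP = 0.2
STOP_FRACTION = 0.02  # enlargement stops before < 2% of points remain
MIN_POINTS = 3
ATANH_CLIP = 1.0 - 1e-10  # finite cap ~ +/- 11.86 for collinear point sets


def pair_points(em1: EffectMatrix, em2: EffectMatrix) -> np.ndarray:
    """Pair effect values of corresponding (channel, band) cells.

    Only the intersection of valid channels of the two sessions enters, and
    cells unusable in either session are dropped. Returns an (n, 2) array.
    """
    common = sorted(set(em1.valid_channels()) & set(em2.valid_channels()))
    bands = [b for b in em1.U.columns if b in em2.U.columns]
    a = em1.U.loc[common, bands].to_numpy(float).ravel()
    b = em2.U.loc[common, bands].to_numpy(float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    return np.column_stack([a[ok], b[ok]])


def zero_centered_correlation(points: np.ndarray) -> float:
    """Zero-centred Pearson correlation (cosine similarity) of an (n, 2) set.

    Returns NaN (flagged missing) when either coordinate has zero norm.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    s1, s2 = pts[:, 0], pts[:, 1]
    n1 = float(np.sum(s1 * s1))
    n2 = float(np.sum(s2 * s2))
    if n1 == 0.0 or n2 == 0.0:
        return float("nan")
    return float(np.sum(s1 * s2) / np.sqrt(n1 * n2))


def consistency_coefficient(points: np.ndarray) -> float:
    """Fisher-transformed zero-centred correlation, atanh(r0).

    r0 is clipped to +/-(1 - 1e-10) first so perfectly collinear point sets
    give a finite cap instead of infinity.
    """
    r0 = zero_centered_correlation(points)
    if np.isnan(r0):
        return float("nan")
    return float(np.arctanh(np.clip(r0, -ATANH_CLIP, ATANH_CLIP)))


@dataclass
class ConsistencyCurve:
    """Consistency coefficient as a function of exclusion-circle radius."""

    radii: np.ndarray
    coefficients: np.ndarray
    n_remaining: np.ndarray
    max_consistency: float
    max_radius: float
    n_points: int = 0

    def __len__(self) -> int:
        return len(self.radii)


def consistency_curve(
    points: np.ndarray,
    step: float = RADIUS_STEP,
    stop_fraction: float = STOP_FRACTION,
    min_points: int = MIN_POINTS,
) -> ConsistencyCurve:
    """Consistency coefficient while growing an exclusion circle at the origin.

    At radius x only points with distance >= x from (0, 0) enter the
    coefficient (points exactly on the circle are retained). Radii advance
    in steps of ``step`` while more than ``stop_fraction`` of the points and
    at least ``min_points`` points remain. The maximum consistency is the
    signed coefficient of largest magnitude; ties go to the smallest radius
    (the estimate using more data).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    n_total = len(pts)
    if n_total < min_points:
        raise ValidationError(f"need at least {min_points} points")
    dist = np.hypot(pts[:, 0], pts[:, 1])
    radii, coeffs, n_rem = [], [], []
    x = 0.0
    while True:
        keep = dist >= x
        n = int(keep.sum())
        if n < min_points or n / n_total <= stop_fraction:
            break
        radii.append(x)
        coeffs.append(consistency_coefficient(pts[keep]))
        n_rem.append(n)
        x = round(x + step, 12)
    if not radii:
        raise ValidationError("no radius retains enough points")
    coeffs_arr = np.asarray(coeffs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        finite = np.where(np.isfinite(coeffs_arr), np.abs(coeffs_arr), -np.inf)
    best = int(np.argmax(finite))  # argmax takes the first = smallest radius
    return ConsistencyCurve(
        radii=np.asarray(radii),
        coefficients=coeffs_arr,
        n_remaining=np.asarray(n_rem, dtype=int),
        max_consistency=float(coeffs_arr[best]),
        max_radius=float(radii[best]),
        n_points=n_total,
    )


@dataclass
class ConsistencyBand:
    """Per-radius 95% two-sided interval of baseline consistency."""

    radii: np.ndarray
    lower: np.ndarray  # 2.5th percentile
    upper: np.ndarray  # 97.5th percentile
    n_pairs: np.ndarray
    global_upper: float = field(default=np.nan)

    def upper_at(self, radius: float) -> float:
        idx = np.argmin(np.abs(self.radii - radius))
        return float(self.upper[idx])


def baseline_consistency_band(
    baseline_pairs: list[np.ndarray],
    step: float = RADIUS_STEP,
    stop_fraction: float = STOP_FRACTION,
    min_points: int = MIN_POINTS,
    min_pairs_per_radius: int = 2,
) -> ConsistencyBand:
    """95% two-sided band of baseline consistency coefficients, per radius.

    Each baseline pair's curve is computed with the same exclusion-circle
    procedure; at every radius reached by at least ``min_pairs_per_radius``
    curves the 2.5th/97.5th percentiles are taken across pairs.
    ``global_upper`` is the maximum of the upper bound over radii — the
    reference for the "maximum consistency" comparison.
    """
    if len(baseline_pairs) < 20:
        warnings.warn(
            f"only {len(baseline_pairs)} baseline pairs; percentiles unstable",
            stacklevel=2,
        )
    curves = [
        consistency_curve(p, step=step, stop_fraction=stop_fraction, min_points=min_points)
        for p in baseline_pairs
    ]
    max_len = max(len(c) for c in curves)
    radii = np.arange(max_len) * step
    lower, upper, counts = [], [], []
    for i in range(max_len):
        vals = np.array(
            [c.coefficients[i] for c in curves if len(c) > i and np.isfinite(c.coefficients[i])]
        )
        if len(vals) < min_pairs_per_radius:
            radii = radii[:i]
            break
        lo, hi = np.percentile(vals, [2.5, 97.5])
        lower.append(lo)
        upper.append(hi)
        counts.append(len(vals))
    if not upper:
        raise ValidationError("no radius has enough baseline pairs")
    upper_arr = np.asarray(upper)
    return ConsistencyBand(
        radii=radii,
        lower=np.asarray(lower),
        upper=upper_arr,
        n_pairs=np.asarray(counts, dtype=int),
        global_upper=float(upper_arr.max()),
    )
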