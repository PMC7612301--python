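"""Attributing cross-session consistency: covariates, regression, bootstrap ANOVA.

Each session pair contributes ten covariates — session time difference,
mean absolute differences of baseline band-power means and SDs, average and
difference of stimulation amplitude, the averaged maximum and minimum
effect, stimulation frequency, signed stimulation depth, and a same/different
task indicator — and the response is the pair's maximum consistency
coefficient. An ordinary-least-squares fit explains the response; per-term
explanatory power ("ANOVA effect") is the Type II F statistic, and its
robustness is assessed by refitting on 200 bootstrap resamples of the pairs.

Stimulation depth is the distance of the anode-cathode midpoint from the
brain surface, negative when the midpoint falls outside the surface's
convex hull. Stimulation duration is deliberately not a covariate: it
co-varies with frequency, so only frequency enters the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial
import scipy.stats
import statsmodels.api as sm

from .effect import EffectMatrix
from .errors import ProcessingError, ValidationError

logger = logging.getLogger(__name__)

COVARIATE_NAMES = (
    "session_time_difference",
    "baseline_mean_difference",
    "baseline_sd_difference",
    "average_max_effect",
    "average_min_effect",
    "average_stim_amplitude",
    "stim_amplitude_difference",
    "stim_frequency",
    "stim_depth",
    "task_difference",
)
RESPONSE_NAME = "max_consistency"


def stimulation_depth(
    anode_xyz: np.ndarray,
    cathode_xyz: np.ndarray,
    surface_points: np.ndarray,
) -> float:
    """Signed depth (mm) of the anode-cathode midpoint below the brain surface.

    Depth is the minimum Euclidean distance from the midpoint to the surface
    point set; the sign is negative iff the midpoint lies outside the
    surface's convex hull.
    """
    surface = np.asarray(surface_points, dtype=np.float64)
    if surface.ndim != 2 or surface.shape[1] != 3 or len(surface) < 4:
        raise ValidationError("surface must be an (n >= 4, 3) point set")
    mid = (np.asarray(anode_xyz, float) + np.asarray(cathode_xyz, float)) / 2.0
    try:
        tri = scipy.spatial.Delaunay(surface)
    except scipy.spatial.QhullError as exc:
        raise ValidationError("degenerate (coplanar) surface point set") from exc
    dist = float(np.linalg.norm(surface - mid, axis=1).min())
    inside = tri.find_simplex(mid) >= 0
    if dist == 0.0:
        return 0.0
    return dist if inside else -dist


@dataclass
class SessionSummary:
    """Everything one processed session contributes to pair covariates."""

    session_id: str
    start_timestamp: float
    task_label: str
    stim_amplitude: float
    stim_frequency: float
    anode_xyz: np.ndarray
    cathode_xyz: np.ndarray
    stim_effect: EffectMatrix
    baseline_effect: EffectMatrix
    baseline_stats: pd.DataFrame  # columns: channel, band, role, mean, sd


@dataclass
class PairCovariates:
    """The ten regression covariates plus the response for one session pair."""

    pair_id: str
    session_time_difference: float
    baseline_mean_difference: float
    baseline_sd_difference: float
    average_max_effect: float
    average_min_effect: float
    average_stim_amplitude: float
    stim_amplitude_difference: float
    stim_frequency: float
    stim_depth: float
    task_difference: int
    max_consistency: float

    def as_row(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COVARIATE_NAMES + (RESPONSE_NAME,)}


def baseline_summary_stats(band_power_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and SD of baseline log band power, both pre and post."""
    base = band_power_table[band_power_table["condition"] == "baseline"]
    if base.empty:
        raise ValidationError("no baseline rows in band power table")
    stats = (
        base.groupby(["channel", "band", "role"])["log_power"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"std": "sd"})
    )
    return stats


def build_pair_covariates(
    s1: SessionSummary,
    s2: SessionSummary,
    surface_points: np.ndarray,
    max_consistency: float,
    pair_id: str | None = None,
) -> PairCovariates:
    """Assemble the regression covariates for one session pair.

    Difference covariates are absolute, so construction is symmetric in
    session order. Baseline differences are averaged over all common
    (channel, band, role) cells — both 'pre' and 'post'.
    """
    for name in ("start_timestamp", "stim_amplitude", "stim_frequency"):
        for s in (s1, s2):
            if getattr(s, name) is None:
                raise ValidationError(f"missing metadata field {name!r}")
    if s1.stim_frequency != s2.stim_frequency:
        raise ValidationError("paired sessions must share stimulation frequency")

    merged = s1.baseline_stats.merge(
        s2.baseline_stats, on=["channel", "band", "role"], suffixes=("_1", "_2")
    )
    if merged.empty:
        raise ValidationError("no common baseline cells between sessions")
    mean_diff = float(np.mean(np.abs(merged["mean_1"] - merged["mean_2"])))
    sd_diff = float(np.mean(np.abs(merged["sd_1"] - merged["sd_2"])))

    max1, max2 = (float(np.nanmax(s.stim_effect.U.to_numpy())) for s in (s1, s2))
    min1, min2 = (float(np.nanmin(s.stim_effect.U.to_numpy())) for s in (s1, s2))
    depth = stimulation_depth(s1.anode_xyz, s1.cathode_xyz, surface_points)

    return PairCovariates(
        pair_id=pair_id or f"{s1.session_id}|{s2.session_id}",
        session_time_difference=abs(s1.start_timestamp - s2.start_timestamp),
        baseline_mean_difference=mean_diff,
        baseline_sd_difference=sd_diff,
        average_max_effect=(max1 + max2) / 2.0,
        average_min_effect=(min1 + min2) / 2.0,
        average_stim_amplitude=(s1.stim_amplitude + s2.stim_amplitude) / 2.0,
        stim_amplitude_difference=abs(s1.stim_amplitude - s2.stim_amplitude),
        stim_frequency=float(s1.stim_frequency),
        stim_depth=depth,
        task_difference=int(s1.task_label != s2.task_label),
        max_consistency=float(max_consistency),
    )


def covariates_frame(pairs: list[PairCovariates]) -> pd.DataFrame:
    df = pd.DataFrame([p.as_row() for p in pairs])
    df.insert(0, "pair_id", [p.pair_id for p in pairs])
    return df


# ---------------------------------------------------------------------------
# regression + ANOVA


def _design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[t].to_numpy(float) for t in terms])
    return X


def _drop_aliased(df: pd.DataFrame, terms: list[str]) -> list[str]:
    """Greedily keep covariates that increase design-matrix rank."""
    kept: list[str] = []
    for t in terms:
        X = _design(df, kept + [t])
        if np.linalg.matrix_rank(X) == len(kept) + 2:
            kept.append(t)
        else:
            logger.warning("dropping aliased covariate %r", t)
    return kept


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def type2_anova(
    df: pd.DataFrame, response: str = RESPONSE_NAME, terms: list[str] | None = None
) -> pd.DataFrame:
    """Type II ANOVA F statistic per term of the linear model.

    For each term, F compares the full model's residual sum of squares with
    the model refit without that term (all terms are single-column, so Type
    II and Type III coincide here up to the absence of interactions).
    """
    terms = list(terms or COVARIATE_NAMES)
    y = df[response].to_numpy(float)
    X_full = _design(df, terms)
    n, p = X_full.shape
    df_resid = n - p
    if df_resid <= 0:
        raise ValidationError("more parameters than observations")
    rss_full = _rss(X_full, y)
    rows = []
    for i, t in enumerate(terms):
        X_red = np.delete(X_full, i + 1, axis=1)
        ss = _rss(X_red, y) - rss_full
        F = (ss / 1.0) / (rss_full / df_resid) if rss_full > 0 else np.inf
        p_val = float(scipy.stats.f.sf(F, 1, df_resid)) if np.isfinite(F) else 0.0
        rows.append({"term": t, "sum_sq": ss, "F": F, "p_value": p_val})
    return pd.DataFrame(rows).set_index("term")


@dataclass
class ModelFit:
    """OLS fit of max consistency on the pair covariates."""

    params: pd.Series
    conf_int: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    anova: pd.DataFrame  # per-term Type II F and p
    terms: list[str]
    n_obs: int


def fit_consistency_model(
    dataset: pd.DataFrame | list[PairCovariates],
    response: str = RESPONSE_NAME,
    terms: list[str] | None = None,
) -> ModelFit:
    """Ordinary least squares of maximum consistency on the ten covariates.

    Aliased (rank-deficient) covariates are dropped with a warning. Reports
    R², adjusted R² and per-term Type II ANOVA F statistics.
    """
    df = covariates_frame(dataset) if isinstance(dataset, list) else dataset
    terms = list(terms or [t for t in COVARIATE_NAMES if t in df.columns])
    if len(df) <= len(terms) + 1:
        raise ValidationError("need more pairs than covariates + 1")
    terms = _drop_aliased(df, terms)
    X = _design(df, terms)
    y = df[response].to_numpy(float)
    res = sm.OLS(y, X).fit()
    names = ["const"] + terms
    return ModelFit(
        params=pd.Series(res.params, index=names),
        conf_int=pd.DataFrame(res.conf_int(), index=names, columns=["lo", "hi"]),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        anova=type2_anova(df, response, terms),
        terms=terms,
        n_obs=int(res.nobs),
    )


def bootstrap_anova(
    dataset: pd.DataFrame | list[PairCovariates],
    n_boot: int = 200,
    rng_seed: int = 0,
    response: str = RESPONSE_NAME,
    terms: list[str] | None = None,
) -> pd.DataFrame:
    """Per-term ANOVA-effect (Type II F) distributions over bootstrap resamples.

    Pairs are resampled with replacement ``n_boot`` times and the model
    refit each time; rank-deficient resamples are redrawn (logged). Returns
    a long frame (bootstrap, term, F).
    """
    df = covariates_frame(dataset) if isinstance(dataset, list) else dataset
    terms = list(terms or [t for t in COVARIATE_NAMES if t in df.columns])
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n = len(df)
    rows = []
    b = 0
    attempts = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        sample = df.iloc[idx]
        attempts += 1
        if attempts > 10 * n_boot:
            raise ProcessingError("too many rank-deficient bootstrap samples")
        if np.linalg.matrix_rank(_design(sample, terms)) < len(terms) + 1:
            logger.warning("rank-deficient bootstrap sample redrawn")
            continue
        anova = type2_anova(sample.reset_index(drop=True), response, terms)
        for t in terms:
            rows.append({"bootstrap": b, "term": t, "F": float(anova.loc[t, "F"])})
        b += 1
    return pd.DataFrame(rows)


def bootstrap_summary(boot: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics (median, quartiles, adjacent values) per term."""
    from .effect import adjacent_values

    rows = []
    for term, grp in boot.groupby("term", sort=False):
        f = grp["F"].to_numpy(float)
        q1, med, q3 = np.percentile(f, [25, 50, 75])
        lo_adj, hi_adj = adjacent_values(f)
        rows.append(
            {
                "term": term,
                "median": med,
                "q1": q1,
                "q3": q3,
                "lower_adjacent": lo_adj,
                "upper_adjacent": hi_adj,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def effect_consistency_correlation(
    dataset: pd.DataFrame | list[PairCovariates],
) -> tuple[float, float]:
    """Pearson correlation of average maximum effect vs maximum consistency."""
    df = covariates_frame(dataset) if isinstance(dataset, list) else dataset
    if len(df) < 3:
        raise ValidationError("need at least 3 pairs")
    x = df["average_max_effect"].to_numpy(float)
    y = df[RESPONSE_NAME].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ProcessingError("zero variance; correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
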