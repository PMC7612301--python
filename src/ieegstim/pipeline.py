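"""End-to-end orchestration: sessions in, summary tables out.

``process_session`` runs one recording through segment extraction,
artifact screening (on raw segments — both screening criteria compare raw
average voltages), detrending, common-average re-referencing, Welch band
power and the effect statistic U for both the stimulation and baseline
conditions.

``run_pipeline`` processes a cohort of synthetic session pairs and emits
the study's summary analyses: per-session effect matrices and extrema, per
pair the consistency curve and covariates, the baseline consistency band
with the three exceedance fractions (radius 0, radius 3, global maximum),
amplitude/frequency screens, the consistency regression and its bootstrap
ANOVA, all written as CSV plus a JSON manifest.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import consistency as cons
from . import effect as eff
from . import pairs as pr
from . import preprocess as pp
from . import session_io, spectral
from .errors import ProcessingError, ValidationError
from .session import SessionRecording
from .synth import GeneratorConfig, generate_session_pair

logger = logging.getLogger(__name__)

COMPARISON_RADII = (0.0, 3.0)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_pairs: int = 2
    seed: int = 0
    n_boot: int = 200
    welch_window: str = "hamming"
    continuity_correction: bool = False
    artifact_t1: float | None = None
    artifact_t2_mult: float = 5.0
    radius_step: float = cons.RADIUS_STEP
    stop_fraction: float = cons.STOP_FRACTION
    min_points: int = cons.MIN_POINTS
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.radius_step <= 0:
            raise ValidationError("radius_step must be > 0")
        if not 0 < self.stop_fraction < 1:
            raise ValidationError("stop_fraction must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", {})
        if "effect_map" in gen:
            gen["effect_map"] = {
                (ch, band): float(f)
                for (ch, band), f in (
                    ((e["channel"], e["band"]), e["factor"]) for e in gen["effect_map"]
                )
            }
        for key in ("intra_group_gap", "inter_group_gap", "artifact_channels"):
            if key in gen:
                gen[key] = tuple(gen[key])
        return cls(generator=GeneratorConfig(**gen), **raw)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["generator"]["effect_map"] = {
            f"{ch}:{band}": f for (ch, band), f in self.generator.effect_map.items()
        }
        return d


@dataclass
class SessionResult:
    """All products of one processed session."""

    recording_id: str
    summary: pr.SessionSummary
    band_power: pd.DataFrame
    mask: pp.ChannelMask
    n_stim_pairs: int
    n_baseline_pairs: int


def process_session(
    recording: SessionRecording, config: RunConfig | None = None
) -> SessionResult:
    """One session through preprocessing, spectra and effect statistics."""
    config = config or RunConfig()
    epochs = pp.find_baseline_epochs(recording.events, recording.duration)
    stim_segments = pp.extract_stim_segments(recording)
    if not stim_segments:
        raise ProcessingError(f"session {recording.session_id}: no usable trials")
    mask = pp.detect_artifact_channels(
        stim_segments,
        t1=config.artifact_t1,
        t2_mult=config.artifact_t2_mult,
        sampling_rate=recording.sampling_rate,
    )
    base_segments = pp.extract_baseline_segments(recording, epochs)
    segments = [pp.detrend_and_center(s) for s in stim_segments + base_segments]
    segments = pp.common_average_rereference(segments, mask, recording.stim_channels)

    table = spectral.band_power_table(
        segments,
        recording.sampling_rate,
        window=config.welch_window,
        session_id=recording.session_id,
    )
    stim_em = eff.session_effect(
        table, "stimulation", recording.session_id, config.continuity_correction
    )
    base_em = eff.session_effect(
        table, "baseline", recording.session_id, config.continuity_correction
    )
    events = recording.events
    anode = events["anode"].iloc[0]
    cathode = events["cathode"].iloc[0]
    coords = recording.channel_coords
    summary = pr.SessionSummary(
        session_id=recording.session_id,
        start_timestamp=recording.start_timestamp,
        task_label=recording.task_label,
        stim_amplitude=float(events["amplitude"].median()),
        stim_frequency=float(events["frequency"].median()),
        anode_xyz=coords[recording.channel_index(anode)],
        cathode_xyz=coords[recording.channel_index(cathode)],
        stim_effect=stim_em,
        baseline_effect=base_em,
        baseline_stats=pr.baseline_summary_stats(table),
    )
    logger.info(
        "session %s: %d trials, %d baseline pairs, %d channels excluded (%s)",
        recording.session_id,
        len(stim_segments) // 2,
        len(base_segments) // 2,
        len(mask.excluded_labels()),
        ",".join(mask.excluded_labels()) or "none",
    )
    return SessionResult(
        recording_id=recording.session_id,
        summary=summary,
        band_power=table,
        mask=mask,
        n_stim_pairs=len(stim_segments) // 2,
        n_baseline_pairs=len(base_segments) // 2,
    )


def effect_matrix_frame(matrices: Sequence[eff.EffectMatrix]) -> pd.DataFrame:
    """Long-format CSV contract for effect matrices."""
    rows = []
    for em in matrices:
        for ch in em.U.index:
            for band in em.U.columns:
                rows.append(
                    {
                        "session": em.session_id,
                        "condition": em.condition,
                        "channel": ch,
                        "band": band,
                        "U": em.U.loc[ch, band],
                        "n_pairs": em.n_pairs.loc[ch, band],
                    }
                )
    return pd.DataFrame(rows)


def amplitude_effect_screen(
    summaries: Sequence[pr.SessionSummary],
    pair_rows: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Correlation screens of stimulation parameters against effect size.

    Session-level: Pearson correlations of each session's min/max U with
    its stimulation amplitude and frequency. Pair-level (when ``pair_rows``
    with columns ``abs_effect_difference`` and ``abs_amplitude_difference``
    is given): correlation of the two absolute differences.
    """
    if len(summaries) < 3:
        raise ValidationError("need at least 3 sessions for the screen")
    rows = []
    mins = np.array([np.nanmin(s.stim_effect.U.to_numpy()) for s in summaries])
    maxs = np.array([np.nanmax(s.stim_effect.U.to_numpy()) for s in summaries])
    for param in ("stim_amplitude", "stim_frequency"):
        x = np.array([getattr(s, param) for s in summaries])
        for name, y in (("min_U", mins), ("max_U", maxs)):
            if x.std() == 0 or y.std() == 0:
                rows.append({"screen": f"{param}_vs_{name}", "r": np.nan, "p": np.nan})
                continue
            r, p = scipy.stats.pearsonr(x, y)
            rows.append({"screen": f"{param}_vs_{name}", "r": r, "p": p})
    if pair_rows is not None and len(pair_rows) >= 3:
        x = pair_rows["abs_amplitude_difference"].to_numpy(float)
        y = pair_rows["abs_effect_difference"].to_numpy(float)
        if x.std() > 0 and y.std() > 0:
            r, p = scipy.stats.pearsonr(x, y)
            rows.append({"screen": "amp_difference_vs_effect_difference", "r": r, "p": p})
        else:
            rows.append(
                {"screen": "amp_difference_vs_effect_difference", "r": np.nan, "p": np.nan}
            )
    return pd.DataFrame(rows)


@dataclass
class RunResult:
    """Bundle returned by :func:`run_pipeline`."""

    sessions: list[SessionResult]
    curves: pd.DataFrame
    pair_summary: pd.DataFrame
    covariates: pd.DataFrame
    band: cons.ConsistencyBand
    exceedance: dict[str, float]
    screens: pd.DataFrame
    model: pr.ModelFit | None
    bootstrap: pd.DataFrame | None
    effect_consistency_r: tuple[float, float] | None
    tables: dict[str, pd.DataFrame]


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Generate, process and summarise ``config.n_pairs`` session pairs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_pairs)
    sessions: list[SessionResult] = []
    stim_points: list[np.ndarray] = []
    base_points: list[np.ndarray] = []
    pair_meta: list[dict] = []

    for i, seq in enumerate(seeds):
        gen = replace(
            config.generator, rng_seed=int(seq.generate_state(1)[0] % 2**31)
        )
        rec1, rec2 = generate_session_pair(
            gen, session_ids=(f"pair{i}_s0", f"pair{i}_s1")
        )
        try:
            res1 = process_session(rec1, config)
            res2 = process_session(rec2, config)
        except ProcessingError as exc:
            raise ProcessingError(f"pair {i}: {exc}") from exc
        sessions += [res1, res2]
        stim_points.append(cons.pair_points(res1.summary.stim_effect, res2.summary.stim_effect))
        base_points.append(
            cons.pair_points(res1.summary.baseline_effect, res2.summary.baseline_effect)
        )
        pair_meta.append(
            {"pair_id": f"pair{i}", "s1": res1, "s2": res2, "surface": rec1.brain_surface}
        )

    band = cons.baseline_consistency_band(
        base_points,
        step=config.radius_step,
        stop_fraction=config.stop_fraction,
        min_points=config.min_points,
    )

    curve_rows, summary_rows, covs = [], [], []
    for meta, pts in zip(pair_meta, stim_points):
        curve = cons.consistency_curve(
            pts,
            step=config.radius_step,
            stop_fraction=config.stop_fraction,
            min_points=config.min_points,
        )
        for r, c, n in zip(curve.radii, curve.coefficients, curve.n_remaining):
            curve_rows.append(
                {"pair_id": meta["pair_id"], "radius": r, "n_remaining": n, "coefficient": c}
            )
        exceeds = {}
        for radius in COMPARISON_RADII:
            idx = np.where(np.isclose(curve.radii, radius))[0]
            bidx = np.where(np.isclose(band.radii, radius))[0]
            if idx.size and bidx.size:
                exceeds[radius] = bool(
                    curve.coefficients[idx[0]] > band.upper[bidx[0]]
                )
            else:
                exceeds[radius] = False
        summary_rows.append(
            {
                "pair_id": meta["pair_id"],
                "max_consistency": curve.max_consistency,
                "max_radius": curve.max_radius,
                "exceeds_band_at_radius0": exceeds[0.0],
                "exceeds_band_at_radius3": exceeds[3.0],
                "exceeds_band_global_max": bool(curve.max_consistency > band.global_upper),
            }
        )
        covs.append(
            pr.build_pair_covariates(
                meta["s1"].summary,
                meta["s2"].summary,
                meta["surface"],
                curve.max_consistency,
                pair_id=meta["pair_id"],
            )
        )
    curves = pd.DataFrame(curve_rows)
    pair_summary = pd.DataFrame(summary_rows)
    cov_df = pr.covariates_frame(covs)

    exceedance = {
        "fraction_above_band_radius0": float(pair_summary["exceeds_band_at_radius0"].mean()),
        "fraction_above_band_radius3": float(pair_summary["exceeds_band_at_radius3"].mean()),
        "fraction_above_band_global_max": float(
            pair_summary["exceeds_band_global_max"].mean()
        ),
    }

    diff_rows = []
    for meta in pair_meta:
        t, capped = eff.pair_effect_difference(
            meta["s1"].summary.stim_effect, meta["s2"].summary.stim_effect
        )
        diff_rows.append(
            {
                "pair_id": meta["pair_id"],
                "abs_effect_difference": t,
                "abs_amplitude_difference": abs(
                    meta["s1"].summary.stim_amplitude - meta["s2"].summary.stim_amplitude
                ),
                "capped": capped,
            }
        )
    diff_df = pd.DataFrame(diff_rows)
    screens = amplitude_effect_screen([s.summary for s in sessions], diff_df)

    model = None
    bootstrap = None
    corr = None
    if len(cov_df) > len(pr.COVARIATE_NAMES) + 1:
        model = pr.fit_consistency_model(cov_df)
        bootstrap = pr.bootstrap_anova(cov_df, n_boot=config.n_boot, rng_seed=config.seed)
        corr = pr.effect_consistency_correlation(cov_df)
    else:
        logger.info(
            "only %d pairs; consistency regression needs > %d — skipped",
            len(cov_df),
            len(pr.COVARIATE_NAMES) + 1,
        )

    tables = {
        "effect_matrices": effect_matrix_frame(
            [s.summary.stim_effect for s in sessions]
            + [s.summary.baseline_effect for s in sessions]
        ),
        "consistency_curves": curves,
        "pair_summary": pair_summary,
        "pair_covariates": cov_df,
        "baseline_band": pd.DataFrame(
            {
                "radius": band.radii,
                "lower": band.lower,
                "upper": band.upper,
                "n_pairs": band.n_pairs,
            }
        ),
        "screens": screens,
        "pair_differences": diff_df,
    }
    if bootstrap is not None:
        tables["bootstrap_anova"] = bootstrap
    if write:
        manifest = {
            "seed": config.seed,
            "config": config.to_manifest(),
            "config_hash": session_io.config_hash(config.to_manifest()),
            "exceedance": exceedance,
        }
        if model is not None:
            manifest["model"] = {
                "r_squared": model.r_squared,
                "adj_r_squared": model.adj_r_squared,
            }
        if corr is not None:
            manifest["effect_consistency_r"], manifest["effect_consistency_p"] = corr
        session_io.write_results(tables, config.out_dir, manifest)
    return RunResult(
        sessions=sessions,
        curves=curves,
        pair_summary=pair_summary,
        covariates=cov_df,
        band=band,
        exceedance=exceedance,
        screens=screens,
        model=model,
        bootstrap=bootstrap,
        effect_consistency_r=corr,
        tables=tables,
    )
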