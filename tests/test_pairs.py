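"""Stimulation depth, pair covariates, OLS fit and bootstrap ANOVA."""

import numpy as np
import pandas as pd
import pytest

from ieegstim import pairs as pr
from ieegstim.effect import EffectMatrix
from ieegstim.errors import ProcessingError, ValidationError


def sphere_surface(radius=50.0, n=200):
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    return radius * np.column_stack([r * np.cos(golden * i), r * np.sin(golden * i), z])


class TestStimulationDepth:
    def test_sphere_centre_positive_radius(self):
        surface = sphere_surface(50.0)
        d = pr.stimulation_depth(np.zeros(3), np.zeros(3), surface)
        assert d == pytest.approx(50.0, rel=0.01)

    def test_outside_point_negative(self):
        # dense sampling so the nearest surface point is close to (50, 0, 0)
        surface = sphere_surface(50.0, n=4000)
        mid = np.array([60.0, 0.0, 0.0])
        d = pr.stimulation_depth(mid, mid, surface)
        assert d == pytest.approx(-10.0, rel=0.05)

    def test_point_on_surface_zero(self):
        surface = sphere_surface(50.0)
        p = surface[0]
        assert pr.stimulation_depth(p, p, surface) == 0.0

    def test_midpoint_used(self):
        surface = sphere_surface(50.0)
        d = pr.stimulation_depth(
            np.array([10.0, 0, 0]), np.array([-10.0, 0, 0]), surface
        )
        assert d == pytest.approx(50.0, rel=0.01)

    def test_degenerate_surface_rejected(self):
        flat = np.column_stack([np.random.rand(10), np.random.rand(10), np.zeros(10)])
        with pytest.raises(ValidationError):
            pr.stimulation_depth(np.zeros(3), np.zeros(3), flat)


def _summary(session_id, start, task, amp, U_values, rng, freq=50.0):
    channels = [f"c{i}" for i in range(len(U_values))]
    U = pd.DataFrame({"theta": U_values}, index=channels)
    em = EffectMatrix(U, U * 0 + 30, "stimulation", session_id)
    stats = pd.DataFrame(
        {
            "channel": np.repeat(channels, 2),
            "band": "theta",
            "role": ["pre", "post"] * len(channels),
            "mean": rng.standard_normal(2 * len(channels)),
            "sd": np.abs(rng.standard_normal(2 * len(channels))) + 0.5,
        }
    )
    return pr.SessionSummary(
        session_id=session_id,
        start_timestamp=start,
        task_label=task,
        stim_amplitude=amp,
        stim_frequency=freq,
        anode_xyz=np.array([5.0, 0, 0]),
        cathode_xyz=np.array([-5.0, 0, 0]),
        stim_effect=em,
        baseline_effect=em,
        baseline_stats=stats,
    )


class TestBuildPairCovariates:
    def test_identical_sessions_zero_differences(self, rng):
        s = _summary("a", 0.0, "t1", 1.0, rng.standard_normal(6), rng)
        cov = pr.build_pair_covariates(s, s, sphere_surface(), max_consistency=0.3)
        assert cov.session_time_difference == 0.0
        assert cov.baseline_mean_difference == 0.0
        assert cov.baseline_sd_difference == 0.0
        assert cov.stim_amplitude_difference == 0.0
        assert cov.task_difference == 0

    def test_amplitude_average_and_difference(self, rng):
        s1 = _summary("a", 0.0, "t1", 1.0, rng.standard_normal(6), rng)
        s2 = _summary("b", 86_400.0, "t2", 2.0, rng.standard_normal(6), rng)
        cov = pr.build_pair_covariates(s1, s2, sphere_surface(), 0.5)
        assert cov.average_stim_amplitude == pytest.approx(1.5)
        assert cov.stim_amplitude_difference == pytest.approx(1.0)
        assert cov.session_time_difference == pytest.approx(86_400.0)
        assert cov.task_difference == 1

    def test_symmetric_in_session_order(self, rng):
        s1 = _summary("a", 0.0, "t1", 1.0, rng.standard_normal(6), rng)
        s2 = _summary("b", 3600.0, "t2", 2.5, rng.standard_normal(6), rng)
        c12 = pr.build_pair_covariates(s1, s2, sphere_surface(), 0.5)
        c21 = pr.build_pair_covariates(s2, s1, sphere_surface(), 0.5)
        for name in pr.COVARIATE_NAMES:
            if name == "stim_depth":
                continue  # depth follows session 1's location (shared in a real pair)
            assert getattr(c12, name) == pytest.approx(getattr(c21, name))

    def test_average_effect_extrema(self, rng):
        s1 = _summary("a", 0.0, "t", 1.0, [0.0, 2.0, -1.0], rng)
        s2 = _summary("b", 0.0, "t", 1.0, [1.0, 4.0, -3.0], rng)
        cov = pr.build_pair_covariates(s1, s2, sphere_surface(), 0.5)
        assert cov.average_max_effect == pytest.approx(3.0)  # (2 + 4) / 2
        assert cov.average_min_effect == pytest.approx(-2.0)  # (-1 - 3) / 2

    def test_frequency_mismatch_rejected(self, rng):
        s1 = _summary("a", 0.0, "t", 1.0, rng.standard_normal(4), rng, freq=50.0)
        s2 = _summary("b", 0.0, "t", 1.0, rng.standard_normal(4), rng, freq=100.0)
        with pytest.raises(ValidationError, match="frequency"):
            pr.build_pair_covariates(s1, s2, sphere_surface(), 0.5)


def synthetic_dataset(rng, n=101, signal_coef=0.6, noise_sd=0.1):
    df = pd.DataFrame(
        {name: rng.standard_normal(n) for name in pr.COVARIATE_NAMES}
    )
    df["task_difference"] = rng.integers(0, 2, n)
    df["pair_id"] = [f"p{i}" for i in range(n)]
    df[pr.RESPONSE_NAME] = signal_coef * df["average_max_effect"] + rng.normal(
        0, noise_sd, n
    )
    return df


class TestModelFit:
    def test_recovers_planted_coefficient(self, rng):
        df = synthetic_dataset(rng)
        fit = pr.fit_consistency_model(df)
        lo, hi = fit.conf_int.loc["average_max_effect"]
        assert lo <= 0.6 <= hi
        assert fit.anova["F"].idxmax() == "average_max_effect"
        assert fit.adj_r_squared <= fit.r_squared

    def test_pure_noise_low_r2(self, rng):
        df = synthetic_dataset(rng, signal_coef=0.0, noise_sd=1.0)
        fit = pr.fit_consistency_model(df)
        assert fit.r_squared < 0.3
        assert fit.adj_r_squared <= fit.r_squared

    def test_duplicated_covariate_dropped(self, rng):
        df = synthetic_dataset(rng)
        df["stim_depth"] = df["average_stim_amplitude"]  # perfect alias
        fit = pr.fit_consistency_model(df)
        assert len(fit.terms) == len(pr.COVARIATE_NAMES) - 1
        assert "stim_depth" not in fit.terms

    def test_too_few_rows_rejected(self, rng):
        df = synthetic_dataset(rng, n=10)
        with pytest.raises(ValidationError):
            pr.fit_consistency_model(df)

    def test_residuals_orthogonal_to_design(self, rng):
        df = synthetic_dataset(rng)
        fit = pr.fit_consistency_model(df)
        X = np.column_stack(
            [np.ones(len(df))] + [df[t].to_numpy(float) for t in fit.terms]
        )
        beta = fit.params.to_numpy()
        resid = df[pr.RESPONSE_NAME].to_numpy() - X @ beta
        assert np.abs(X.T @ resid).max() < 1e-8


class TestTypeIIAnova:
    def test_matches_statsmodels(self, rng):
        """Cross-check the hand-rolled Type II F against statsmodels."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = synthetic_dataset(rng, n=60)
        terms = list(pr.COVARIATE_NAMES)
        ours = pr.type2_anova(df, terms=terms)
        formula = f"{pr.RESPONSE_NAME} ~ " + " + ".join(terms)
        theirs = sm.stats.anova_lm(ols(formula, data=df).fit(), typ=2)
        for t in terms:
            assert ours.loc[t, "F"] == pytest.approx(theirs.loc[t, "F"], rel=1e-8)
            assert ours.loc[t, "p_value"] == pytest.approx(
                theirs.loc[t, "PR(>F)"], abs=1e-10
            )


class TestBootstrapAnova:
    def test_deterministic_under_seed(self, rng):
        df = synthetic_dataset(rng, n=40)
        a = pr.bootstrap_anova(df, n_boot=5, rng_seed=3)
        b = pr.bootstrap_anova(df, n_boot=5, rng_seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_single_bootstrap_matches_direct_fit(self, rng):
        df = synthetic_dataset(rng, n=40)
        boot = pr.bootstrap_anova(df, n_boot=1, rng_seed=7)
        idx = np.random.default_rng(7).integers(0, len(df), len(df))
        direct = pr.type2_anova(df.iloc[idx].reset_index(drop=True))
        for t in pr.COVARIATE_NAMES:
            got = float(boot.loc[boot["term"] == t, "F"].iloc[0])
            assert got == pytest.approx(direct.loc[t, "F"])

    def test_deterministic_response_dominates_every_sample(self, rng):
        df = synthetic_dataset(rng, n=60, noise_sd=1e-8)
        boot = pr.bootstrap_anova(df, n_boot=20, rng_seed=0)
        wide = boot.pivot(index="bootstrap", columns="term", values="F")
        assert (wide.idxmax(axis=1) == "average_max_effect").all()

    def test_median_concentrates_near_full_sample_effect(self, rng):
        df = synthetic_dataset(rng, n=101)
        full = pr.type2_anova(df)
        boot = pr.bootstrap_anova(df, n_boot=400, rng_seed=1)
        med = boot.groupby("term")["F"].median()
        f_full = full.loc["average_max_effect", "F"]
        assert abs(med["average_max_effect"] - f_full) / f_full < 0.5

    def test_summary_boxplot_statistics(self, rng):
        df = synthetic_dataset(rng, n=40)
        boot = pr.bootstrap_anova(df, n_boot=50, rng_seed=2)
        summary = pr.bootstrap_summary(boot)
        assert set(summary.columns) == {
            "median", "q1", "q3", "lower_adjacent", "upper_adjacent"
        }
        assert (summary["q1"] <= summary["median"]).all()
        assert (summary["median"] <= summary["q3"]).all()


class TestEffectConsistencyCorrelation:
    def test_exact_proportionality_gives_unity(self, rng):
        df = synthetic_dataset(rng, n=30)
        df[pr.RESPONSE_NAME] = 2.0 * df["average_max_effect"]
        r, p = pr.effect_consistency_correlation(df)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_bruteforce_covariance(self, rng):
        df = synthetic_dataset(rng, n=50)
        r, _ = pr.effect_consistency_correlation(df)
        x = df["average_max_effect"].to_numpy()
        y = df[pr.RESPONSE_NAME].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        oracle = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged(self, rng):
        df = synthetic_dataset(rng, n=10)
        df["average_max_effect"] = 1.0
        with pytest.raises(ProcessingError):
            pr.effect_consistency_correlation(df)
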