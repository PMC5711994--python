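"""Cox engine: partial likelihood, ties, truncation, Schoenfeld residuals,
time-varying-coefficient smoothing and (reverse) Kaplan-Meier."""

import numpy as np
import pandas as pd
import pytest

from landcox.coxfit import (
    NoEventsError,
    SingularModelError,
    fit_cox,
    fit_report,
    kaplan_meier,
    ph_score_test,
    read_counting_csv,
    schoenfeld_tv_coefficient,
)
from landcox.experiments import counting_process_encoding
from landcox.simulate import SimConfig, simulate_illness_death


def three_subject_data():
    # all events, covariate pattern (1, 0, 1) at times (1, 2, 3)
    return pd.DataFrame(
        {
            "start": [0.0, 0.0, 0.0],
            "stop": [1.0, 2.0, 3.0],
            "event": [1, 1, 1],
            "x": [1.0, 0.0, 1.0],
        }
    )


def naive_breslow_loglik(df, beta):
    """Independent O(n^2) partial likelihood (no ties in the inputs used)."""
    ll = 0.0
    for _, row in df[df["event"] == 1].iterrows():
        t = row["stop"]
        risk = df[(df["start"] < t) & (df["stop"] >= t)]
        ll += beta * row["x"] - np.log(np.sum(np.exp(beta * risk["x"])))
    return ll


class TestPartialLikelihood:
    def test_three_subject_mle_matches_grid_search(self):
        df = three_subject_data()
        fit = fit_cox(df, ["x"])
        # closed form: 2 e^{2 beta} = 1  =>  beta = -log(2)/2
        assert fit.coef[0] == pytest.approx(-0.5 * np.log(2.0), abs=1e-6)
        grid = np.linspace(-5, 5, 20001)
        lls = [naive_breslow_loglik(df, b) for b in grid]
        assert fit.coef[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)
        assert fit.loglik == pytest.approx(max(lls), abs=1e-6)

    def test_covariate_without_variation_is_singular(self):
        df = three_subject_data().assign(x=0.0)
        with pytest.raises(SingularModelError):
            fit_cox(df, ["x"])

    def test_no_events_rejected(self):
        df = three_subject_data().assign(event=0)
        with pytest.raises(NoEventsError):
            fit_cox(df, ["x"])

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        tt = rng.exponential(1.0 / (0.2 * np.exp(0.7 * x)))
        df = pd.DataFrame({"start": 0.0, "stop": tt, "event": 1, "x": x})
        fe = fit_cox(df, ["x"], ties="efron")
        fb = fit_cox(df, ["x"], ties="breslow")
        assert fe.coef[0] == pytest.approx(fb.coef[0], abs=1e-12)
        assert fe.loglik == pytest.approx(fb.loglik, abs=1e-9)

    def test_left_truncation_equals_time_reset_encoding(self):
        """A landmark dataset gives the same fit whether encoded as (s,
        stop] with left truncation or with times reset to stop - s."""
        subjects = simulate_illness_death(
            SimConfig(n=2000, seed=101, horizon=50.0), 0.2, 0.1, 1.0
        )
        from landcox.experiments import build_landmark_dataset

        lm = build_landmark_dataset(subjects, 2.0).rows
        reset = lm.assign(start=0.0, stop=lm["stop"] - 2.0)
        f1 = fit_cox(lm, ["x"])
        f2 = fit_cox(reset, ["x"])
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-10)

    def test_loglik_at_optimum_beats_null(self):
        df = three_subject_data()
        fit = fit_cox(df, ["x"])
        assert fit.loglik >= fit.loglik_null

    def test_schoenfeld_residuals_sum_to_zero_at_mle(self):
        subjects = simulate_illness_death(
            SimConfig(n=3000, seed=103, horizon=50.0), 0.2, 0.1, 1.0
        )
        fit = fit_cox(counting_process_encoding(subjects), ["x"])
        assert abs(fit.schoenfeld["resid_x"].sum()) < 1e-6

    def test_se_matches_numerical_hessian_of_independent_loglik(self):
        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(size=n)
        tt = rng.exponential(1.0 / (0.3 * np.exp(0.5 * x)))
        cens = rng.uniform(1, 6, n)
        df = pd.DataFrame(
            {
                "start": 0.0,
                "stop": np.minimum(tt, cens),
                "event": (tt <= cens).astype(int),
                "x": x,
            }
        )
        fit = fit_cox(df, ["x"])
        h = 1e-4
        b = fit.coef[0]
        d2 = (
            naive_breslow_loglik(df, b + h)
            - 2 * naive_breslow_loglik(df, b)
            + naive_breslow_loglik(df, b - h)
        ) / h**2
        assert fit.se[0] == pytest.approx(1.0 / np.sqrt(-d2), rel=1e-4)

    def test_matches_lifelines_on_counting_process_data(self):
        lifelines = pytest.importorskip("lifelines")
        subjects = simulate_illness_death(
            SimConfig(n=3000, seed=107, horizon=50.0), 0.2, 0.1, 1.0
        )
        df = counting_process_encoding(subjects)
        ours = fit_cox(df, ["x"])
        ctv = lifelines.CoxTimeVaryingFitter()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(
                df.rename(columns={"event": "ev"}),
                id_col="id", start_col="start", stop_col="stop", event_col="ev",
            )
        assert ours.coef[0] == pytest.approx(float(ctv.params_.iloc[0]), abs=1e-7)
        assert ours.se[0] == pytest.approx(
            float(ctv.standard_errors_.iloc[0]), abs=1e-7
        )

    def test_efron_ties_match_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(size=n)
        tt = np.ceil(rng.exponential(3.0 / np.exp(0.5 * x)))  # heavy ties
        df = pd.DataFrame(
            {"start": 0.0, "stop": tt + 0.0, "event": 1, "x": x}
        )
        ours = fit_cox(df, ["x"], ties="efron")
        cph = lifelines.CoxPHFitter()
        cph.fit(df[["stop", "event", "x"]], duration_col="stop", event_col="event")
        assert ours.coef[0] == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)

    def test_recovers_generating_coefficient_on_td_data(self):
        subjects = simulate_illness_death(
            SimConfig(n=10_000, seed=109, horizon=50.0), 0.2, 0.1, 1.0
        )
        fit = fit_cox(counting_process_encoding(subjects), ["x"])
        assert abs(fit.coef[0] - 1.0) < 3 * fit.se[0]

    def test_divergence_flagged_on_separated_data(self):
        # perfectly separated: all events carry x=1, all censored x=0
        n = 12
        df = pd.DataFrame(
            {
                "start": 0.0,
                "stop": np.arange(1.0, 2 * n + 1),
                "event": [1] * n + [0] * n,
                "x": [1.0] * n + [0.0] * n,
            }
        )
        with pytest.warns(RuntimeWarning):
            fit = fit_cox(df, ["x"])
        assert fit.divergent

    def test_report_is_json_serialisable(self):
        import json

        fit = fit_cox(three_subject_data(), ["x"])
        json.dumps(fit_report(fit))


class TestTimeVaryingCoefficient:
    def test_curve_invariant_to_covariate_location_shift(self):
        subjects = simulate_illness_death(
            SimConfig(n=2000, seed=113, horizon=50.0), 0.2, 0.1, 1.0
        )
        df = counting_process_encoding(subjects)
        c1 = schoenfeld_tv_coefficient(fit_cox(df, ["x"]))
        c2 = schoenfeld_tv_coefficient(fit_cox(df.assign(x=df["x"] + 5.0), ["x"]))
        np.testing.assert_allclose(c1["beta_t"], c2["beta_t"], atol=1e-8)

    def test_ph_score_test_keeps_nominal_level_under_the_null(self):
        """Data generated under proportional hazards with a time-fixed
        covariate: the trend test should be non-significant at the 5% level
        in at least 90% of replicates."""
        rejections = 0
        n_reps = 100
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            n = 300
            x = rng.integers(0, 2, n).astype(float)
            tt = rng.exponential(1.0 / (0.1 * np.exp(0.8 * x)))
            cens = rng.uniform(5, 15, n)
            df = pd.DataFrame(
                {
                    "start": 0.0,
                    "stop": np.minimum(tt, cens),
                    "event": (tt <= cens).astype(int),
                    "x": x,
                }
            )
            _, p = ph_score_test(fit_cox(df, ["x"]))
            rejections += p < 0.05
        assert rejections <= 0.10 * n_reps

    def test_too_few_events_rejected(self):
        df = three_subject_data()
        with pytest.raises(Exception, match="10 events"):
            schoenfeld_tv_coefficient(fit_cox(df, ["x"]))


class TestKaplanMeier:
    def test_two_subject_closed_form(self):
        km = kaplan_meier([1.0, 2.0], [1, 1])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])
        # median convention: smallest time with survival <= 0.5
        assert km.median == 1.0

    def test_all_censored_flat_curve_without_median(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at(5.0) == 1.0
        assert km.median is None

    def test_exponential_sample_matches_true_survival(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(10.0, size=10_000)
        km = kaplan_meier(t, np.ones_like(t, dtype=int))
        idx = np.searchsorted(km.times, 5.0, side="right") - 1
        se = np.sqrt(km.variance[idx])
        assert abs(km.survival_at(5.0) - np.exp(-0.5)) < 3 * se

    def test_matches_lifelines_estimate(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(19)
        t = rng.exponential(5.0, 500)
        c = rng.uniform(0, 12, 500)
        obs = np.minimum(t, c)
        ev = (t <= c).astype(int)
        km = kaplan_meier(obs, ev)
        kmf = lifelines.KaplanMeierFitter().fit(obs, ev)
        grid = np.array([1.0, 3.0, 6.0])
        np.testing.assert_allclose(
            km.survival_at(grid),
            kmf.survival_function_at_times(grid).to_numpy(),
            atol=1e-10,
        )

    def test_reverse_mode_estimates_censoring_distribution(self):
        rng = np.random.default_rng(23)
        n = 4000
        t = rng.exponential(20.0, n)  # long survival
        c = rng.uniform(0, 10, n)     # known censoring law, median 5
        obs = np.minimum(t, c)
        ev = (t <= c).astype(int)
        rkm = kaplan_meier(obs, ev, reverse=True)
        assert rkm.median == pytest.approx(5.0, abs=0.4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestCountingCSV:
    def test_reader_validates_and_reports_rows(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {"id": [1, 1], "start": [0.0, 2.0], "stop": [2.0, 1.0],
             "event": [0, 1], "x": [0, 1]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="start >= stop"):
            read_counting_csv(path)
        path2 = tmp_path / "overlap.csv"
        pd.DataFrame(
            {"id": [1, 1], "start": [0.0, 1.0], "stop": [2.0, 3.0],
             "event": [0, 1], "x": [0, 1]}
        ).to_csv(path2, index=False)
        with pytest.raises(ValueError, match="overlap"):
            read_counting_csv(path2)
        path3 = tmp_path / "missing.csv"
        pd.DataFrame({"id": [1], "start": [0.0]}).to_csv(path3, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_counting_csv(path3)
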