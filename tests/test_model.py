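"""Design assembly, IRLS fitting, deviance analysis, odds ratios and maps."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from noiselag import (
    Design,
    DesignSpec,
    LogisticFit,
    RankDeficiencyError,
    SeparationError,
    build_design,
    covariate_correlation,
    default_true_beta,
    design_columns,
    fit_logistic,
    generate_covariates,
    interpret_numeric_change,
    odds_ratio_table,
    predict_probability,
    probability_map,
    sequential_deviance,
)
from noiselag.model import MONTH_LEVELS, WEEKDAY_LEVELS
from noiselag.panel import LAG_COLUMNS


class TestBuildDesign:
    def test_weekday_levels_and_reference(self, small_design, small_dataset):
        cols = [c for c in small_design.columns if c.startswith("weekday[")]
        assert len(cols) == 6
        assert "weekday[Sunday]" not in cols
        # Sunday rows have all weekday indicators at zero
        dates = pd.to_datetime(small_dataset.trimmed["date"])
        sunday = (dates.dt.weekday == 6).to_numpy()
        block = small_design.X[:, small_design.term_slices["weekday"]]
        assert (block[sunday] == 0).all()
        assert (block[~sunday].sum(axis=1) == 1).all()

    def test_month_and_district_column_counts(self, small_design, small_dataset):
        assert sum(c.startswith("month[") for c in small_design.columns) == 11
        n_districts = len(small_dataset.lattice.districts)
        assert (
            sum(c.startswith("district[") for c in small_design.columns)
            == n_districts - 1
        )

    def test_log_inhab_natural_log(self, small_design, small_dataset):
        col = small_design.columns.index("log_inhab")
        unit = small_dataset.trimmed["unit_id"].iloc[0]
        year = pd.to_datetime(small_dataset.trimmed["date"].iloc[0]).year
        cov = small_dataset.covariates
        inhab = cov[(cov.unit_id == unit) & (cov.year == year)]["inhab"].item()
        assert small_design.X[0, col] == pytest.approx(math.log(inhab), rel=1e-12)

    def test_missing_covariate_record_named(self, small_dataset):
        cov = small_dataset.covariates
        partial = cov[~((cov.unit_id == "u001") & (cov.year == 2014))]
        with pytest.raises(ValueError, match="u001"):
            build_design(small_dataset.trimmed, partial)

    def test_untrimmed_panel_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="undefined lags"):
            build_design(small_dataset.panel, small_dataset.covariates)

    def test_response_is_noisebin(self, small_design, small_dataset):
        assert (
            small_design.y == small_dataset.trimmed["noisebin"].to_numpy()
        ).all()


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        y = np.array([1] * 5 + [0] * 5, dtype=float)
        fit = fit_logistic(np.ones((10, 1)), y)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("k,n", [(3, 10), (7, 20), (1, 50)])
    def test_intercept_only_closed_form(self, k, n):
        y = np.zeros(n)
        y[:k] = 1.0
        fit = fit_logistic(np.ones((n, 1)), y)
        # accuracy is bounded by the score-based stopping rule (1e-8)
        assert fit.params[0] == pytest.approx(math.log(k / (n - k)), abs=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_generic_optimizer(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 50))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_true = rng.normal(scale=0.8, size=2)
        y = (rng.random(n) < expit(X @ beta_true)).astype(float)
        if y.sum() in (0, n):
            pytest.skip("degenerate draw")

        def nll(b):
            eta = X @ b
            return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

        try:
            fit = fit_logistic(X, y)
        except SeparationError:
            pytest.skip("separated draw")
        opt = minimize(nll, np.zeros(2), method="BFGS", tol=1e-12)
        assert np.allclose(fit.params, opt.x, atol=1e-6)
        assert fit.deviance == pytest.approx(2.0 * opt.fun, rel=1e-10)

    def test_separation_raises(self):
        X = np.column_stack([np.ones(8), np.array([-4.0, -3, -2, -1, 1, 2, 3, 4])])
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        X = np.column_stack([np.ones(40), x, 2.0 * x])
        y = (rng.random(40) < 0.5).astype(float)
        with pytest.raises(RankDeficiencyError, match="dup"):
            fit_logistic(X, y, columns=["intercept", "x", "dup"])

    def test_nonbinary_response_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(np.ones((4, 1)), np.array([0.0, 1.0, 2.0, 0.0]))

    def test_full_fit_residual_df(self, small_fit, small_design):
        assert small_fit.df_resid == small_design.n - small_design.X.shape[1]
        assert small_fit.converged


class TestOddsRatios:
    def test_published_style_arithmetic(self):
        # beta 0.63 (SE 0.02) corresponds to an 88% odds increase with a
        # Wald interval [exp(0.63 - 1.96*0.02), exp(0.63 + 1.96*0.02)]
        fit = LogisticFit(
            columns=["night"], params=np.array([0.63]), se=np.array([0.02]),
            loglik=0.0, deviance=0.0, null_deviance=0.0, df_resid=1, n_obs=2,
            n_iter=1, converged=True,
        )
        table = odds_ratio_table(fit)
        assert table["odds_ratio"].item() == pytest.approx(1.88, abs=0.005)
        assert table["ci_lower"].item() == pytest.approx(1.81, abs=0.005)
        assert table["ci_upper"].item() == pytest.approx(1.95, abs=0.005)

    def test_zero_beta_symmetric_interval(self):
        fit = LogisticFit(
            columns=["x"], params=np.array([0.0]), se=np.array([0.1]),
            loglik=0.0, deviance=0.0, null_deviance=0.0, df_resid=1, n_obs=2,
            n_iter=1, converged=True,
        )
        t = odds_ratio_table(fit)
        assert t["odds_ratio"].item() == 1.0
        assert t["ci_lower"].item() * t["ci_upper"].item() == pytest.approx(1.0, rel=1e-12)

    def test_ci_brackets_estimate(self, small_fit):
        t = odds_ratio_table(small_fit)
        assert (t["ci_lower"] <= t["odds_ratio"]).all()
        assert (t["odds_ratio"] <= t["ci_upper"]).all()

    def test_lag2_percent_increase(self):
        assert interpret_numeric_change(0.20, 1.0) == pytest.approx(1.22, abs=0.005)

    def test_log_scale_population_increase(self):
        assert interpret_numeric_change(
            0.93, 1.10, variable_on_log_scale=True
        ) == pytest.approx(1.09, abs=0.005)

    def test_log_scale_factor_e(self):
        assert interpret_numeric_change(
            0.93, math.e, variable_on_log_scale=True
        ) == pytest.approx(math.exp(0.93), rel=1e-12)

    def test_unit_multiplier_is_neutral(self):
        assert interpret_numeric_change(0.5, 1.0, variable_on_log_scale=True) == 1.0

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            interpret_numeric_change(0.5, 0.0, variable_on_log_scale=True)


def toy_design(seed=3, n=300, terms=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(terms)])
    beta = np.concatenate([[0.2], rng.normal(scale=0.5, size=terms)])
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    columns = ["intercept"] + [f"t{k}" for k in range(terms)]
    slices = {"intercept": slice(0, 1)}
    for k in range(terms):
        slices[f"t{k}"] = slice(1 + k, 2 + k)
    return Design(X=X, y=y, columns=columns, term_slices=slices, spec=DesignSpec())


class TestSequentialDeviance:
    def test_null_row_closed_form(self):
        d = toy_design()
        d.y = np.zeros(100)
        d.y[:30] = 1.0
        d.X = d.X[:100]
        table = sequential_deviance(d)
        # 2 * 100 * (-0.3 log 0.3 - 0.7 log 0.7)
        assert table.iloc[0]["resid_dev"] == pytest.approx(122.17286, abs=1e-4)
        assert table.iloc[0]["resid_df"] == 99

    def test_drops_nonnegative_and_telescoping(self, small_design):
        table = sequential_deviance(small_design)
        drops = table["deviance"].iloc[1:]
        assert (drops >= -1e-8).all()
        total = table.iloc[0]["resid_dev"] - table.iloc[-1]["resid_dev"]
        assert drops.sum() == pytest.approx(total, abs=1e-8)

    def test_district_added_last_by_default(self, small_design):
        table = sequential_deviance(small_design)
        assert table["term"].iloc[-1] == "district"
        assert table["resid_df"].is_monotonic_decreasing

    def test_matches_nested_refits_oracle(self):
        import statsmodels.api as sm

        d = toy_design(seed=8)
        table = sequential_deviance(d).set_index("term")
        devs = {}
        for upto in range(0, 4):
            cols = list(range(0, upto + 1))
            res = sm.GLM(d.y, d.X[:, cols], family=sm.families.Binomial()).fit()
            devs[upto] = res.deviance
        for k in range(3):
            drop = devs[k] - devs[k + 1]
            assert table.loc[f"t{k}", "deviance"] == pytest.approx(drop, abs=1e-6)

    def test_final_model_equals_full_fit(self, small_design, small_fit):
        table = sequential_deviance(small_design)
        assert table.iloc[-1]["resid_dev"] == pytest.approx(small_fit.deviance, abs=1e-6)
        assert table.iloc[-1]["resid_df"] == small_fit.df_resid


class TestPredict:
    def test_inverse_logit_values(self, small_fit):
        p = small_fit.params.size
        row = np.zeros(p)
        row[0] = 0.0
        fit = LogisticFit(
            columns=list(small_fit.columns), params=np.zeros(p), se=np.ones(p),
            loglik=0.0, deviance=0.0, null_deviance=0.0, df_resid=1, n_obs=2,
            n_iter=1, converged=True,
        )
        assert predict_probability(fit, row) == pytest.approx(0.5)
        fit.params[0] = 20.0
        assert predict_probability(fit, np.eye(p)[0]) > 0.999

    def test_mean_probability_equals_prevalence(self, small_fit, small_design):
        probs = small_fit.predict(small_design.X)
        assert probs.mean() == pytest.approx(small_design.y.mean(), abs=1e-8)

    def test_logit_round_trip(self, small_fit, small_design):
        eta = small_design.X[:50] @ small_fit.params
        probs = small_fit.predict(small_design.X[:50])
        assert np.allclose(np.log(probs / (1 - probs)), eta, atol=1e-10)


def synthetic_fit(lattice, beta_map):
    cols = design_columns(lattice)
    params = np.array([beta_map.get(c, 0.0) for c in cols])
    return LogisticFit(
        columns=cols, params=params, se=np.ones(len(cols)),
        loglik=0.0, deviance=0.0, null_deviance=0.0, df_resid=1,
        n_obs=len(cols), n_iter=1, converged=True,
    )


class TestProbabilityMap:
    def test_zero_coefficients_give_half(self, small_dataset):
        fit = synthetic_fit(small_dataset.lattice, {})
        table = probability_map(
            fit, small_dataset.lattice, small_dataset.panel,
            small_dataset.covariates,
            {"weekday": "Sunday", "month": "June", "period": "night", "year": 2014},
        )
        assert np.allclose(table["probability"], 0.5)
        assert table["top_k"].sum() == 5

    def test_known_beta_matches_hand_computation(self, small_dataset):
        lattice = small_dataset.lattice
        beta = default_true_beta(lattice)
        fit = synthetic_fit(lattice, beta)
        scenario = {"weekday": "Friday", "month": "June", "period": "night", "year": 2014}
        table = probability_map(
            fit, lattice, small_dataset.panel, small_dataset.covariates, scenario
        ).set_index("unit_id")

        df = small_dataset.panel.copy()
        dates = pd.to_datetime(df["date"])
        mask = (
            (dates.dt.year == 2014)
            & (dates.dt.weekday == WEEKDAY_LEVELS.index("Friday"))
            & (dates.dt.month == MONTH_LEVELS.index("June") + 1)
            & (df["period"] == "night")
            & (df["date_index"] > 14)
        )
        d_star = df.loc[mask, "date_index"].max()
        rows = df[mask & (df.date_index == d_star)].set_index("unit_id")
        cov = small_dataset.covariates
        cov14 = cov[cov.year == 2014].set_index("unit_id")
        for u in lattice.unit_ids:
            eta = beta["intercept"]
            eta += beta["weekday[Friday]"]
            # June is the reference month; no month term
            eta += beta["period[night]"]
            for lagcol in LAG_COLUMNS:
                eta += beta[lagcol] * rows.loc[u, lagcol]
            eta += beta.get(f"district[{lattice.district_of[u]}]", 0.0)
            c = cov14.loc[u]
            eta += beta["log_inhab"] * math.log(c["inhab"])
            for term in (
                "inhab14", "inhab1529", "inhab65", "mphouse", "barrest", "svi",
                "mainroad", "buildage", "educuse", "greenuse", "botellon",
            ):
                eta += beta[term] * c[term]
            assert table.loc[u, "probability"] == pytest.approx(expit(eta), abs=1e-12)

    def test_negative_level_lowers_probability_with_fixed_lags(self, small_dataset):
        # with an all-zero call history the lag inputs are fixed at zero, so
        # switching Sunday (reference) to Monday (negative coefficient) must
        # lower every unit's probability
        from noiselag import add_lags, aggregate_counts, neighbor_orders

        lattice = small_dataset.lattice
        empty = aggregate_counts(
            small_dataset.sim.events.iloc[:0], lattice,
            small_dataset.config.start_date, small_dataset.config.n_days,
        )
        panel = add_lags(empty, neighbor_orders(lattice))
        beta = default_true_beta(lattice)
        fit = synthetic_fit(lattice, beta)
        base = {"weekday": "Sunday", "month": "June", "period": "night", "year": 2014}
        low = dict(base, weekday="Monday")
        p_base = probability_map(fit, lattice, panel, small_dataset.covariates, base)
        p_low = probability_map(fit, lattice, panel, small_dataset.covariates, low)
        assert (p_low["probability"].to_numpy() < p_base["probability"].to_numpy()).all()

    def test_unknown_scenario_level_rejected(self, small_dataset):
        fit = synthetic_fit(small_dataset.lattice, {})
        with pytest.raises(ValueError, match="month"):
            probability_map(
                fit, small_dataset.lattice, small_dataset.panel,
                small_dataset.covariates,
                {"weekday": "Sunday", "month": "Smarch", "period": "night", "year": 2014},
            )

    def test_ranks_are_a_permutation(self, small_dataset):
        fit = synthetic_fit(small_dataset.lattice, default_true_beta(small_dataset.lattice))
        table = probability_map(
            fit, small_dataset.lattice, small_dataset.panel, small_dataset.covariates,
            {"weekday": "Saturday", "month": "July", "period": "day", "year": 2014},
            k=3,
        )
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))
        assert set(table.loc[table["top_k"], "rank"]) == {1, 2, 3}


class TestCovariateCorrelation:
    def test_matches_pearson_oracle(self, small_lattice):
        from scipy import stats

        cov = generate_covariates(small_lattice, [2014], seed=4)
        result = covariate_correlation(cov, alpha=0.05)
        for a in ("inhab", "svi", "barrest"):
            for b in ("mphouse", "greenuse"):
                r, p = stats.pearsonr(cov[a], cov[b])
                assert result.r.loc[a, b] == pytest.approx(r, abs=1e-10)
                assert result.p.loc[a, b] == pytest.approx(p, abs=1e-10)
                if p >= 0.05:
                    assert np.isnan(result.masked.loc[a, b])
                else:
                    assert result.masked.loc[a, b] == pytest.approx(r, abs=1e-10)

    def test_perfect_linear_pair_shown(self, small_lattice):
        cov = generate_covariates(small_lattice, [2014], seed=4).copy()
        cov["mainroad"] = 2.0 * cov["barrest"]
        result = covariate_correlation(cov)
        assert result.masked.loc["barrest", "mainroad"] == pytest.approx(1.0)

    def test_diagonal_is_one(self, small_lattice):
        cov = generate_covariates(small_lattice, [2014], seed=4)
        result = covariate_correlation(cov)
        assert np.allclose(np.diag(result.masked.to_numpy()), 1.0)

    def test_constant_column_masked_with_warning(self, small_lattice):
        cov = generate_covariates(small_lattice, [2014], seed=4).copy()
        cov["botellon"] = 1
        with pytest.warns(UserWarning, match="botellon"):
            result = covariate_correlation(cov)
        assert result.masked["botellon"].isna().all()

    def test_too_few_rows_rejected(self, small_lattice):
        cov = generate_covariates(small_lattice, [2014], seed=4).iloc[:2]
        with pytest.raises(ValueError, match="3 rows"):
            covariate_correlation(cov)
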