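import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import locpattern as lp
from locpattern.inference import (
    build_design,
    chi_square_2x2,
    mixed_model,
    ols,
    pearson,
    power_simulation,
    stepwise_aic,
)
from locpattern.synthetic_data import simulate_regression_cohort


class TestOls:
    def test_noiseless_linear_fit_is_exact(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=40)})
        df["y"] = 2.0 + 3.0 * df["x"]
        res = ols(df, "y", ["x"])
        assert res.model_stats["adjusted_r2"] == pytest.approx(1.0)
        est = res.terms.set_index("term")["estimate"]
        assert est["Intercept"] == pytest.approx(2.0)
        assert est["x"] == pytest.approx(3.0)

    def test_null_coefficients_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=10_000),
                           "y": rng.normal(size=10_000)})
        res = ols(df, "y", ["x"])
        row = res.terms.set_index("term").loc["x"]
        assert abs(row["estimate"]) < 3 * row["se"]

    def test_onset_group_coded_early_reference(self):
        df = pd.DataFrame(
            {"onset_group": ["early"] * 5 + ["late"] * 5,
             "y": [10.0] * 5 + [4.0] * 5}
        )
        res = ols(df, "y", ["onset_group"])
        est = res.terms.set_index("term")["estimate"]
        assert est["Intercept"] == pytest.approx(10.0)   # early mean
        assert est["onset_group"] == pytest.approx(-6.0)  # late minus early

    def test_rank_deficiency_names_columns(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5]})
        df["b"] = 2 * df["a"]
        df["y"] = df["a"] + 1
        with pytest.raises(ValueError, match="collinear"):
            ols(df, "y", ["a", "b"])

    def test_f_df_pair(self):
        long, fac = simulate_regression_cohort(48, rng=3)
        summary = long.groupby("subject", as_index=False)["log_rms"].mean()
        df = summary.merge(fac, on="subject")
        res = ols(df, "log_rms", ["onset_group", "testing_age"])
        assert res.model_stats["f_df"] == (2, 45)


class TestMixedModel:
    def test_noiseless_exact_recovery(self):
        coeffs = {"intercept": 3.0, "od_effect": -0.4,
                  "sta_effect": 4e-5, "interaction": 3e-5}
        long, _ = simulate_regression_cohort(12, coeffs, 0.0, 0.0, rng=0)
        # add microscopic jitter: a literally zero-residual mixed fit is
        # degenerate, the coefficients must still match to ~1e-6
        rng = np.random.default_rng(1)
        long["log_rms"] += 1e-8 * rng.normal(size=len(long))
        res = mixed_model(long)
        est = res.terms.set_index("term")["estimate"]
        assert est["Intercept"] == pytest.approx(3.0, abs=1e-6)
        assert est["od"] == pytest.approx(-0.4, abs=1e-6)
        assert est["sta"] == pytest.approx(4e-5, abs=1e-9)
        assert est["od:sta"] == pytest.approx(3e-5, abs=1e-9)

    def test_matches_pooled_ols_when_no_grouping_structure(self):
        # no between-subject variance: fixed effects must agree with OLS on
        # the pooled long table to high precision
        long, _ = simulate_regression_cohort(
            24, sigma_between=0.0, sigma_within=0.3, rng=5)
        mm = mixed_model(long).terms.set_index("term")["estimate"]
        ls = ols(long, "log_rms", ["od", "sta", "od:sta"]).terms.set_index(
            "term")["estimate"]
        assert np.allclose(mm.to_numpy(), ls.to_numpy(), atol=5e-3)

    def test_zero_between_variance_boundary_warns(self):
        long, _ = simulate_regression_cohort(
            24, sigma_between=0.0, sigma_within=0.3, rng=6)
        with pytest.warns(UserWarning, match="boundary"):
            res = mixed_model(long)
        assert res.model_stats["random_intercept_variance"] == 0.0

    def test_satterthwaite_df_split(self):
        """Between-subject effects get df near the subject count; the
        within-subject slope terms get df near the residual count (the
        balanced-design arithmetic is n_obs - n_subjects)."""
        long, _ = simulate_regression_cohort(48, rng=7)
        res = mixed_model(long)
        df = res.terms.set_index("term")["df"]
        assert 30 < df["Intercept"] < 70
        assert 30 < df["od"] < 70
        assert 800 < df["sta"] <= 864
        assert 800 < df["od:sta"] <= 864

    def test_agrees_with_lmer_satterthwaite(self, tmp_path):
        """Independent oracle: lme4 + lmerTest reproduce the coefficients,
        SEs and Satterthwaite dfs of the same REML fit."""
        long, _ = simulate_regression_cohort(16, rng=11)
        res = mixed_model(long)
        csv = tmp_path / "long.csv"
        long.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            m <- lmer(log_rms ~ od*sta + (1|subject), data=d, REML=TRUE)
            co <- summary(m)$coefficients
            write.csv(co, "{tmp_path}/coef.csv")
        """)
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "coef.csv", index_col=0)
        mine = res.terms.set_index("term")
        for ours, theirs in [("Intercept", "(Intercept)"), ("od", "od"),
                             ("sta", "sta"), ("od:sta", "od:sta")]:
            assert mine.loc[ours, "estimate"] == pytest.approx(
                ref.loc[theirs, "Estimate"], rel=1e-4)
            assert mine.loc[ours, "se"] == pytest.approx(
                ref.loc[theirs, "Std. Error"], rel=1e-3)
            assert mine.loc[ours, "df"] == pytest.approx(
                ref.loc[theirs, "df"], rel=0.02)


class TestStepwise:
    def test_noise_predictor_eliminated(self):
        """A strong predictor always survives backward elimination; a
        pure-noise predictor is dropped at the AIC-characteristic rate
        P(chi2_1 < 2) ~ 0.843 (asserted within 3 binomial SEs)."""
        rng = np.random.default_rng(12)
        keep_strong, drop_noise = 0, 0
        n_sim = 100
        for _ in range(n_sim):
            df = pd.DataFrame({"x": rng.normal(size=500),
                               "junk": rng.normal(size=500)})
            df["y"] = 1.0 + 0.5 * df["x"] + rng.normal(size=500)
            res, trace = stepwise_aic(df, "y", ["x", "junk"])
            terms = set(res.terms["term"])
            keep_strong += "x" in terms
            drop_noise += "junk" not in terms
        assert keep_strong / n_sim >= 0.99
        assert 0.73 <= drop_noise / n_sim <= 0.95

    def test_all_noise_returns_intercept_only(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"a": rng.normal(size=300),
                           "y": rng.normal(size=300)})
        res, trace = stepwise_aic(df, "y", ["a"])
        assert list(res.terms["term"]) == ["Intercept"]
        assert trace["dropped"].iloc[-1] == "a"

    def test_collinearity_screen_blocks_pair(self):
        df = pd.DataFrame({"testing_age": [1.0], "acoustic_exposure": [1.0],
                           "y": [1.0]})
        with pytest.raises(ValueError, match="collinear"):
            stepwise_aic(df, "y", ["testing_age", "acoustic_exposure"],
                         screened_pairs=[("testing_age", "acoustic_exposure")])

    def test_interaction_removed_before_main_effect(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({"a": rng.normal(size=400),
                           "b": rng.normal(size=400)})
        df["y"] = 2 * df["a"] + rng.normal(size=400)  # no b, no interaction
        res, trace = stepwise_aic(df, "y", ["a", "b", "a:b"])
        dropped = list(trace["dropped"])[1:]
        if "b" in dropped and "a:b" in dropped:
            assert dropped.index("a:b") < dropped.index("b")
        assert "a" in set(res.terms["term"])

    def test_od_dropped_when_truly_null(self):
        """With the onset-group effect set to zero the mixed-family stepwise
        selection drops OD (and the interaction) in the majority of runs."""
        coeffs = {"intercept": 3.3, "od_effect": 0.0,
                  "sta_effect": 3.6e-5, "interaction": 0.0}
        rng = np.random.default_rng(15)
        drops = 0
        n_sim = 3
        for _ in range(n_sim):
            long, _ = simulate_regression_cohort(
                200, coeffs, rng=np.random.default_rng(rng.integers(2**63)))
            res, _ = stepwise_aic(long, "log_rms", ["od", "sta", "od:sta"],
                                  family="mixed")
            drops += "od" not in set(res.terms["term"])
        assert drops >= 2


class TestChiSquare:
    def test_published_sd_margin_statistic(self):
        t = chi_square_2x2([[12, 20], [1, 15]])
        assert t.statistic == pytest.approx(5.275, abs=5e-4)
        assert t.df == 1 and t.p < 0.05

    def test_published_mean_margin_statistic(self):
        t = chi_square_2x2([[12, 4], [18, 14]])
        assert t.statistic == pytest.approx(1.600, abs=5e-4)
        assert t.p == pytest.approx(0.206, abs=1e-3)

    def test_equal_proportions_statistic_zero(self):
        assert chi_square_2x2([[5, 5], [5, 5]]).statistic == 0.0

    def test_row_and_column_swap_invariance(self):
        base = chi_square_2x2([[12, 20], [1, 15]]).statistic
        assert chi_square_2x2([[1, 15], [12, 20]]).statistic == pytest.approx(base)
        assert chi_square_2x2([[20, 12], [15, 1]]).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 5], [0, 7]])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[1.5, 2], [3, 4]])


class TestPowerSimulation:
    def test_null_calibration(self):
        power, se = power_simulation(0.3, 100, 0.3, 100, rng=0)
        assert abs(power - 0.05) <= 3 * max(se, 0.003)

    def test_certain_difference_power_one(self):
        power, _ = power_simulation(0.0, 50, 1.0, 50, rng=1)
        assert power == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_effect_size(self):
        powers = [
            power_simulation(0.3, 60, p2, 60, n_sims=4000, rng=2)[0]
            for p2 in (0.3, 0.45, 0.6, 0.75, 0.9)
        ]
        assert all(b >= a - 0.03 for a, b in zip(powers, powers[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_simulation(1.2, 10, 0.5, 10)
        with pytest.raises(ValueError):
            power_simulation(0.5, 1, 0.5, 10)


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(3)
        res = pearson(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(res.r) < 0.03
        assert res.r2 == pytest.approx(res.r**2)

    def test_constant_series_missing(self):
        assert np.isnan(pearson([1, 1, 1, 1], [1, 2, 3, 4]).r)


def test_design_interaction_column():
    df = pd.DataFrame({"onset_group": ["early", "late"], "sta": [100.0, 200.0]})
    X = build_design(df, ["onset_group", "sta", "onset_group:sta"])
    assert list(X["onset_group:sta"]) == [0.0, 200.0]
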