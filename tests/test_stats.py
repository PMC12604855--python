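import numpy as np
import pandas as pd
import pytest

import phenolag as pl
from phenolag.stats import compact_letters, summaries_to_frame, variable_influence


def two_group_frame(mean_a=2.0, mean_b=7.0, n=30, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mean in (("a_level", mean_a), ("b_level", mean_b)):
        for i in range(n):
            rows.append(
                {
                    "n_o": rng.normal(mean, sd),
                    "n_c": rng.normal(mean, sd),
                    "region": "boreal" if g == "a_level" else "temperate",
                    "location": f"loc{i % 10}",
                    "species": f"sp{i % 15}",
                    "event": "leafing",
                }
            )
    return pd.DataFrame(rows)


class TestSummarizeGroups:
    def make_table(self):
        return pd.DataFrame(
            {
                "event": ["leafing"] * 4,
                "region": ["boreal", "boreal", "temperate", "temperate"],
                "o_ci": [120, 130, 100, 110],
                "t_b": [10.0, np.nan, 12.0, 14.0],
                "altitude_m": [1000.0, 1200.0, 300.0, 500.0],
                "latitude": [45.0, 47.0, 41.0, 43.0],
                "mat_c": [2.0, 3.0, 9.0, 11.0],
                "f_c": [60.0, 70.0, 90.0, 100.0],
                "s_w": [1.2, 1.4, 1.3, 1.3],
                "n_c": [2.0, 3.0, 1.0, 2.0],
            }
        )

    def test_level_means_and_sizes(self):
        out = pl.summarize_groups(self.make_table(), "region", event="leafing")
        by_level = {s.level: s for s in out}
        assert by_level["boreal"].means["forcing_change_dd"] == pytest.approx(65.0)
        assert by_level["temperate"].means["budburst_temperature_c"] == pytest.approx(13.0)
        assert sum(s.sample_size for s in out) == 4

    def test_undefined_budburst_temperature_excluded_from_its_mean_only(self):
        out = pl.summarize_groups(self.make_table(), "region")
        boreal = next(s for s in out if s.level == "boreal")
        assert boreal.means["budburst_temperature_c"] == pytest.approx(10.0)
        assert boreal.sample_size == 2

    def test_single_level_equals_overall_mean(self):
        df = self.make_table().assign(region="boreal")
        (only,) = pl.summarize_groups(df, "region")
        assert only.means["spring_phenology_julian"] == pytest.approx(115.0)

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="grouping factor"):
            pl.summarize_groups(self.make_table(), "species")

    def test_display_frame_rounds_to_one_decimal(self):
        out = summaries_to_frame(pl.summarize_groups(self.make_table(), "region"))
        assert out.loc[out["level"] == "boreal", "spring_phenology_julian"].iloc[0] == 125.0
        assert out["sample_size"].sum() == 4


class TestGroupContrast:
    def test_balanced_ols_fallback_lsmeans_equal_arithmetic_means(self):
        # single record per location forces the fixed-effects fallback path
        df = two_group_frame(sd=0.5, seed=1)
        df["location"] = [f"L{i}" for i in range(len(df))]
        df["species"] = df["location"]
        model = pl.GroupContrastModel(response="n_o", factor="region").fit(df)
        assert not model.used_mixed_
        arithmetic = df.groupby("region")["n_o"].mean()
        for _, row in model.lsmeans_.iterrows():
            assert row["estimate"] == pytest.approx(arithmetic[row["level"]])

    def test_recovers_injected_group_difference_within_two_se(self):
        df = two_group_frame(mean_a=0.0, mean_b=5.0, n=50, sd=2.0, seed=2)
        model = pl.GroupContrastModel(response="n_o", factor="region").fit(df)
        (pair,) = model.pairwise_.to_dict("records")
        assert abs(abs(pair["difference"]) - 5.0) <= 2 * pair["se"]
        assert set(model.letters_.values()) == {"a", "b"}

    def test_identical_groups_share_a_letter_at_the_null_rate(self):
        # type-I error of the letter display should sit near alpha
        hits = 0
        reps = 200
        for s in range(reps):
            df = two_group_frame(mean_a=3.0, mean_b=3.0, n=12, sd=1.0, seed=100 + s)
            df["location"] = [f"L{i}" for i in range(len(df))]
            df["species"] = df["location"]
            model = pl.GroupContrastModel(response="n_o", factor="region").fit(df)
            if len(set(model.letters_.values())) == 1:
                hits += 1
        rate = hits / reps
        se = np.sqrt(0.95 * 0.05 / reps)
        assert abs(rate - 0.95) <= 3 * se + 0.02

    def test_too_few_levels_rejected(self):
        df = two_group_frame().assign(region="boreal")
        with pytest.raises(ValueError, match="levels"):
            pl.GroupContrastModel(factor="region").fit(df)

    def test_report_carries_lsmeans_and_letters(self):
        rep = pl.fit_group_contrast(two_group_frame(seed=3), response="n_c", factor="region")
        assert rep.lsmeans is not None and len(rep.lsmeans) == 2
        assert set(rep.letters) == {"boreal", "temperate"}


class TestCompactLetters:
    def test_all_different_levels_get_distinct_letters(self):
        levels = ["x", "y", "z"]
        p = pd.DataFrame(np.zeros((3, 3)), index=levels, columns=levels)
        np.fill_diagonal(p.values, 1.0)
        letters = compact_letters(levels, p)
        assert len({letters[l] for l in levels}) == 3

    def test_chain_structure_shares_middle_letter(self):
        # x != z but y indistinguishable from both
        levels = ["x", "y", "z"]
        p = pd.DataFrame(1.0, index=levels, columns=levels)
        p.loc["x", "z"] = p.loc["z", "x"] = 0.001
        letters = compact_letters(levels, p)
        assert set(letters["x"]) & set(letters["y"])
        assert set(letters["y"]) & set(letters["z"])
        assert not set(letters["x"]) & set(letters["z"])


def synthetic_regression(seed, n=500):
    rng = np.random.default_rng(seed)
    noise_names = ["altitude_m", "latitude", "mat_c", "map_mm", "o_ci", "t_b", "s_w"]
    df = pd.DataFrame({c: rng.standard_normal(n) for c in noise_names})
    df["f_c"] = rng.normal(100, 40, n)
    df["n_c"] = rng.normal(2, 3, n)
    y = 2.0 + 0.07 * df["f_c"] - 0.95 * df["n_c"] + rng.normal(0, 0.5, n)
    return df, y, noise_names


class TestStepwiseAIC:
    def test_recovers_true_predictors(self):
        df, y, noise = synthetic_regression(seed=0)
        reg = pl.StepwiseAICRegressor().fit(df, y)
        assert {"f_c", "n_c"} <= set(reg.selected_features_)
        assert reg.coef_["f_c"] == pytest.approx(0.07, abs=0.01)
        assert reg.coef_["n_c"] == pytest.approx(-0.95, abs=0.01)
        assert reg.rsquared_ > 0.97

    def test_selection_invariant_to_candidate_order(self):
        df, y, _ = synthetic_regression(seed=1)
        a = pl.StepwiseAICRegressor(candidates=list(df.columns)).fit(df, y)
        b = pl.StepwiseAICRegressor(candidates=list(df.columns)[::-1]).fit(df, y)
        assert set(a.selected_features_) == set(b.selected_features_)

    def test_collinear_duplicate_keeps_exactly_one(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x1": rng.standard_normal(200)})
        df["x2"] = df["x1"]
        y = 3.0 * df["x1"] + rng.normal(0, 0.5, 200)
        reg = pl.StepwiseAICRegressor().fit(df, y)
        assert len(set(reg.selected_features_) & {"x1", "x2"}) == 1

    def test_null_data_rarely_keeps_many_terms(self):
        kept = []
        for s in range(30):
            rng = np.random.default_rng(500 + s)
            df = pd.DataFrame(rng.standard_normal((150, 5)), columns=list("abcde"))
            y = rng.standard_normal(150)
            reg = pl.StepwiseAICRegressor().fit(df, y)
            kept.append(len(reg.selected_features_))
        # AIC's known per-term false-inclusion rate is ~16%
        assert np.mean(kept) < 1.5

    def test_predict_matches_fitted_values(self):
        df, y, _ = synthetic_regression(seed=2, n=200)
        reg = pl.StepwiseAICRegressor().fit(df, y)
        resid = y.to_numpy() - reg.predict(df)
        assert np.std(resid) < 0.6

    def test_too_few_complete_cases_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((5, 8)))
        df.columns = [f"c{i}" for i in range(8)]
        with pytest.raises(ValueError, match="complete cases"):
            pl.StepwiseAICRegressor().fit(df, np.zeros(5))


class TestVariableInfluence:
    def test_single_term_model_takes_all_term_influence(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"x": rng.standard_normal(300)})
        y = 5.0 * df["x"] + rng.normal(0, 0.3, 300)
        reg = pl.StepwiseAICRegressor().fit(df, y)
        infl = variable_influence(reg)
        term_rows = infl.drop(index="Intercept")
        assert term_rows["influence_pct"].idxmax() == "x"
        assert infl["influence_pct"].sum() == pytest.approx(100.0, abs=0.2)

    def test_orthogonal_equal_contributors_split_evenly(self):
        rng = np.random.default_rng(13)
        n = 2000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        df = pd.DataFrame({"a": a - a.mean(), "b": b - b.mean()})
        y = df["a"] + df["b"] + rng.normal(0, 0.5, n)
        reg = pl.StepwiseAICRegressor().fit(df, y)
        infl = variable_influence(reg)
        assert infl.loc["a", "influence_pct"] == pytest.approx(
            infl.loc["b", "influence_pct"], abs=7.0
        )

    def test_dominant_term_has_strictly_largest_share(self):
        rng = np.random.default_rng(14)
        n = 500
        df = pd.DataFrame(
            {"big": rng.standard_normal(n), "small": rng.standard_normal(n)}
        )
        y = 5.0 * df["big"] + 0.3 * df["small"] + rng.normal(0, 1.0, n)
        reg = pl.StepwiseAICRegressor().fit(df, y)
        infl = variable_influence(reg).drop(index="Intercept")
        assert infl.loc["big", "influence_pct"] == infl["influence_pct"].max()
        assert (infl["delta_aic"] >= 0).all()

    def test_shares_nonnegative_and_sum_to_100(self):
        df, y, _ = synthetic_regression(seed=3)
        reg = pl.StepwiseAICRegressor().fit(df, y)
        infl = variable_influence(reg)
        assert (infl["influence_pct"] >= 0).all()
        assert infl["influence_pct"].sum() == pytest.approx(100.0, abs=0.2)

    def test_near_identity_coefficient_on_lag(self, study_partition):
        # regressing observed on forcing, rate and lag pins the lag near -1
        _, _, table = study_partition
        rep = pl.stepwise_aic(table[table["t_b_defined"]], response="n_o")
        assert "n_c" in rep.selected
        assert rep.params["n_c"] == pytest.approx(-1.0, abs=0.1)
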