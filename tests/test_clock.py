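"""Imputation, SMOGN, clock training, importance, phenotypic-age scoring."""

import numpy as np
import pandas as pd
import pytest

from waterflea.clock import (
    ClockConfig,
    GroupMeanImputer,
    PhenotypicClock,
    aging_rate_slope,
    impute,
    resample_smogn,
)


def _aging_cohort(n=500, seed=0, noise=0.4):
    """Feature table with age-monotone speed/size plus pure-noise columns."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(5, 80, n)
    X = pd.DataFrame({
        "speed": 5.0 - 0.05 * age + rng.normal(0, noise * 0.06, n),
        "size": 1.5 + 0.03 * age + rng.normal(0, noise * 0.04, n),
        "noise_a": rng.normal(size=n),
        "noise_b": rng.normal(size=n),
    })
    return X, age


class TestImpute:
    def test_group_mean_fills_missing(self):
        df = pd.DataFrame({"f": [2.0, 4.0, np.nan]})
        out = impute(df, ages=[10, 11, 12], bin_days=5.0)
        assert out["f"].iloc[2] == 3.0

    def test_no_missing_values_table_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        pd.testing.assert_frame_equal(impute(df, ages=rng.uniform(0, 50, 20)), df)

    def test_matches_brute_force_group_means(self, rng):
        n = 200
        ages = rng.uniform(0, 60, n)
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        mask = rng.random((n, 4)) < 0.2
        df = df.mask(mask)
        out = impute(df, ages, bin_days=10.0)
        bins = np.floor(ages / 10.0).astype(int)
        for col in df.columns:
            for i in np.where(df[col].isna())[0]:
                grp = df[col][bins == bins[i]]
                expected = grp.mean() if grp.notna().any() else df[col].mean()
                assert out[col].iloc[i] == pytest.approx(expected)

    def test_feature_missing_everywhere_rejected(self):
        df = pd.DataFrame({"f": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="missing everywhere"):
            impute(df, ages=[1, 2])

    def test_empty_group_falls_back_to_global_mean(self):
        imp = GroupMeanImputer(bin_days=5.0).fit(pd.DataFrame({"f": [1.0, 3.0]}), [1, 2])
        out = imp.transform(pd.DataFrame({"f": [np.nan]}), ages=[50.0])
        assert out["f"].iloc[0] == 2.0


class TestSmogn:
    def test_uniform_density_unchanged(self):
        y = np.linspace(0, 100, 120)
        X = pd.DataFrame({"a": 2 * y, "b": np.ones(120)})
        Xo, yo = resample_smogn(X, y, ClockConfig(seed=1))
        assert len(yo) == 120
        pd.testing.assert_frame_equal(Xo, X)

    def test_seeded_determinism(self, rng):
        y = np.concatenate([rng.uniform(0, 50, 200), rng.uniform(70, 80, 10)])
        X = pd.DataFrame({"a": y + rng.normal(0, 1, 210), "b": rng.normal(size=210)})
        X1, y1 = resample_smogn(X, y, ClockConfig(seed=5))
        X2, y2 = resample_smogn(X, y, ClockConfig(seed=5))
        pd.testing.assert_frame_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_rare_bin_topped_up_and_originals_kept(self, rng):
        y = np.concatenate([rng.uniform(0, 50, 300), rng.uniform(70, 80, 12)])
        X = pd.DataFrame({"a": 2 * y + rng.normal(0, 1, 312), "b": rng.normal(size=312)})
        Xo, yo = resample_smogn(X, y, ClockConfig(seed=3))
        assert len(yo) >= len(y)
        assert (yo > 65).sum() > (y > 65).sum()
        pd.testing.assert_frame_equal(Xo.iloc[: len(y)], X)
        np.testing.assert_array_equal(yo[: len(y)], y)

    def test_synthetic_rows_lie_on_segments_between_rare_rows(self, rng):
        y = np.concatenate([rng.uniform(0, 50, 300), rng.uniform(70, 80, 15)])
        X = pd.DataFrame({"a": 3 * y + rng.normal(0, 0.5, 315), "b": rng.normal(size=315)})
        cfg = ClockConfig(seed=7, noise_scale=1e-6)
        Xo, yo = resample_smogn(X, y, cfg)
        rare = X[y > 65].to_numpy()
        new = Xo.iloc[len(y):].to_numpy()
        for row in new:
            on_segment = False
            for i in range(len(rare)):
                for j in range(len(rare)):
                    if i == j:
                        continue
                    seg = rare[j] - rare[i]
                    denom = float(seg @ seg)
                    if denom == 0:
                        continue
                    u = float((row - rare[i]) @ seg) / denom
                    if -1e-6 <= u <= 1 + 1e-6 and np.linalg.norm(rare[i] + u * seg - row) < 1e-3:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_single_row_returned_with_warning(self):
        X = pd.DataFrame({"a": [1.0]})
        with pytest.warns(UserWarning):
            Xo, yo = resample_smogn(X, [5.0], ClockConfig())
        assert len(yo) == 1


class TestTraining:
    def test_perfect_feature_near_perfect_heldout(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(5, 80, 300)
        X = pd.DataFrame({"agecopy": age})
        res = PhenotypicClock(X, age, ClockConfig(model_family="lasso", seed=1)).fit()
        assert res.metrics["heldout_adj_r2"] >= 0.99
        assert res.metrics["heldout_rmse"] < 1.0

    def test_permuted_labels_no_skill(self):
        X, age = _aging_cohort(n=400, seed=2)
        rng = np.random.default_rng(3)
        res = PhenotypicClock(X, rng.permutation(age), ClockConfig(model_family="lasso", seed=2)).fit()
        assert abs(res.metrics["heldout_r2"]) < 0.1

    def test_heldout_rmse_near_noise_floor_oracle(self):
        """RMSE within 20% of an oracle fitted on a huge independent sample."""
        from sklearn.linear_model import LinearRegression

        X, age = _aging_cohort(n=800, seed=4, noise=1.0)
        res = PhenotypicClock(X, age, ClockConfig(model_family="elastic_net", seed=4)).fit()
        Xbig, agebig = _aging_cohort(n=40_000, seed=5, noise=1.0)
        oracle = LinearRegression().fit(Xbig[["speed", "size"]], agebig)
        Xtest, agetest = _aging_cohort(n=40_000, seed=6, noise=1.0)
        floor = np.sqrt(np.mean((oracle.predict(Xtest[["speed", "size"]]) - agetest) ** 2))
        assert res.metrics["heldout_rmse"] <= 1.2 * floor

    def test_no_leakage_fold_imputers_use_train_rows_only(self):
        X, age = _aging_cohort(n=300, seed=7)
        rng = np.random.default_rng(8)
        X = X.mask(rng.random(X.shape) < 0.15)
        cfg = ClockConfig(model_family="lasso", seed=7, age_bin_days=20.0)
        res = PhenotypicClock(X, age, cfg).fit()
        for imp, te in zip(res._fold_imputers, res._fold_tests):
            tr = np.setdiff1d(np.arange(len(age)), te)
            expected = GroupMeanImputer(cfg.age_bin_days).fit(X.iloc[tr], age[tr])
            pd.testing.assert_frame_equal(imp.group_means_, expected.group_means_)
            # means computed with test rows included must differ
            leaky = GroupMeanImputer(cfg.age_bin_days).fit(X, age)
            assert not imp.group_means_.equals(leaky.group_means_)

    def test_deterministic_metrics_under_fixed_seed(self):
        X, age = _aging_cohort(n=250, seed=9)
        m1 = PhenotypicClock(X, age, ClockConfig(model_family="random_forest", seed=5)).fit().metrics
        m2 = PhenotypicClock(X, age, ClockConfig(model_family="random_forest", seed=5)).fit().metrics
        assert m1 == m2

    @pytest.mark.parametrize("family", ["lasso", "elastic_net", "svm"])
    def test_all_linear_families_learn_aging_signal(self, family):
        X, age = _aging_cohort(n=400, seed=10)
        res = PhenotypicClock(X, age, ClockConfig(model_family=family, seed=10)).fit()
        assert res.metrics["heldout_r2"] > 0.8

    def test_smogn_training_runs_and_reports(self):
        rng = np.random.default_rng(11)
        n1, n2 = 300, 25  # old ages depleted, as in longitudinal cohorts
        age = np.concatenate([rng.uniform(5, 50, n1), rng.uniform(60, 80, n2)])
        X = pd.DataFrame({"speed": 5 - 0.05 * age + rng.normal(0, 0.1, n1 + n2),
                          "size": 1.5 + 0.03 * age + rng.normal(0, 0.05, n1 + n2)})
        cfg = ClockConfig(model_family="lasso", oversample="smogn", seed=11)
        res = PhenotypicClock(X, age, cfg).fit()
        assert res.metrics["heldout_r2"] > 0.8


class TestImportance:
    def _fitted(self):
        X, age = _aging_cohort(n=300, seed=20)
        X["constant"] = 1.0
        return PhenotypicClock(X, age, ClockConfig(model_family="random_forest", seed=20)).fit()

    def test_constant_feature_unimportant_both_dialects(self):
        res = self._fitted()
        for method in ("permutation", "refit"):
            imp = res.feature_importance(method, n_repeats=2)
            row = imp.set_index("feature").loc["constant", "importance"]
            assert abs(row) < 0.2

    def test_age_proxy_ranked_first(self):
        rng = np.random.default_rng(21)
        age = rng.uniform(5, 80, 300)
        X = pd.DataFrame({"agecopy": age, "n1": rng.normal(size=300), "n2": rng.normal(size=300)})
        res = PhenotypicClock(X, age, ClockConfig(model_family="random_forest", seed=21)).fit()
        imp = res.feature_importance("permutation", n_repeats=3)
        assert imp["feature"].iloc[0] == "agecopy"

    def test_ranking_stable_under_row_order(self):
        rng = np.random.default_rng(22)
        X, age = _aging_cohort(n=300, seed=22)
        perm = rng.permutation(len(age))
        r1 = PhenotypicClock(X, age, ClockConfig(model_family="lasso", seed=3)).fit()
        r2 = PhenotypicClock(X.iloc[perm].reset_index(drop=True), age[perm],
                             ClockConfig(model_family="lasso", seed=3)).fit()
        top1 = r1.feature_importance("permutation", n_repeats=3)["feature"].iloc[0]
        top2 = r2.feature_importance("permutation", n_repeats=3)["feature"].iloc[0]
        assert top1 == top2 == "speed" or top1 == top2 == "size"


class TestPhenotypicAge:
    def test_delta_definition(self):
        """predicted 30, chronological 20 -> delta = +10, exactly."""
        X, age = _aging_cohort(n=200, seed=30)
        res = PhenotypicClock(X, age, ClockConfig(model_family="lasso", seed=30)).fit()
        pa = res.phenotypic_age(X, age)
        np.testing.assert_allclose(pa.table["delta"], pa.table["predicted"] - pa.table["chronological"])
        assert set(pa.by_condition.columns) >= {"mean_delta", "sem_delta", "slope", "slope_se"}

    def test_training_rows_have_near_zero_delta_with_perfect_feature(self):
        rng = np.random.default_rng(31)
        age = rng.uniform(5, 80, 200)
        X = pd.DataFrame({"agecopy": age})
        res = PhenotypicClock(X, age, ClockConfig(model_family="lasso", seed=31)).fit()
        pa = res.phenotypic_age(X, age)
        assert abs(pa.by_condition["mean_delta"].iloc[0]) < 0.5

    def test_unknown_feature_column_rejected(self):
        X, age = _aging_cohort(n=150, seed=32)
        res = PhenotypicClock(X, age, ClockConfig(model_family="lasso", seed=32)).fit()
        bad = X.copy()
        bad["mystery"] = 1.0
        with pytest.raises(ValueError, match="unknown feature columns"):
            res.predict(bad)

    def test_rejuvenating_transform_lowers_predicted_age_monotonically(self):
        """Pushing features toward younger phenotypes (faster + smaller)
        lowers mean predicted age, monotonically in transform strength."""
        X, age = _aging_cohort(n=400, seed=33)
        res = PhenotypicClock(X, age, ClockConfig(model_family="gradient_boost", seed=33)).fit()
        means = []
        for s in (0.0, 5.0, 10.0):
            Xs = X.copy()
            Xs["speed"] = Xs["speed"] + 0.05 * s   # as if s days younger
            Xs["size"] = Xs["size"] - 0.03 * s
            means.append(res.predict(Xs, ages=age).mean())
        assert means[0] > means[1] > means[2]


class TestAgingRateSlope:
    def test_identity_and_double(self):
        x = np.array([10.0, 20.0, 30.0])
        assert aging_rate_slope(x, x)[0] == pytest.approx(1.0)
        assert aging_rate_slope(2 * x, x)[0] == pytest.approx(2.0)

    def test_hand_computed_example(self):
        slope, se = aging_rate_slope([12.0, 19.0, 33.0], [10.0, 20.0, 30.0])
        assert slope == pytest.approx(1490.0 / 1400.0)
        assert se > 0

    def test_all_zero_ages_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            aging_rate_slope([1.0, 2.0], [0.0, 0.0])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        from waterflea.io import load_clock, save_clock

        X, age = _aging_cohort(n=200, seed=40)
        res = PhenotypicClock(X, age, ClockConfig(model_family="lasso", seed=40)).fit()
        path = tmp_path / "clock.zip"
        save_clock(res, path)
        back = load_clock(path)
        np.testing.assert_allclose(back.predict(X, ages=age), res.predict(X, ages=age))
        assert back.metrics == res.metrics
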