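"""Lodging scores, leaf-type threshold classifier, and linear AGBM models."""

import numpy as np
import pandas as pd
import pytest

from peafield.trait_models import (PRESETS, SPRING_1231, WINTER_1268,
                                   LinearAGBMModel, TraitModelError,
                                   apply_agbm_model, classify_leaf_type,
                                   fit_lasso_agbm, fit_leaf_type, lodging_score,
                                   lodging_scores, predict_entries,
                                   standardize_features)


def row(pid, add, ch, cc):
    return {"plot_id": pid, "ADD": add, "CH_uas": ch, "CC": cc}


class TestLodgingScore:
    def test_unchanged_canopy_scores_zero(self):
        s = lodging_score(row("P", 1231, 0.5, 0.4), row("P", 1648, 0.5, 0.4))
        assert s.score == 0.0

    def test_direct_arithmetic(self):
        s = lodging_score(row("P", 1231, 0.5, 0.4), row("P", 1648, 0.3, 0.6))
        assert s.score == pytest.approx(-0.04)

    def test_height_only_form(self):
        s = lodging_score(row("P", 1231, 0.5, 0.4), row("P", 1648, 0.3, 0.6),
                          include_cc=False)
        assert s.score == pytest.approx(0.2)

    def test_mismatched_plots_rejected(self):
        with pytest.raises(TraitModelError, match="mismatched"):
            lodging_score(row("A", 1231, 0.5, 0.4), row("B", 1648, 0.3, 0.6))

    def test_timepoint_order_enforced(self):
        with pytest.raises(TraitModelError, match="ADD1 < ADDk"):
            lodging_score(row("P", 1648, 0.5, 0.4), row("P", 1231, 0.3, 0.6))

    def test_lodged_plots_score_opposite_sign_to_erect(self, spring_cfg,
                                                       spring_sim, spring_features):
        layout, truth, spec, scenes = spring_sim
        scores = lodging_scores(spring_features, 1231.0, 1648.0, include_cc=True)
        merged = scores.merge(truth.ground_truth_table(), on="plot_id")
        lodged = merged[merged["lodged"].astype(str) == "True"]
        erect = merged[merged["lodged"].astype(str) == "False"]
        assert lodged["lodging_score"].mean() < 0 < erect["lodging_score"].mean()


class TestLeafType:
    def test_perfectly_separated_classes(self):
        model = fit_leaf_type([0.10, 0.11, 0.12, 0.16, 0.17, 0.18],
                              ["af", "af", "af", "Af", "Af", "Af"])
        assert model.training_accuracy == 1.0
        assert model.class_means["af"] < model.decision_threshold < model.class_means["Af"]

    def test_three_sd_separation_reaches_ninety_percent(self, rng):
        af = rng.normal(0.12, 0.01, 100)
        af_norm = rng.normal(0.15, 0.01, 100)  # 3 SD apart
        x = np.concatenate([af, af_norm])
        y = ["af"] * 100 + ["Af"] * 100
        model = fit_leaf_type(x, y)
        assert model.training_accuracy >= 0.90

    def test_degenerate_equal_means_fall_back_to_majority(self):
        model = fit_leaf_type([0.1] * 5, ["af", "af", "af", "Af", "Af"])
        assert model.training_accuracy == pytest.approx(0.6)

    def test_single_class_rejected(self):
        with pytest.raises(TraitModelError, match="two leaf-type classes"):
            fit_leaf_type([0.1, 0.2], ["af", "af"])

    def test_accuracy_invariant_under_monotone_transform(self, rng):
        x = rng.normal(0.13, 0.02, 60)
        y = np.where(x > 0.13, "Af", "af")
        flips = rng.random(60) < 0.1
        y = np.where(flips, np.where(y == "af", "Af", "af"), y)
        base = fit_leaf_type(x, y).training_accuracy
        transformed = fit_leaf_type(np.exp(5 * x), y).training_accuracy
        assert transformed == pytest.approx(base)

    def test_classify_applies_frozen_threshold(self):
        model = fit_leaf_type([0.1, 0.1, 0.2, 0.2], ["af", "af", "Af", "Af"])
        pred, acc = classify_leaf_type(model, [0.09, 0.21], ["af", "Af"])
        assert list(pred) == ["af", "Af"]
        assert acc == 1.0

    def test_recovers_leaf_type_from_synthetic_green_reflectance(self, spring_sim):
        layout, truth, spec, scenes = spring_sim
        sub = truth.for_timepoint(1231.0)
        model = fit_leaf_type(sub["canopy_G"], sub["leaf_type"])
        assert model.training_accuracy >= 0.70


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 5, 50), "b": rng.uniform(0, 9, 50)})
        std, means, sds = standardize_features(df, ["a", "b"])
        for c in ("a", "b"):
            assert abs(std[c].mean()) < 1e-12
            assert std[c].std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(TraitModelError, match="'a'"):
            standardize_features(df, ["a"])

    def test_destandardization_roundtrip(self, rng):
        df = pd.DataFrame({"a": rng.normal(10, 2, 30)})
        std, means, sds = standardize_features(df, ["a"])
        back = std["a"] * sds["a"] + means["a"]
        np.testing.assert_allclose(back, df["a"], atol=1e-12)


class TestPresets:
    def test_winter_intercept_only(self):
        x = {f: 0.0 for f in WINTER_1268.feature_names}
        assert apply_agbm_model(WINTER_1268, x) == pytest.approx(8.85 / 1.5e4)

    def test_spring_intercept_only(self):
        x = {f: 0.0 for f in SPRING_1231.feature_names}
        assert apply_agbm_model(SPRING_1231, x) == pytest.approx(87.83 / 1.0e3)

    def test_single_term_evaluation(self):
        x = {f: 0.0 for f in WINTER_1268.feature_names}
        x["GRVI_sum"] = 1.0
        assert apply_agbm_model(WINTER_1268, x) == pytest.approx((1.56 + 8.85) / 1.5e4)

    def test_preset_matches_bruteforce_dot_product(self, rng):
        for preset in PRESETS.values():
            rows = pd.DataFrame(rng.normal(size=(10, len(preset.feature_names))),
                                columns=list(preset.feature_names))
            got = apply_agbm_model(preset, rows)
            for i in range(10):
                expected = (sum(c * rows.iloc[i][f] for c, f in
                                zip(preset.coefficients, preset.feature_names))
                            + preset.intercept) / preset.divisor
                assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_model_is_affine_in_features(self, rng):
        a = {f: float(v) for f, v in zip(WINTER_1268.feature_names, rng.normal(size=4))}
        b = {f: float(v) for f, v in zip(WINTER_1268.feature_names, rng.normal(size=4))}
        avg = {f: (a[f] + b[f]) / 2 for f in a}
        assert apply_agbm_model(WINTER_1268, avg) == pytest.approx(
            (apply_agbm_model(WINTER_1268, a) + apply_agbm_model(WINTER_1268, b)) / 2)

    def test_missing_feature_named(self):
        with pytest.raises(TraitModelError, match="CC"):
            apply_agbm_model(WINTER_1268, {"GRVI_sum": 1.0, "NDVI_sum": 0.0,
                                           "NDRE_sum": 0.0})

    def test_json_roundtrip(self, tmp_path):
        path = WINTER_1268.to_json(tmp_path / "model.json")
        back = LinearAGBMModel.from_json(path)
        assert back == WINTER_1268


def synth_regression(n=180, weights=(1.2, -0.6, 0.4, 0.1), noise_sd=0.0, seed=7):
    rng = np.random.default_rng(seed)
    names = ["GRVI_sum", "NDVI_sum", "NDRE_sum", "CC"]
    x = rng.normal(size=(n, 4))
    x = (x - x.mean(0)) / x.std(0)
    y = x @ np.asarray(weights) + 5.0 + rng.normal(0, noise_sd, n)
    feats = pd.DataFrame(x, columns=names)
    feats["plot_id"] = [f"P{i:03d}" for i in range(n)]
    truth = pd.DataFrame({"plot_id": feats["plot_id"], "AGBM": y})
    return feats, truth, names, np.asarray(weights)


class TestLassoFit:
    def test_noiseless_coefficient_recovery(self):
        feats, truth, names, w = synth_regression(noise_sd=0.0)
        model, val = fit_lasso_agbm(feats, truth, names, seed=3)
        np.testing.assert_allclose(model.coefficients, w, rtol=0.05)
        assert val["r"] > 0.999

    def test_null_response_shrinks_all_coefficients(self):
        rng = np.random.default_rng(11)
        feats, truth, names, _ = synth_regression(n=300, seed=11)
        truth["AGBM"] = rng.normal(size=300)
        model, val = fit_lasso_agbm(feats, truth, names, seed=11)
        assert np.all(np.abs(model.coefficients) < 0.05)

    def test_same_seed_gives_identical_model(self):
        feats, truth, names, _ = synth_regression(noise_sd=0.3)
        a, _ = fit_lasso_agbm(feats, truth, names, seed=5)
        b, _ = fit_lasso_agbm(feats, truth, names, seed=5)
        assert a == b

    def test_small_sample_rejected(self):
        feats, truth, names, _ = synth_regression(n=5)
        with pytest.raises(TraitModelError, match=">= 10"):
            fit_lasso_agbm(feats, truth, names)

    def test_weak_penalty_limit_approaches_ols(self):
        from sklearn.linear_model import LinearRegression, Lasso
        feats, truth, names, w = synth_regression(n=200, noise_sd=0.2, seed=2)
        x = feats[names].to_numpy()
        y = truth["AGBM"].to_numpy()
        ols = LinearRegression().fit(x, y)
        weak = Lasso(alpha=1e-8, max_iter=200000).fit(x, y)
        np.testing.assert_allclose(weak.coef_, ols.coef_, rtol=0.01)


class TestPredictEntries:
    def test_entry_count_and_groupby_oracle(self, rng):
        feats, truth, names, _ = synth_regression(n=60, noise_sd=0.1)
        feats["entry"] = [f"E{i % 20:02d}" for i in range(60)]
        model, _ = fit_lasso_agbm(feats, truth, names, seed=1)
        out = predict_entries(model, feats)
        assert len(out) == 20
        # brute-force per-entry mean of per-plot predictions
        std = feats.copy()
        for f in names:
            std[f] = (feats[f] - model.standardization_means[f]) \
                / model.standardization_sds[f]
        per_plot = apply_agbm_model(model, std)
        for entry, grp in feats.assign(est=per_plot).groupby("entry"):
            got = out.set_index("entry").loc[entry, "AGBM_est"]
            assert got == pytest.approx(grp["est"].mean(), abs=1e-12)
        assert out["above_mean"].any() and not out["above_mean"].all()

    def test_identical_features_give_equal_estimates(self):
        feats = pd.DataFrame({"plot_id": [f"P{i}" for i in range(6)],
                              "entry": ["A", "A", "B", "B", "C", "C"],
                              "GRVI_sum": 1.0, "NDVI_sum": 2.0,
                              "NDRE_sum": 3.0, "CC": 4.0})
        out = predict_entries(WINTER_1268, feats)
        assert out["AGBM_est"].nunique() == 1
        assert not out["above_mean"].any()

    def test_missing_feature_values_listed(self):
        feats = pd.DataFrame({"plot_id": ["P1", "P2", "P3"],
                              "entry": ["A", "B", "C"],
                              "GRVI_sum": [1.0, np.nan, 2.0], "NDVI_sum": 0.0,
                              "NDRE_sum": 0.0, "CC": 0.0})
        with pytest.raises(TraitModelError, match="P2"):
            predict_entries(WINTER_1268, feats)
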