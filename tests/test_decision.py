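"""Landing models, trial labeling, the decision GLM and matching."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from obstride import GeneratorConfig, fit_decision_glm, fit_landing_model, \
    forward_select, label_modification, match_trials, \
    predict_landing_distance, shuffled_baseline
from obstride.decision import (conditional_landing_heatmap,
                               fit_contact_model, impute_contact_frame,
                               impute_contact_position, _prepare_xy)
from obstride.errors import AnalysisError
from obstride.sim import generate_decision_cohort, generate_decision_trials
from obstride.decision import assemble_decision_dataset


class TestLandingModel:
    def test_colinear_steps_exact(self):
        v = np.linspace(0.3, 0.8, 20)
        steps = pd.DataFrame({"speed": v, "length": -3.7 + 107.0 * v})
        m = fit_landing_model(steps)
        assert m.intercept == pytest.approx(-3.7, abs=1e-8)
        assert m.slope == pytest.approx(107.0, abs=1e-8)
        assert m.mae == pytest.approx(0.0, abs=1e-8)

    def test_mae_converges_to_closed_form(self, rng):
        n = 60_000
        v = rng.normal(0.55, 0.1, n)
        eps = rng.normal(0, 6.9, n)
        steps = pd.DataFrame({"speed": v, "length": -3.7 + 107 * v + eps})
        m = fit_landing_model(steps)
        assert m.mae == pytest.approx(6.9 * np.sqrt(2 / np.pi), rel=0.02)

    def test_two_steps_interpolate(self):
        steps = pd.DataFrame({"speed": [0.4, 0.6], "length": [40.0, 60.0]})
        m = fit_landing_model(steps, min_steps=2)
        assert m.predict_length(0.5) == pytest.approx(50.0)
        assert m.mae == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_steps_named(self):
        steps = pd.DataFrame({"speed": [0.5], "length": [50.0]})
        with pytest.raises(AnalysisError, match="LF"):
            fit_landing_model(steps, session=3, paw="LF")

    def test_holdout_variant_larger_error(self, rng):
        v = rng.normal(0.55, 0.1, 40)
        steps = pd.DataFrame({"speed": v,
                              "length": -3.7 + 107 * v + rng.normal(0, 6.9, 40)})
        m_in = fit_landing_model(steps)
        m_out = fit_landing_model(steps, holdout=True)
        assert m_out.mae >= m_in.mae * 0.8  # held-out is not smaller in general


class TestPredictLanding:
    def test_lands_short(self):
        m = fit_landing_model(pd.DataFrame({"speed": [0.0, 1.0],
                                            "length": [0.0, 30.0]}),
                              min_steps=2)
        # lift-off 40 mm before obstacle, predicted length 30 mm
        assert predict_landing_distance(-40.0, 1.0, 0.0, m) == pytest.approx(-10.0)

    def test_exact_gap(self):
        m = fit_landing_model(pd.DataFrame({"speed": [0.0, 1.0],
                                            "length": [0.0, 30.0]}),
                              min_steps=2)
        assert predict_landing_distance(-30.0, 1.0, 0.0, m) == pytest.approx(0.0)

    def test_cohort_dpred_matches_planted(self):
        """Model-predicted landing distances recover the planted ones up to
        the landing-model fit error."""
        cfg = GeneratorConfig()
        trials, cs = generate_decision_cohort(cfg, 2, 1, 100, seed=5)
        ds = assemble_decision_dataset(trials, cs)
        err = ds["dpred"] - ds["true_dpred"]
        assert np.abs(err.mean()) < 1.0
        assert err.std() < 2.0


class TestLabelModification:
    def test_within_band_in_front_unmodified(self):
        assert label_modification(-20.0, -19.0) == "unmodified"

    def test_far_short_is_shortened(self):
        assert label_modification(-5.0, -15.0) == "shortened"

    def test_over_obstacle_never_unmodified(self):
        # lands 1 mm beyond the prediction but beyond the obstacle
        assert label_modification(4.0, 5.0) == "lengthened"

    def test_vector_input(self):
        labs = label_modification([-20.0, -5.0], [-19.0, -15.0])
        assert list(labs) == ["unmodified", "shortened"]


def _toy_dataset(n, rng, informative=True):
    X = rng.normal(0, 1, (n, 8))
    logit = 3.0 * X[:, 0] if informative else np.zeros(n)
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    cols = ["obstacle_x", "obstacle_z", "paw_x", "paw_z", "paw_vx",
            "paw_vz", "wheel_velocity", "body_angle"]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = np.where(y, "lengthened", "shortened")
    return df


class TestDecisionGLM:
    def test_separable_dataset_high_accuracy(self, rng):
        df = _toy_dataset(400, rng)
        df["label"] = np.where(df["obstacle_x"] > 0, "lengthened", "shortened")
        res = fit_decision_glm(df, seed=0)
        assert res.mean_accuracy >= 0.99
        assert len(res.fold_accuracies) == 15

    def test_single_class_rejected(self, rng):
        df = _toy_dataset(100, rng)
        df["label"] = "shortened"
        with pytest.raises(AnalysisError):
            fit_decision_glm(df)

    def test_class_weighting_equals_minority_duplication(self, rng):
        """Inverse-frequency weights reproduce the fit obtained by
        duplicating the minority class to parity and dropping the weights."""
        X = rng.normal(0, 1, (80, 4))
        y = (rng.random(80) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        while y.sum() not in range(15, 40):
            y = (rng.random(80) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        n, n1 = len(y), int(y.sum())
        # balance by duplicating the minority class to parity
        k = max(1, round((n - n1) / n1))
        reps = np.where(y == 1, k, 1)
        Xd, yd = np.repeat(X, reps, axis=0), np.repeat(y, reps)
        w = LogisticRegression(C=1e4, class_weight={0: 1.0, 1: float(k)},
                               max_iter=20000, tol=1e-12)
        w.fit(X, y)
        d = LogisticRegression(C=1e4, max_iter=20000, tol=1e-12)
        d.fit(Xd, yd)
        np.testing.assert_allclose(w.coef_, d.coef_, atol=1e-4)
        # sklearn's "balanced" mode is the same weighting up to a common
        # scale factor, so the fitted direction matches it too
        b = LogisticRegression(C=1e4, class_weight="balanced",
                               max_iter=20000, tol=1e-12)
        b.fit(X, y)
        if abs(n / (2 * n1) - k * n / (2 * (n - n1))) < 1e-9:
            np.testing.assert_allclose(b.coef_, d.coef_, atol=1e-3)

    def test_planted_threshold_recovered_in_dpred_space(self):
        """With a nearly deterministic planted rule, the fitted boundary in
        (dpred, height) space recovers theta within 1 mm."""
        cfg = GeneratorConfig(decision_temperature=0.05)
        trials = generate_decision_trials(cfg, 4000,
                                          np.random.default_rng(2), tau=0.05)
        keep = trials["exclusion"] == ""
        keep &= trials["true_label"].isin(["shortened", "lengthened"])
        df = trials[keep].copy()
        df["label"] = df["true_label"]
        df["dpred"] = df["true_dpred"]
        X = df[["dpred", "obstacle_z"]].to_numpy()
        y = (df["label"] == "lengthened").to_numpy(int)
        clf = LogisticRegression(C=1e6, max_iter=5000)
        clf.fit(X, y)
        w0, (w1, w2) = clf.intercept_[0], clf.coef_[0]
        h_bar = 7.0
        boundary = -(w0 + w2 * h_bar) / w1
        planted = cfg.decision_threshold + cfg.decision_height_coefficient * h_bar
        assert boundary == pytest.approx(planted, abs=1.0)

    def test_weight_signs_match_planted_rule(self, default_tau):
        """Fitted weights point the way the planted rule does: lengthening is
        favoured by a closer obstacle, lower obstacle, more anterior paw,
        lower horizontal paw velocity, faster running."""
        cfg = GeneratorConfig()
        trials = generate_decision_trials(cfg, 20_000,
                                          np.random.default_rng(3),
                                          tau=default_tau)
        keep = (trials["exclusion"] == "") & \
            trials["true_label"].isin(["shortened", "lengthened"])
        df = trials[keep].copy()
        df["label"] = df["true_label"]
        res = fit_decision_glm(df, seed=0, folds=15)
        w = dict(zip(res.features, res.weights))
        assert w["obstacle_x"] < 0
        assert w["obstacle_z"] < 0
        assert w["paw_x"] > 0
        assert w["paw_vx"] < 0
        assert w["wheel_velocity"] > 0


class TestForwardSelection:
    def test_informative_feature_first(self, rng):
        datasets = [_toy_dataset(200, rng) for _ in range(3)]
        path = forward_select(datasets, seed=0, folds=5)
        assert path.features[0] == "obstacle_x"
        assert len(path.features) == 8
        assert sorted(path.features) == sorted(set(path.features))

    def test_all_noise_flat_path(self, rng):
        datasets = [_toy_dataset(150, rng, informative=False)
                    for _ in range(3)]
        path = forward_select(datasets, seed=0, folds=5)
        assert all(abs(a - 0.5) < 0.12 for a in path.accuracies)

    def test_default_cohort_top_two(self, default_tau):
        """On the default synthetic cohort the first two selected features
        are the obstacle and paw horizontal positions (either order)."""
        cfg = GeneratorConfig()
        datasets = []
        for m in range(16):
            t = generate_decision_trials(cfg, 216,
                                         np.random.default_rng(600 + m),
                                         tau=default_tau)
            keep = (t["exclusion"] == "") & \
                t["true_label"].isin(["shortened", "lengthened"])
            d = t[keep].copy()
            d["label"] = d["true_label"]
            datasets.append(d)
        path = forward_select(datasets, seed=0, folds=15, max_features=2)
        assert set(path.features[:2]) == {"obstacle_x", "paw_x"}


class TestShuffledBaseline:
    def test_mean_near_half(self, rng):
        df = _toy_dataset(400, rng)
        accs = shuffled_baseline(df, 10, seed=4)
        assert abs(accs.mean() - 0.5) < 0.05

    def test_zero_shuffles_rejected(self, rng):
        with pytest.raises(AnalysisError):
            shuffled_baseline(_toy_dataset(100, rng), 0)

    def test_seed_reproducible(self, rng):
        df = _toy_dataset(200, rng)
        a = shuffled_baseline(df, 5, seed=9)
        b = shuffled_baseline(df, 5, seed=9)
        np.testing.assert_array_equal(a, b)


class TestHeatmap:
    def test_diagonal_when_unmodified(self):
        vals = np.linspace(-30, 20, 200)
        edges = np.arange(-30, 21, 5.0)
        H = conditional_landing_heatmap(vals, vals, edges)
        np.testing.assert_allclose(H.to_numpy().sum(axis=0), 1.0)
        assert np.trace(H.to_numpy()) == pytest.approx(len(edges) - 1)

    def test_empty_columns_stay_zero(self):
        H = conditional_landing_heatmap([5.0], [5.0], [0, 2, 4, 6])
        sums = H.to_numpy().sum(axis=0)
        np.testing.assert_allclose(sums, [0.0, 0.0, 1.0])

    def test_single_trial(self):
        H = conditional_landing_heatmap([-10.0], [-12.0], [-20, -10, 0])
        assert H.to_numpy().sum() == 1.0

    def test_bimodal_columns_near_threshold(self, default_tau):
        """With low decision noise, landing distributions conditioned on the
        predicted landing are bimodal around theta: mass in front and beyond
        the obstacle, none at it."""
        cfg = GeneratorConfig(decision_temperature=1.0)
        t = generate_decision_trials(cfg, 20_000, np.random.default_rng(8),
                                     tau=1.0)
        t = t[(t["exclusion"] == "")
              & t["true_label"].isin(["shortened", "lengthened"])]
        near = t[np.abs(t["true_dpred"] - cfg.decision_threshold) < 2.0]
        frac_at_obstacle = np.mean(np.abs(near["actual_landing"]) < 2.0)
        assert frac_at_obstacle < 0.05
        assert (near["actual_landing"] < -2).any()
        assert (near["actual_landing"] > 2).any()

    def test_bad_edges(self):
        with pytest.raises(AnalysisError):
            conditional_landing_heatmap([0.0], [0.0], [0, -1, 2])


class TestMatchTrials:
    @staticmethod
    def _frames(rng, n_c=60, n_m=40):
        cols = ["wheel_velocity", "body_angle", "tail_height"]
        c = pd.DataFrame(rng.normal(0, 1, (n_c, 3)), columns=cols)
        m = pd.DataFrame(rng.normal(0, 1, (n_m, 3)), columns=cols)
        return c, m

    def test_exact_duplicate_matched_first(self, rng):
        c, m = self._frames(rng)
        m.iloc[7] = c.iloc[3]
        res = match_trials(c, m, fraction=0.05)
        assert res.pairs[0] == (3, 7)
        assert res.distances[0] == pytest.approx(0.0, abs=1e-12)

    def test_retained_count(self, rng):
        c, m = self._frames(rng, 100, 70)
        res = match_trials(c, m, fraction=0.2)
        assert abs(len(res.pairs) - int(0.2 * 70)) <= 1

    def test_each_trial_used_once(self, rng):
        c, m = self._frames(rng, 50, 50)
        res = match_trials(c, m, fraction=0.5)
        ci = [p[0] for p in res.pairs]
        mi = [p[1] for p in res.pairs]
        assert len(set(ci)) == len(ci) and len(set(mi)) == len(mi)

    def test_order_invariance(self, rng):
        c, m = self._frames(rng, 40, 40)
        res1 = match_trials(c, m, fraction=0.3)
        perm = rng.permutation(len(c))
        res2 = match_trials(c.iloc[perm], m, fraction=0.3)
        assert sorted(res1.pairs) == sorted(res2.pairs)

    def test_matched_means_indistinguishable(self, rng):
        """With identical generating distributions, retained pairs have
        closely matched feature means across conditions."""
        c, m = self._frames(rng, 200, 200)
        res = match_trials(c, m, fraction=0.2)
        ci = [p[0] for p in res.pairs]
        mi = [p[1] for p in res.pairs]
        diff = c.loc[ci].mean() - m.loc[mi].mean()
        assert np.all(np.abs(diff.to_numpy()) < 0.15)

    def test_empty_condition_rejected(self, rng):
        c, m = self._frames(rng)
        with pytest.raises(AnalysisError):
            match_trials(c.iloc[:0], m)

    def test_optimal_variant_no_worse_at_full_matching(self, rng):
        c, m = self._frames(rng, 30, 30)
        g = match_trials(c, m, fraction=1.0, method="greedy")
        o = match_trials(c, m, fraction=1.0, method="optimal")
        assert o.distances.sum() <= g.distances.sum() + 1e-9


class TestContactImputation:
    def test_intercept_only_model(self):
        model = fit_contact_model([0.4, 0.6], [15.0, 15.0])
        assert impute_contact_position(0.9, model) == pytest.approx(15.0)

    def test_imputed_frame_monotone_in_position(self):
        disp = np.linspace(0, 1000, 2001)
        f1 = impute_contact_frame(disp, 800.0, 20.0)
        f2 = impute_contact_frame(disp, 800.0, 10.0)
        assert f2 > f1

    def test_extrapolation_warns(self):
        model = fit_contact_model([0.4, 0.6], [14.0, 18.0])
        with pytest.warns(UserWarning):
            impute_contact_position(0.9, model, training_range=(0.4, 0.6))
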