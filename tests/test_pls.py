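import warnings

import numpy as np
import pandas as pd
import pytest

from mitoscreen import (
    correct_dataset,
    fit_pls,
    pls_pipeline,
    predict_scores,
    remove_outlier_controls,
    select_features,
)
from mitoscreen.errors import FitError


def two_class_controls(rng, n_per_class=40, n_params=84, n_shifted=65, shift=3.0):
    """Control wells: negatives at 0, positives shifted on the first n_shifted."""
    X = rng.normal(0, 1, (2 * n_per_class, n_params))
    X[n_per_class:, :n_shifted] -= shift
    labels = ["negative_control"] * n_per_class + ["positive_control"] * n_per_class
    cols = [f"p{i:02d}" for i in range(n_params)]
    return pd.DataFrame(X, columns=cols), labels


class TestSelectFeatures:
    def test_identical_parameter_never_selected(self, rng):
        X, labels = two_class_controls(rng, n_shifted=10, n_params=12)
        X["p11"] = 1.0  # constant in both classes
        result = select_features(X, labels)
        assert not result.loc["p11", "selected"]
        assert result.loc["p11", "p"] == 1.0

    def test_shifted_parameters_recovered(self, rng):
        X, labels = two_class_controls(rng)
        result = select_features(X, labels, fdr=0.05)
        shifted = [f"p{i:02d}" for i in range(65)]
        null = [f"p{i:02d}" for i in range(65, 84)]
        assert result.loc[shifted, "selected"].sum() >= 60
        assert result.loc[null, "selected"].sum() <= 2

    def test_fdr_zero_selects_nothing(self, rng):
        X, labels = two_class_controls(rng)
        assert select_features(X, labels, fdr=0.0)["selected"].sum() == 0

    def test_adjusted_p_not_below_raw(self, rng):
        X, labels = two_class_controls(rng, n_per_class=10, n_params=20, n_shifted=5)
        result = select_features(X, labels)
        assert (result["p_adj"] >= result["p"] - 1e-12).all()


class TestOutlierRemoval:
    def test_null_calibration(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (80, 10)))
        report = remove_outlier_controls(X, confidence=0.99)
        assert 0 <= report["excluded"].mean() <= 0.06  # ~1% expected at 99%

    def test_planted_outlier_flagged(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (60, 8)))
        X.iloc[7, 3] += 10.0
        report = remove_outlier_controls(X)
        assert bool(report.loc[7, "excluded"])

    def test_degenerate_shape_handled(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (3, 84)))
        report = remove_outlier_controls(X)
        assert len(report) == 3  # subspace reduction engages; no crash

    def test_exclusion_consistent_with_limit(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (50, 6)))
        report = remove_outlier_controls(X)
        assert (report["excluded"] == (report["t2"] > report["limit"])).all()


class TestFitPls:
    def test_separable_controls(self, rng):
        X, labels = two_class_controls(rng, n_per_class=30, n_params=20, n_shifted=15, shift=8.0)
        model = fit_pls(X, labels, seed=0)
        scores = predict_scores(model, X)
        neg = scores[:30]
        pos = scores[30:]
        assert neg.min() > pos.max() or pos.min() > neg.max()
        assert model.cv_error < 0.05

    def test_weight_matches_cross_covariance_oracle(self):
        """One-component PLS weight = dominant singular vector of Xc' yc."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            n, m = 30, 8
            X = pd.DataFrame(r.normal(0, 1, (n, m)))
            y = np.where(r.random(n) > 0.5, 1.0, -1.0)
            model = fit_pls(X, y, max_components=1, folds=3, seed=0)
            Xc = X.to_numpy() - X.to_numpy().mean(0)
            yc = y - y.mean()
            oracle = Xc.T @ yc
            oracle /= np.linalg.norm(oracle)
            w = model.estimator.x_weights_[:, 0]
            assert abs(np.dot(w, oracle)) >= 0.999

    def test_permutation_null(self, rng):
        X, labels = two_class_controls(rng, n_per_class=30, n_params=20, n_shifted=15, shift=5.0)
        permuted = rng.permutation(labels)
        model = fit_pls(X, permuted, seed=0)
        assert model.cv_error > 0.5  # no better than guessing the +-1 label
        assert model.n_components <= 3

    def test_deterministic_given_seed(self, rng):
        X, labels = two_class_controls(rng, n_per_class=20, n_params=10, n_shifted=6)
        m1 = fit_pls(X, labels, seed=5)
        m2 = fit_pls(X, labels, seed=5)
        assert m1.n_components == m2.n_components
        np.testing.assert_array_equal(
            predict_scores(m1, X).to_numpy(), predict_scores(m2, X).to_numpy()
        )

    def test_one_class_raises(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (20, 5)))
        with pytest.raises(FitError):
            fit_pls(X, ["negative_control"] * 20)


class TestPredictScores:
    def test_affine_invariance(self, rng):
        X, labels = two_class_controls(rng, n_per_class=20, n_params=6, n_shifted=4)
        shift = rng.normal(0, 5, 6)
        model_a = fit_pls(X, labels, seed=1)
        model_b = fit_pls(X + shift, labels, seed=1)
        wells = pd.DataFrame(rng.normal(0, 1, (10, 6)), columns=X.columns)
        sa = predict_scores(model_a, wells)
        sb = predict_scores(model_b, wells + shift)
        np.testing.assert_allclose(sa.to_numpy(), sb.to_numpy(), atol=1e-8)

    def test_negative_centroid_scores_at_negative_pole(self, rng):
        X, labels = two_class_controls(rng, n_per_class=30, n_params=10, n_shifted=8, shift=6.0)
        model = fit_pls(X, labels, seed=0)
        centroid = X.iloc[:30].mean().to_frame().T
        s = predict_scores(model, centroid).iloc[0]
        neg_scores = predict_scores(model, X.iloc[:30])
        assert neg_scores.min() - 1e-9 <= s <= neg_scores.max() + 1e-9

    def test_held_out_positives_cluster_at_positive_pole(self, rng):
        X, labels = two_class_controls(rng, n_per_class=40, n_params=12, n_shifted=9, shift=6.0)
        model = fit_pls(X, labels, seed=0)
        new_pos = pd.DataFrame(rng.normal(0, 1, (15, 12)), columns=X.columns)
        new_pos.iloc[:, :9] -= 6.0
        pos_pole = predict_scores(model, X.iloc[40:]).mean()
        neg_pole = predict_scores(model, X.iloc[:40]).mean()
        s = predict_scores(model, new_pos)
        assert all(abs(s - pos_pole) < abs(s - neg_pole))

    def test_missing_selected_parameter(self, rng):
        X, labels = two_class_controls(rng, n_per_class=20, n_params=6, n_shifted=4)
        model = fit_pls(X, labels, seed=0)
        with pytest.raises(KeyError):
            predict_scores(model, X.drop(columns=["p01"]))


class TestPlsPipeline:
    def test_planted_recovery_end_to_end(self, planted_screen):
        (dataset, truth), _ = planted_screen
        corrected, _ = correct_dataset(dataset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, details = pls_pipeline(corrected, seed=0)
        planted = set(truth.planted_genes()) & set(table.index)
        hits = set(table.index[table["pls_hit"] != "none"])
        null_genes = set(table.index) - planted
        assert len(hits & planted) / len(planted) >= 0.9
        assert len(hits - planted) / max(1, len(null_genes)) <= 0.01
        # the bad plate was removed by score-based QC
        assert not details["qc_report"].loc[
            details["qc_report"]["plate_id"] == "P003", "passed"
        ].any()
        # feature selection found (most of) the informative parameters
        informative = [p for p, flag in truth.informative.items() if flag]
        fs = details["feature_selection"]
        assert fs.loc[informative, "selected"].mean() >= 0.9

    def test_planted_ranking_dominates_null(self, planted_screen):
        (dataset, truth), _ = planted_screen
        corrected, _ = correct_dataset(dataset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, _ = pls_pipeline(corrected, seed=0)
        planted = [g for g in table.index if truth.direction[g] != 0]
        null = [g for g in table.index if truth.direction[g] == 0]
        cut = table.loc[null, "pls_ssmd"].abs().quantile(0.95)
        assert (table.loc[planted, "pls_ssmd"].abs() > cut).all()
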