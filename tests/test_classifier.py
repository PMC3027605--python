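"""Shrunken-centroids training/prediction, cross-validation, and evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from sklearn.neighbors import NearestCentroid

from metacgh.classifier import (cross_validate_nsc, default_delta_grid, evaluate,
                                feature_report, load_nsc, mann_whitney_auc,
                                predict_nsc, roc_from_score, save_nsc, train_nsc)
from metacgh.genome import Genome
from metacgh.io import CloneMap


def brute_force_nsc(X, y, delta, s0=None):
    """Loop implementation of the four shrunken-centroid formulas."""
    labels = sorted(set(y), key=list(y).index)
    n, p = X.shape
    overall = np.array([X[:, i].mean() for i in range(p)])
    cent = np.array([[X[y == k, i].mean() for i in range(p)] for k in labels])
    s = np.zeros(p)
    for i in range(p):
        ss = 0.0
        for k, lab in enumerate(labels):
            for xi in X[y == lab, i]:
                ss += (xi - cent[k, i]) ** 2
        s[i] = np.sqrt(ss / (n - len(labels)))
    if s0 is None:
        s0 = np.median(s)
    shrunken = np.zeros_like(cent)
    for k, lab in enumerate(labels):
        nk = (y == lab).sum()
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        for i in range(p):
            d = (cent[k, i] - overall[i]) / (mk * (s[i] + s0))
            dp = np.sign(d) * max(abs(d) - delta, 0.0)
            shrunken[k, i] = overall[i] + mk * (s[i] + s0) * dp
    return labels, overall, cent, s, s0, shrunken


@pytest.fixture(scope="module")
def toy_xy():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(14, 3))
    X[:6] += np.array([1.0, 0.0, -0.5])
    y = np.array(["pos"] * 6 + ["neg"] * 8, dtype=object)
    return X, y


class TestTrainNsc:
    def test_zero_delta_keeps_raw_centroids(self, toy_xy):
        X, y = toy_xy
        m = train_nsc(X, y, 0.0)
        assert np.max(np.abs(m.shrunken_centroids - m.class_centroids)) < 1e-12

    def test_full_shrinkage_collapses_to_overall(self, toy_xy):
        X, y = toy_xy
        m = train_nsc(X, y, 1e6)
        assert np.allclose(m.shrunken_centroids, m.overall_centroid)
        assert len(m.selected_features) == 0

    @pytest.mark.parametrize("delta", [0.0, 0.2, 0.7, 1.5])
    def test_matches_bruteforce_formulas(self, toy_xy, delta):
        X, y = toy_xy
        m = train_nsc(X, y, delta)
        labels, overall, cent, s, s0, shrunken = brute_force_nsc(X, y, delta)
        assert m.class_labels == labels
        assert np.max(np.abs(m.overall_centroid - overall)) < 1e-12
        assert np.max(np.abs(m.pooled_sd - s)) < 1e-12
        assert m.s0 == pytest.approx(s0, abs=1e-12)
        assert np.max(np.abs(m.shrunken_centroids - shrunken)) < 1e-12

    @pytest.mark.parametrize("delta", [0.3, 1.0])
    def test_matches_sklearn_shrunken_centroids(self, toy_xy, delta):
        """Independent cross-check: sklearn's shrink_threshold implements the
        same soft-thresholded standardized deviations."""
        X, y = toy_xy
        m = train_nsc(X, y, delta)
        nc = NearestCentroid(shrink_threshold=delta).fit(X, y.astype(str))
        ours = pd.DataFrame(m.shrunken_centroids, index=m.class_labels)
        theirs = pd.DataFrame(nc.centroids_, index=nc.classes_)
        assert np.max(np.abs(ours.loc[theirs.index].to_numpy() - theirs.to_numpy())) < 1e-10

    def test_selected_features_shrink_with_delta(self, toy_xy):
        X, y = toy_xy
        counts = [len(train_nsc(X, y, d).selected_features) for d in np.linspace(0, 3, 10)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_input_validation(self, toy_xy):
        X, y = toy_xy
        with pytest.raises(ValueError, match="nonnegative"):
            train_nsc(X, y, -0.1)
        with pytest.raises(ValueError, match="at least 2 samples"):
            train_nsc(X[:7], np.array(["a"] * 6 + ["b"]), 0.0)
        Xm = X.copy()
        Xm[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            train_nsc(Xm, y, 0.0)


class TestPredictNsc:
    def test_centroid_classified_to_own_class(self, toy_xy):
        X, y = toy_xy
        m = train_nsc(X, y, 0.2, priors=np.array([0.5, 0.5]))
        for k, lab in enumerate(m.class_labels):
            pred, _ = predict_nsc(m, m.shrunken_centroids[k])
            assert pred[0] == lab

    def test_fully_shrunk_predicts_prior_argmax(self, toy_xy):
        X, y = toy_xy
        m = train_nsc(X, y, 1e6)  # empirical priors: neg 8/14 > pos 6/14
        pred, _ = predict_nsc(m, X)
        assert set(pred) == {"neg"}

    def test_probabilities_sum_to_one_and_swap_with_labels(self, toy_xy):
        X, y = toy_xy
        m = train_nsc(X, y, 0.2)
        _, prob = predict_nsc(m, X)
        assert np.allclose(prob.sum(axis=1), 1.0)
        y_swapped = np.where(y == "pos", "neg", "pos").astype(object)
        m2 = train_nsc(X, y_swapped, 0.2)
        _, prob2 = predict_nsc(m2, X)
        i = {lab: j for j, lab in enumerate(m.class_labels)}
        i2 = {lab: j for j, lab in enumerate(m2.class_labels)}
        # class renaming permutes probability columns
        assert np.allclose(prob[:, i["pos"]], prob2[:, i2["neg"]])

    def test_reduces_to_standardized_nearest_centroid(self, toy_xy):
        """At delta=0, equal priors, s0=0 the rule is nearest centroid in
        s_i-standardized coordinates."""
        X, y = toy_xy
        m = train_nsc(X, y, 0.0, priors=np.array([0.5, 0.5]), s0=0.0)
        pred, _ = predict_nsc(m, X)
        nc = NearestCentroid().fit(X / m.pooled_sd, y.astype(str))
        assert np.array_equal(pred.astype(str), nc.predict(X / m.pooled_sd))

    def test_dimension_mismatch(self, toy_xy):
        X, y = toy_xy
        m = train_nsc(X, y, 0.0)
        with pytest.raises(ValueError, match="dimension"):
            predict_nsc(m, X[:, :2])


def test_model_flat_file_round_trip(tmp_path, toy_xy):
    X, y = toy_xy
    m = train_nsc(X, y, 0.4)
    save_nsc(m, tmp_path / "model.tsv")
    back = load_nsc(tmp_path / "model.tsv")
    assert back.class_labels == m.class_labels
    assert back.delta == m.delta and back.s0 == m.s0
    assert np.array_equal(back.priors, m.priors)
    assert np.array_equal(back.shrunken_centroids, m.shrunken_centroids)
    p1, pr1 = predict_nsc(m, X)
    p2, pr2 = predict_nsc(back, X)
    assert np.array_equal(p1, p2) and np.array_equal(pr1, pr2)


class TestCrossValidation:
    def test_separable_blobs_reach_zero_error(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, (15, 4)), rng.normal(3, 0.3, (15, 4))])
        y = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        cv = cross_validate_nsc(X, y, np.array([0.0, 0.5]), n_folds=5, seed=0)
        assert cv.error[0] == 0.0

    def test_huge_delta_gives_majority_error(self, toy_xy):
        X, y = toy_xy
        cv = cross_validate_nsc(X, y, np.array([1e6]), n_folds=4, seed=1)
        assert cv.error[0] == pytest.approx(1 - 8 / 14, abs=0.15)

    def test_seed_contract_and_empty_grid(self, toy_xy):
        X, y = toy_xy
        a = cross_validate_nsc(X, y, np.array([0.0, 0.3]), 4, seed=7)
        b = cross_validate_nsc(X, y, np.array([0.0, 0.3]), 4, seed=7)
        assert np.array_equal(a.error, b.error) and a.chosen_delta == b.chosen_delta
        with pytest.raises(ValueError, match="empty"):
            cross_validate_nsc(X, y, np.array([]), 4, seed=0)

    def test_default_grid_spans_to_empty_model(self, toy_xy):
        X, y = toy_xy
        grid = default_delta_grid(X, y)
        assert grid[0] == 0.0
        assert len(train_nsc(X, y, grid[-1] + 1e-9).selected_features) == 0


class TestEvaluation:
    def test_perfect_predictions(self):
        truth = np.array(["p", "p", "n", "n"], dtype=object)
        ev = evaluate(truth, np.array([0.9, 0.8, 0.1, 0.2]), truth, "p")
        assert ev.accuracy == ev.sensitivity == ev.specificity == 1.0
        assert ev.auc == 1.0

    def test_constant_probability_auc_half(self):
        truth = np.array(["p", "n", "p", "n"], dtype=object)
        ev = evaluate(truth, np.full(4, 0.5), truth, "p")
        assert ev.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(8)
        truth = np.array(["p"] * 30 + ["n"] * 40, dtype=object)
        scores = np.round(rng.normal(size=70) + (truth == "p") * 0.7, 1)  # with ties
        _, auc = roc_from_score(scores, truth, "p")
        assert auc == pytest.approx(mann_whitney_auc(scores, truth, "p"), abs=1e-12)

    def test_reversed_scores_flip_auc(self):
        rng = np.random.default_rng(9)
        truth = np.array(["p"] * 10 + ["n"] * 10, dtype=object)
        scores = rng.normal(size=20)
        _, a = roc_from_score(scores, truth, "p")
        _, b = roc_from_score(-scores, truth, "p")
        assert a == pytest.approx(1.0 - b)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_from_score(np.r_[1.0, 2.0], np.array(["p", "p"], dtype=object), "p")

    def test_unknown_positive_label_rejected(self):
        truth = np.array(["p", "n"], dtype=object)
        with pytest.raises(ValueError, match="absent"):
            evaluate(truth, np.r_[0.9, 0.1], truth, "x")


class TestFeatureReport:
    @pytest.fixture()
    def ten_clone_map(self):
        gen = Genome({"1": 60_000_000, "2": 60_000_000}, {"1": 25_000_000, "2": 25_000_000})
        rows = [(f"c{i}", "1" if i < 5 else "2", 5_000_000 + (i % 5) * 10_000_000)
                for i in range(10)]
        return CloneMap.from_positions(
            pd.DataFrame(rows, columns=["clone_id", "chromosome", "position_bp"]), gen)

    def test_no_selected_features_empty_report(self, toy_xy, ten_clone_map):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(14, 10))
        y = np.array(["a"] * 7 + ["b"] * 7, dtype=object)
        m = train_nsc(X, y, 1e6)
        feats, enr = feature_report(m, ten_clone_map)
        assert len(feats) == 0
        assert (enr["p_enrichment"] == 1.0).all()

    def test_hypergeometric_matches_tail_sum(self, ten_clone_map):
        """One-sided enrichment p equals the explicit hypergeometric tail."""
        rng = np.random.default_rng(1)
        # concentrate signal on the 3 chr1 p-arm clones (positions 5,15,25 Mb)
        X = rng.normal(0, 0.3, size=(16, 10))
        X[:8, :3] += 2.0
        y = np.array(["a"] * 8 + ["b"] * 8, dtype=object)
        m = train_nsc(X, y, 1.0)
        feats, enr = feature_report(m, ten_clone_map)
        sel = m.selected_features
        arms = pd.Series(ten_clone_map.arm_label())
        for _, row in enr.iterrows():
            M, n, N = 10, row["clones_on_arm"], len(sel)
            k = row["selected_on_arm"]
            tail = sum(comb(n, j) * comb(M - n, N - j) / comb(M, N)
                       for j in range(int(k), int(min(n, N)) + 1))
            assert row["p_enrichment"] == pytest.approx(tail, rel=1e-10)

    def test_concentrated_selection_minimizes_that_arm(self, ten_clone_map):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 0.2, size=(16, 10))
        X[:8, :3] += 3.0  # chr1 p-arm clones only
        y = np.array(["a"] * 8 + ["b"] * 8, dtype=object)
        m = train_nsc(X, y, 2.0)
        feats, enr = feature_report(m, ten_clone_map)
        assert set(feats["chromosome"]) == {"1"}
        assert enr.iloc[0]["arm"] == "1p"
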