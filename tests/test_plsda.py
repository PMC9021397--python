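"""PLS-DA core, LOOCV, balanced voting ensemble, VIP, confusion metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrfp import plsda


class TestFitPLS:
    def test_separable_single_column(self):
        rng = np.random.default_rng(0)
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        X = np.column_stack([y, rng.normal(scale=0.01, size=(6, 3))])
        model = plsda.fit_pls(X, y, 1)
        w = np.abs(model.x_weights[:, 0])
        assert np.argmax(w) == 0 and w[0] > 0.99
        _, labels = plsda.plsda_predict(model, X)
        np.testing.assert_array_equal(labels, plsda.decode_labels(y))

    def test_matches_library_oracle(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        y = np.array([-1.0] * 5 + [1.0] * 5)
        model = plsda.fit_pls(X, y, 3)
        sk = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        for a in range(3):
            mine, theirs = model.x_weights[:, a], sk.x_weights_[:, a]
            sign = np.sign(mine @ theirs)
            np.testing.assert_allclose(mine, sign * theirs, atol=1e-6)
            np.testing.assert_allclose(model.x_loadings[:, a],
                                       sign * sk.x_loadings_[:, a], atol=1e-6)
        np.testing.assert_allclose(model.predict_score(X),
                                   sk.predict(X).ravel(), atol=1e-6)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 8))
        y = np.array([-1.0, 1.0] * 10)
        model = plsda.fit_pls(X, y, 4)
        G = model.x_scores.T @ model.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_first_direction_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 5))
        y = np.array([-1.0] * 8 + [1.0] * 7)
        w0 = plsda.fit_pls(X, y, 1).x_weights[:, 0]
        w1 = plsda.fit_pls(X + 17.3, y, 1).x_weights[:, 0]
        np.testing.assert_allclose(w0, w1, atol=1e-10)

    @pytest.mark.parametrize("bad_y", [np.ones(6), np.full(6, -1.0)])
    def test_single_class_rejected(self, bad_y):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="both classes"):
            plsda.fit_pls(X, bad_y, 1)

    def test_zero_components_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        y = np.array([-1.0, 1, -1, 1, -1, 1])
        with pytest.raises(ValueError):
            plsda.fit_pls(X, y, 0)


class TestPredict:
    def test_mean_row_predicts_y_mean(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        y = np.array([-1.0] * 7 + [1.0] * 5)
        model = plsda.fit_pls(X, y, 2)
        score = model.predict_score(X.mean(axis=0))
        assert score[0] == pytest.approx(model.y_mean, abs=1e-12)

    def test_brute_force_score_recomputation(self):
        # recompute predictions through the sequential weights/loadings
        # instead of the collapsed coefficient vector
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 4))
        y = np.array([-1.0, 1, -1, 1, -1, 1])
        model = plsda.fit_pls(X, y, 2)
        Xc = X - model.x_mean
        pred = np.full(X.shape[0], model.y_mean)
        for a in range(model.n_components):
            t = Xc @ model.x_weights[:, a]
            pred += model.y_loadings[a] * t
            Xc = Xc - np.outer(t, model.x_loadings[:, a])
        np.testing.assert_allclose(model.predict_score(X), pred, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        y = np.array([-1.0, 1, -1, 1, -1, 1])
        model = plsda.fit_pls(X, y, 1)
        with pytest.raises(ValueError, match="columns"):
            model.predict_score(np.zeros((2, 5)))


class TestVIP:
    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 9))
        y = np.array([-1.0] * 8 + [1.0] * 7)
        for ncomp in (1, 3, 5):
            vip, _ = plsda.vip_scores(plsda.fit_pls(X, y, ncomp))
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-10)

    def test_informative_column_has_max_vip_and_is_selected(self):
        rng = np.random.default_rng(7)
        y = np.array([-1.0] * 10 + [1.0] * 10)
        X = np.column_stack([y + rng.normal(scale=0.05, size=20),
                             rng.normal(size=(20, 5))])
        vip, selected = plsda.vip_scores(plsda.fit_pls(X, y, 2))
        assert np.argmax(vip) == 0
        assert selected[0]

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 6))
        y = np.array([-1.0] * 5 + [1.0] * 5)
        model = plsda.fit_pls(X, y, 3)
        ss = np.array([model.y_loadings[a] ** 2
                       * model.x_scores[:, a] @ model.x_scores[:, a]
                       for a in range(3)])
        expected = np.sqrt(6 * (model.x_weights**2 @ ss) / ss.sum())
        vip, _ = plsda.vip_scores(model)
        np.testing.assert_allclose(vip, expected, atol=1e-10)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        labels = np.array(["deceased", "survivor", "deceased"])
        m = plsda.confusion_metrics(labels, labels)
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_published_style_counts(self):
        # unique integer confusion matrix on class sizes (26, 80) giving
        # sensitivity 76.9%, specificity 68.8%, accuracy 70.8%
        m = plsda.ConfusionMetrics(tp=20, fn=6, tn=55, fp=25)
        assert round(100 * m.sensitivity, 1) == 76.9
        assert round(100 * m.specificity, 1) == 68.8
        assert round(100 * m.accuracy, 1) == 70.8

    def test_all_negative_prediction_has_zero_sensitivity(self):
        pred = np.array(["survivor"] * 5)
        truth = np.array(["survivor", "deceased", "deceased", "survivor",
                          "survivor"])
        m = plsda.confusion_metrics(pred, truth)
        assert m.sensitivity == 0.0
        assert m.tp == 0 and m.fn == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            plsda.confusion_metrics(np.array([]), np.array([]))


class TestLOOCV:
    def test_tight_clusters_classify_perfectly(self, separable_blobs):
        X, y = separable_blobs
        _, metrics = plsda.loocv(X, y, 2)
        assert metrics.accuracy == 1.0

    def test_minimal_balanced_case_runs(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(4, 3))
        y = np.array([-1.0, -1, 1, 1])
        labels, _ = plsda.loocv(X, y, 1)
        assert labels.shape == (4,)

    def test_permutation_null_accuracy_near_half(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 20))
        y = np.array([-1.0] * 30 + [1.0] * 30)
        accs = []
        for k in range(50):
            yp = np.random.default_rng(k).permutation(y)
            _, m = plsda.loocv(X, yp, 3)
            accs.append(m.accuracy)
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_loocv_never_beats_resubstitution_on_average(self):
        diffs = []
        for k in range(20):
            rng = np.random.default_rng(100 + k)
            n = 30
            y = np.array([-1.0] * 15 + [1.0] * 15)
            X = rng.normal(size=(n, 10)) + 0.4 * y[:, None]
            model = plsda.fit_pls(X, y, 3)
            resub = plsda.confusion_metrics(model.predict_label(X),
                                            plsda.decode_labels(y)).accuracy
            _, cv = plsda.loocv(X, y, 3)
            diffs.append(resub - cv.accuracy)
        assert np.mean(diffs) >= 0.0

    def test_small_or_degenerate_inputs_rejected(self):
        X = np.zeros((2, 2))
        with pytest.raises(ValueError):
            plsda.loocv(X, np.array([-1.0, 1.0]), 1)
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="2 members"):
            plsda.loocv(X, np.array([-1.0, 1, 1, 1, 1]), 1)


class TestMajorityVote:
    @pytest.mark.parametrize("votes,margin,gray,pred", [
        (60, 0.10, False, "deceased"),   # boundary: strict < keeps it out
        (55, 0.05, True, "deceased"),
        (50, 0.00, True, "survivor"),    # tie -> survivor, flagged gray
        (40, 0.10, False, "survivor"),
        (100, 0.50, False, "deceased"),
    ])
    def test_margin_and_gray_zone_semantics(self, votes, margin, gray, pred):
        v = plsda.majority_vote(votes, 100)
        assert v.margin == pytest.approx(margin)
        assert v.gray_zone is gray
        assert v.predicted_class == pred

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            plsda.majority_vote(1, 0)
        with pytest.raises(ValueError):
            plsda.majority_vote(5, 4)


@settings(deadline=None, max_examples=100)
@given(st.integers(0, 200), st.integers(1, 200))
def test_majority_vote_invariants(votes_d, total):
    """Margin bounded by 1/2; gray-zone definition is consistent."""
    if votes_d > total:
        votes_d = total
    v = plsda.majority_vote(votes_d, total)
    assert 0.0 <= v.margin <= 0.5
    assert v.votes_deceased <= v.votes_total
    if v.margin >= 0.10 + 1e-12:
        assert not v.gray_zone
    if v.margin < 0.10 - 1e-12:
        assert v.gray_zone


class TestEnsemble:
    def test_every_sample_gets_exactly_n_iter_votes(self, separable_blobs):
        X, y = separable_blobs
        res = plsda.balanced_ensemble(X, y, n_iter=12, per_class=10,
                                      n_components=2, seed=0)
        assert (res.votes["votes_total"] == 12).all()

    def test_same_seed_reproduces_votes(self, separable_blobs):
        X, y = separable_blobs
        a = plsda.balanced_ensemble(X, y, n_iter=8, per_class=10,
                                    n_components=2, seed=3)
        b = plsda.balanced_ensemble(X, y, n_iter=8, per_class=10,
                                    n_components=2, seed=3)
        assert a.votes.equals(b.votes)

    def test_growing_n_iter_preserves_early_iterations(self, separable_blobs):
        X, y = separable_blobs
        short = plsda.balanced_ensemble(X, y, n_iter=5, per_class=10,
                                        n_components=2, seed=3)
        long = plsda.balanced_ensemble(X, y, n_iter=10, per_class=10,
                                       n_components=2, seed=3)
        np.testing.assert_allclose(
            short.iteration_metrics["accuracy"],
            long.iteration_metrics["accuracy"][:5])

    def test_separable_data_classified_perfectly(self, separable_blobs):
        X, y = separable_blobs
        res = plsda.balanced_ensemble(X, y, n_iter=15, per_class=10,
                                      n_components=2, seed=1)
        assert res.metrics().accuracy == 1.0

    def test_gray_zone_removal_never_hurts_separable_benchmark(
            self, separable_blobs):
        X, y = separable_blobs
        res = plsda.balanced_ensemble(X, y, n_iter=15, per_class=10,
                                      n_components=2, seed=2)
        assert res.metrics(exclude_gray=True).accuracy >= \
            res.metrics().accuracy

    def test_per_class_too_large_suggests_reduction(self, separable_blobs):
        X, y = separable_blobs
        with pytest.raises(ValueError, match="reduce per_class"):
            plsda.balanced_ensemble(X, y, per_class=31)

    def test_summary_mentions_key_metrics(self, separable_blobs):
        X, y = separable_blobs
        res = plsda.balanced_ensemble(X, y, n_iter=6, per_class=10,
                                      n_components=2, seed=0)
        text = res.summary()
        assert "accuracy" in text and "gray-zone" in text
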