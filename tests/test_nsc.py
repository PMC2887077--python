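"""Nearest-shrunken-centroid classifier and repeated-CV voting."""

import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest

from bastage.nsc import (
    UNCLASSIFIED,
    NSCError,
    NSCModel,
    fit_nsc,
    predict_matrix,
    predict_nsc,
    repeated_cv_classify,
    select_delta,
    shrink,
)


def make_frame(X, labels=None):
    X = np.asarray(X, dtype=float)
    m = pd.DataFrame(X, index=[f"P{i}" for i in range(X.shape[0])],
                     columns=[f"S{j}" for j in range(X.shape[1])])
    if labels is None:
        return m
    return m, pd.Series(labels, index=m.columns)


def brute_force_fit(X, y, m_variant="plus"):
    """Independent loop-based recomputation of every fitted quantity."""
    classes = sorted(set(y))
    n, K = len(y), len(classes)
    p = X.shape[0]
    overall = np.array([np.mean(X[i]) for i in range(p)])
    cents = np.zeros((p, K))
    ss = np.zeros(p)
    n_k = np.zeros(K)
    for k, c in enumerate(classes):
        cols = [j for j in range(n) if y[j] == c]
        n_k[k] = len(cols)
        for i in range(p):
            cents[i, k] = np.mean([X[i, j] for j in cols])
            ss[i] += sum((X[i, j] - cents[i, k]) ** 2 for j in cols)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    if m_variant == "plus":
        m_k = np.sqrt(1 / n_k + 1 / n)
    else:
        m_k = np.sqrt(1 / n_k - 1 / n)
    d = np.zeros((p, K))
    for i in range(p):
        for k in range(K):
            d[i, k] = (cents[i, k] - overall[i]) / (m_k[k] * (s[i] + s0))
    return overall, cents, s, s0, m_k, d, n_k


class TestFit:
    def test_two_sample_hand_case(self):
        # one probe, class A = (1,3), class B = (5,7)
        m, labels = make_frame([[1.0, 3.0, 5.0, 7.0]], ["A", "A", "B", "B"])
        model = fit_nsc(m, labels)
        assert model.overall_centroid[0] == pytest.approx(4.0)
        np.testing.assert_allclose(model.class_centroids[0], [2.0, 6.0])
        # pooled variance: ((1-2)^2+(3-2)^2+(5-6)^2+(7-6)^2)/(4-2) = 2
        assert model.pooled_sd[0] == pytest.approx(np.sqrt(2.0))
        assert model.s0 == pytest.approx(np.sqrt(2.0))
        np.testing.assert_allclose(model.m_k, np.sqrt(1 / 2 + 1 / 4))
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    @pytest.mark.parametrize("m_variant", ["plus", "minus"])
    def test_matches_brute_force_oracle(self, rng, m_variant):
        X = rng.normal(5, 2, size=(7, 12))
        y = list("AAAABBBBBCCC")
        m, labels = make_frame(X, y)
        model = fit_nsc(m, labels, m_variant=m_variant)
        overall, cents, s, s0, m_k, d, n_k = brute_force_fit(X, y, m_variant)
        np.testing.assert_allclose(model.overall_centroid, overall, atol=1e-12)
        np.testing.assert_allclose(model.class_centroids, cents, atol=1e-12)
        np.testing.assert_allclose(model.pooled_sd, s, atol=1e-12)
        assert model.s0 == pytest.approx(s0, abs=1e-12)
        np.testing.assert_allclose(model.d, d, atol=1e-12)

    def test_reconstruction_identity(self, small_matrix):
        m, labels = small_matrix
        model = fit_nsc(m, labels)
        rebuilt = (
            model.overall_centroid[:, None]
            + model.m_k[None, :] * (model.pooled_sd + model.s0)[:, None] * model.d
        )
        np.testing.assert_allclose(rebuilt, model.class_centroids, atol=1e-12)

    def test_all_zero_variance_rejected(self):
        m, labels = make_frame([[0.0, 0.0, 2.0, 2.0]], ["A", "A", "B", "B"])
        with pytest.raises(NSCError, match="zero pooled variance"):
            fit_nsc(m, labels)

    def test_singleton_class_rejected(self):
        m, labels = make_frame(np.random.default_rng(0).normal(size=(3, 4)),
                               ["A", "A", "A", "B"])
        with pytest.raises(NSCError, match="singleton"):
            fit_nsc(m, labels)

    def test_label_swap_leaves_predictions_unchanged(self, small_matrix):
        m, labels = small_matrix
        swapped = labels.map({"inflammation": "fibrosis", "fibrosis": "inflammation"})
        pred1 = predict_matrix(fit_nsc(m, labels), m)
        pred2 = predict_matrix(fit_nsc(m, swapped), m)
        assert (pred1 == pred2.map(
            {"inflammation": "fibrosis", "fibrosis": "inflammation"}
        )).all()


class TestShrink:
    def test_delta_zero_is_identity(self, small_matrix):
        m, labels = small_matrix
        model = fit_nsc(m, labels)
        np.testing.assert_array_equal(shrink(model, 0.0).shrunken_d, model.d)

    def test_soft_threshold_arithmetic(self, small_matrix):
        m, labels = small_matrix
        model = fit_nsc(m, labels)
        model = dataclasses.replace(model, d=np.array([[1.5, -0.3]] * len(model.probe_ids)))
        np.testing.assert_allclose(
            shrink(model, 0.5).shrunken_d, [[1.0, 0.0]] * len(model.probe_ids)
        )

    def test_full_shrinkage_collapses_to_overall_centroid(self, small_matrix):
        m, labels = small_matrix
        model = fit_nsc(m, labels)
        big = shrink(model, float(np.abs(model.d).max()) + 1.0)
        assert big.surviving_probes.sum() == 0
        np.testing.assert_allclose(
            big.shrunken_centroids,
            np.repeat(model.overall_centroid[:, None], 2, axis=1),
        )

    def test_surviving_probes_nonincreasing_in_delta(self, small_matrix):
        m, labels = small_matrix
        model = fit_nsc(m, labels)
        deltas = np.linspace(0, np.abs(model.d).max() * 1.1, 25)
        counts = [shrink(model, d).surviving_probes.sum() for d in deltas]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_delta_rejected(self, small_matrix):
        m, labels = small_matrix
        with pytest.raises(NSCError, match="nonnegative"):
            shrink(fit_nsc(m, labels), -0.1)


class TestPredict:
    def test_probabilities_sum_to_one(self, small_matrix, rng):
        m, labels = small_matrix
        model = fit_nsc(m, labels)
        for _ in range(10):
            _, probs, _ = predict_nsc(model, rng.normal(7, 1, size=30))
            assert probs.sum() == pytest.approx(1.0)
            assert (probs >= 0).all()

    def test_full_shrinkage_uniform_priors_ties(self, small_matrix, caplog):
        m, labels = small_matrix
        model = fit_nsc(m, labels, priors="uniform")
        model = shrink(model, float(np.abs(model.d).max()) + 1.0)
        with caplog.at_level(logging.WARNING, logger="bastage.nsc"):
            label, probs, scores = predict_nsc(model, m.iloc[:, 0].to_numpy())
        assert label == model.class_labels[0]
        assert scores[0] == pytest.approx(scores[1])
        assert "tie" in caplog.text

    def test_centroid_classifies_to_its_class(self, small_matrix):
        m, labels = small_matrix
        model = fit_nsc(m, labels, priors="uniform")
        for k, cls in enumerate(model.class_labels):
            label, probs, _ = predict_nsc(model, model.shrunken_centroids[:, k])
            assert label == cls
            assert probs[k] == probs.max()

    def test_length_mismatch_rejected(self, small_matrix):
        m, labels = small_matrix
        with pytest.raises(NSCError, match="length"):
            predict_nsc(fit_nsc(m, labels), np.zeros(5))

    def test_equals_nearest_standardized_centroid_limit(self, rng):
        """delta=0, uniform priors, s0=0 is the diagonal-Gaussian classifier."""
        for _ in range(20):
            X = rng.normal(0, 1, size=(4, 10))
            X[:2, 5:] += 1.5
            y = ["a"] * 5 + ["b"] * 5
            m, labels = make_frame(X, y)
            fitted = fit_nsc(m, labels, priors="uniform")
            # force the s0 = 0 limit: d must be recomputed consistently
            d0 = (fitted.class_centroids - fitted.overall_centroid[:, None]) / (
                fitted.m_k[None, :] * fitted.pooled_sd[:, None]
            )
            model = dataclasses.replace(fitted, s0=0.0, d=d0)
            queries = rng.normal(0, 1.5, size=(4, 6))
            got = [predict_nsc(model, q)[0] for q in queries.T]
            # independent implementation
            cents = np.stack(
                [X[:, :5].mean(axis=1), X[:, 5:].mean(axis=1)], axis=1
            )
            resid = np.concatenate(
                [X[:, :5] - cents[:, :1], X[:, 5:] - cents[:, 1:]], axis=1
            )
            s = np.sqrt((resid ** 2).sum(axis=1) / (10 - 2))
            expected = []
            for q in queries.T:
                dist = ((q[:, None] - cents) ** 2 / s[:, None] ** 2).sum(axis=0)
                expected.append(["a", "b"][int(np.argmin(dist))])
            assert got == expected


class TestSelectDelta:
    def test_separable_classes_zero_error_at_zero_delta(self, rng):
        X = rng.normal(0, 0.2, size=(10, 20))
        X[:, 10:] += 4.0
        m, labels = make_frame(X, ["a"] * 10 + ["b"] * 10)
        chosen, curve = select_delta(m, labels, [0.0, 0.5, 1.0], folds=5, seed=0)
        assert curve.loc[0.0] == 0.0
        assert curve.min() == 0.0

    def test_prefers_sparser_model_on_ties(self, rng):
        X = rng.normal(0, 0.2, size=(10, 20))
        X[:, 10:] += 4.0
        m, labels = make_frame(X, ["a"] * 10 + ["b"] * 10)
        chosen, curve = select_delta(m, labels, [0.0, 0.1, 0.2], folds=5, seed=0)
        ties = [d for d, e in curve.items() if e == curve.min()]
        assert chosen == max(ties)

    def test_deterministic_under_seed(self, small_matrix):
        m, labels = small_matrix
        a = select_delta(m, labels, [0.0, 0.3, 0.6], folds=5, seed=7)
        b = select_delta(m, labels, [0.0, 0.3, 0.6], folds=5, seed=7)
        assert a[0] == b[0]
        pd.testing.assert_series_equal(a[1], b[1])

    def test_empty_grid_rejected(self, small_matrix):
        m, labels = small_matrix
        with pytest.raises(NSCError, match="empty"):
            select_delta(m, labels, [], seed=0)


class TestRepeatedCV:
    @pytest.fixture()
    def separable(self, rng):
        X = rng.normal(0, 0.3, size=(12, 14))
        X[:6, 9:] += 3.0
        train = make_frame(X)
        labels = pd.Series(["inflammation"] * 9 + ["fibrosis"] * 5,
                           index=train.columns)
        Xe = rng.normal(0, 0.3, size=(12, 6))
        Xe[:6, 3:] += 3.0
        ext = pd.DataFrame(Xe, index=train.index,
                           columns=[f"E{j}" for j in range(6)])
        return train, labels, ext

    def test_vote_bookkeeping_invariants(self, separable):
        train, labels, ext = separable
        votes = repeated_cv_classify(train, labels, ext, seed=3)
        t = votes.table
        total = (t["n_inflammation_votes"] + t["n_fibrosis_votes"]
                 + t["n_abstentions"])
        assert (total == 10).all()
        assert set(t.loc[[f"E{j}" for j in range(6)], "role"]) == {"external"}
        assert set(t.loc[list(train.columns), "role"]) == {"train"}

    def test_unanimous_separable_samples_assigned(self, separable):
        train, labels, ext = separable
        votes = repeated_cv_classify(train, labels, ext, seed=3)
        t = votes.table
        assert (t["assignment"] != UNCLASSIFIED).all()
        # external truth: E0-E2 share the baseline (inflammation) pattern,
        # E3-E5 the shifted (fibrosis) pattern
        assert (t.loc[["E0", "E1", "E2"], "assignment"] == "inflammation").all()
        assert (t.loc[["E3", "E4", "E5"], "assignment"] == "fibrosis").all()

    def test_five_five_split_is_unclassified(self):
        from bastage.nsc import _tally

        counts, abst, assignment = _tally(
            ["a"] * 5 + ["b"] * 5, ("a", "b"), vote_threshold=6
        )
        assert assignment == UNCLASSIFIED
        counts, abst, assignment = _tally(
            ["a"] * 6 + ["b"] * 4, ("a", "b"), vote_threshold=6
        )
        assert assignment == "a"
        counts, abst, assignment = _tally(
            ["a"] * 5 + ["b"] * 4 + [None], ("a", "b"), vote_threshold=6
        )
        assert assignment == UNCLASSIFIED and abst == 1

    def test_assignments_invariant_to_orderings(self, separable):
        train, labels, ext = separable
        base = repeated_cv_classify(train, labels, ext, seed=9).assignments
        perm_cols = train.columns[::-1]
        perm_rows = train.index[::-1]
        shuffled = repeated_cv_classify(
            train.loc[perm_rows, perm_cols], labels[perm_cols],
            ext.loc[perm_rows], seed=9,
        ).assignments
        assert (base.sort_index() == shuffled.sort_index()).all()

    def test_too_many_folds_rejected(self, separable):
        train, labels, _ = separable
        with pytest.raises(NSCError, match="folds"):
            repeated_cv_classify(train, labels, folds=99, seed=0)

    def test_full_model_external_mode(self, separable):
        train, labels, ext = separable
        votes = repeated_cv_classify(train, labels, ext, seed=3,
                                     external_mode="full_model")
        ext_rows = votes.table.loc[[f"E{j}" for j in range(6)]]
        assert (ext_rows["n_abstentions"] == 0).all()
        assert (ext_rows["assignment"] != UNCLASSIFIED).all()


class TestSklearnCrossCheck:
    def test_shrunken_centroids_match_sklearn(self, rng):
        """Shrunken centroid geometry agrees with scikit-learn's PAM variant."""
        sklearn = pytest.importorskip("sklearn.neighbors")
        for _ in range(10):
            X = rng.normal(size=(9, 3))
            y = np.array(["a"] * 5 + ["b"] * 4)
            m = pd.DataFrame(X.T, index=[f"P{i}" for i in range(3)],
                             columns=[f"S{j}" for j in range(9)])
            model = shrink(
                fit_nsc(m, pd.Series(y, index=m.columns), m_variant="minus"), 0.25
            )
            sk = sklearn.NearestCentroid(shrink_threshold=0.25)
            sk.fit(X, y)
            np.testing.assert_allclose(
                model.shrunken_centroids.T, sk.centroids_, atol=1e-10
            )


def test_model_json_round_trip(small_matrix):
    m, labels = small_matrix
    model = shrink(fit_nsc(m, labels), 0.4)
    restored = NSCModel.from_json(model.to_json())
    np.testing.assert_allclose(restored.d, model.d)
    np.testing.assert_allclose(restored.shrunken_centroids, model.shrunken_centroids)
    assert restored.class_labels == model.class_labels
    assert restored.delta == model.delta
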