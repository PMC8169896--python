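"""PCA reduction, LDA axes, cross-validated classification and k-NN."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from morphosus.classify import (
    DEFAULT_VARIANCE_THRESHOLD,
    ClassificationError,
    choose_k,
    crossvalidated_accuracy,
    fit_discriminant,
    fit_lda,
    knn_status_predict,
    pca_reduce,
    project_specimens,
)


def _spectrum_data(shares=(0.90, 0.06, 0.04), n=40, seed=0):
    """Rows whose sample covariance has exactly the given eigenvalue shares."""
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, len(shares)))
    Z -= Z.mean(axis=0)
    # orthonormalize columns, then scale to exact singular values
    Q, _ = np.linalg.qr(Z)
    s = np.sqrt(np.array(shares))
    return Q[:, : len(shares)] * s


def test_pca_axis_count_from_constructed_spectrum():
    X = _spectrum_data()
    model = pca_reduce(X, 0.95)
    assert model.n_components == 2  # 0.90 + 0.06 >= 0.95
    assert model.retained_variance >= 0.95


def test_pca_threshold_one_keeps_positive_variance_axes():
    X = _spectrum_data((0.7, 0.2, 0.1))
    model = pca_reduce(np.hstack([X, np.zeros((X.shape[0], 2))]), 1.0)
    assert model.n_components == 3  # zero-variance columns dropped


def test_pca_default_threshold_and_validation():
    assert DEFAULT_VARIANCE_THRESHOLD == 0.95
    with pytest.raises(ClassificationError):
        pca_reduce(np.zeros((2, 3)))
    with pytest.raises(ClassificationError):
        pca_reduce(np.random.default_rng(0).normal(size=(5, 3)), 1.5)


def _two_group_data(direction, n=30, noise=0.05, seed=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=noise, size=(2 * n, direction.size))
    X[n:] += direction
    labels = np.repeat(["a", "b"], n)
    return X, labels


def test_lda_axis_count_and_direction():
    # axis-angle error scales like sqrt(dims/df), so the 5-degree check
    # needs a comfortable sample size
    direction = np.zeros(5)
    direction[2] = 1.0
    X, labels = _two_group_data(direction, n=500)
    model = fit_discriminant(X, labels, 0.999)
    assert model.ld_axes.shape[1] == 1  # g - 1
    # leading LD axis mapped back to feature space within 5 degrees of truth
    axis = model.pca_components.T @ model.ld_axes[:, 0]
    cos = abs(axis @ direction) / np.linalg.norm(axis)
    assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0


def test_lda_agrees_with_sklearn_on_separable_data():
    """Independent cross-check: predictions match sklearn LDA when both use
    the same PC space and the groups are cleanly separated."""
    direction = np.array([1.0, -1.0, 0.5, 0.0])
    X, labels = _two_group_data(direction, n=25, noise=0.1, seed=3)
    model = fit_discriminant(X, labels, 1.0)
    scores = project_specimens(model, X)
    centroids = np.stack([model.group_means[g] for g in model.group_means])
    mine = np.array(
        [list(model.group_means)[i] for i in
         np.argmin(((scores[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1)]
    )
    ref = LinearDiscriminantAnalysis().fit(X, labels).predict(X)
    assert (mine == ref).all()


def test_lda_single_member_group_rejected():
    X = np.random.default_rng(0).normal(size=(5, 3))
    labels = np.array(["a", "a", "a", "a", "b"])
    with pytest.raises(ClassificationError, match="single member"):
        fit_discriminant(X, labels, 0.95)


def test_projection_idempotent_on_training_rows():
    direction = np.array([2.0, 0.0, -1.0])
    X, labels = _two_group_data(direction, n=10, seed=5)
    model = fit_discriminant(X, labels, 1.0)
    s1 = project_specimens(model, X)
    s2 = project_specimens(model, X)
    assert np.allclose(s1, s2, atol=1e-12)
    # the grand mean maps to the LD-space origin
    origin = project_specimens(model, model.grand_mean[None, :])
    assert np.allclose(origin, 0.0, atol=1e-9)
    with pytest.raises(ClassificationError, match="variables"):
        project_specimens(model, np.zeros((1, 7)))


def test_crossvalidation_determinism_and_validation():
    direction = np.array([1.0, 0.0, 0.0, 0.0])
    X, labels = _two_group_data(direction, n=8, seed=6)
    r1 = crossvalidated_accuracy(X, labels, n_iter=1, seed=42)
    r2 = crossvalidated_accuracy(X, labels, n_iter=1, seed=42)
    assert r1.per_group_accuracy == r2.per_group_accuracy
    assert r1.fold_scheme == "two-fold, stratified"
    with pytest.raises(ClassificationError, match="too small"):
        crossvalidated_accuracy(X[:9], np.array(["a"] * 8 + ["b"]), n_iter=1, seed=0)
    # min_n silently excludes the undersized group instead
    rep = crossvalidated_accuracy(
        np.vstack([X, X[:1] + 10]), np.concatenate([labels, ["c"]]), n_iter=2, seed=0, min_n=4
    )
    assert set(rep.per_group_accuracy) == {"a", "b"}


def test_choose_k_square_root_rule():
    assert choose_k(107) == 10  # the published calcaneus training size
    assert choose_k(4) == 2
    assert choose_k(1) == 1
    with pytest.raises(ClassificationError):
        choose_k(0)


def test_knn_exact_match_and_oracle():
    rng = np.random.default_rng(9)
    train = rng.normal(size=(40, 3))
    classes = rng.choice(["w", "c", "d"], size=40)
    # a query duplicating a training point at k=1 returns that point's class
    pred = knn_status_predict(train, classes, train[7], k=1)
    assert pred.predicted_class == [classes[7]]

    queries = rng.normal(size=(50, 3))
    k = 5
    pred = knn_status_predict(train, classes, queries, k=k)
    # exhaustive-scan oracle with the same distance-tie and vote-tie rules
    for qi, q in enumerate(queries):
        d = np.sqrt(((train - q) ** 2).sum(axis=1))
        ranked = np.argsort(d, kind="stable")
        kk = k
        while True:
            votes = {}
            for idx in ranked[:kk]:
                votes[classes[idx]] = votes.get(classes[idx], 0) + 1
            top = max(votes.values())
            winners = sorted(c for c, v in votes.items() if v == top)
            if len(winners) == 1 or kk == 1:
                break
            kk -= 1
        assert pred.predicted_class[qi] == winners[0]


def test_knn_tie_broken_by_decrementing_k():
    train = np.array([[0.0], [1.0], [10.0], [11.0]])
    classes = np.array(["a", "a", "b", "b"])
    pred = knn_status_predict(train, classes, np.array([[5.4]]), k=4)
    # 2-2 vote tie at k=4 resolves at k=3 (neighbours a, b, a -> a)
    assert pred.tie_broken == [True]
    assert pred.predicted_class == ["a"]


def test_knn_validation():
    train = np.zeros((3, 2))
    classes = np.array(["a", "b", "a"])
    with pytest.raises(ClassificationError, match="k="):
        knn_status_predict(train, classes, np.zeros((1, 2)), k=4)
    with pytest.raises(ClassificationError, match="empty"):
        knn_status_predict(train, classes, np.zeros((0, 2)), k=1)
    with pytest.raises(ClassificationError, match="2 training classes"):
        knn_status_predict(train, np.repeat("a", 3), np.zeros((1, 2)), k=1)
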