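"""Discriminant classification of shape and form data.

The canonical-variate workflow: reduce the high-dimensional shape/form rows
with PCA (retaining the smallest number of axes whose cumulative explained
variance reaches a threshold, 95% by default), build LDA axes in PC space
(at most g-1, ordered by discriminant eigenvalue), and classify by the
nearest group centroid in LD space under equal priors.  The published
per-group "percentage of correct classification" is the average over
repeated stratified two-fold cross-validation; PCA and LDA are refitted
inside each training fold so no information leaks from the held-out half (a
``global_pca`` switch fits PCA once on all rows for comparability with
workflows that reduce globally).

Ecophenotypic status of archaeological unknowns (free-ranging vs captive vs
domestic, read from calcaneus shape) is predicted with a k-nearest-neighbour
majority vote in LD space, k defaulting to floor(sqrt(N)) of the training
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

__all__ = [
    "DiscriminantModel",
    "ClassificationReport",
    "KnnPrediction",
    "ClassificationError",
    "DEFAULT_VARIANCE_THRESHOLD",
    "pca_reduce",
    "fit_lda",
    "fit_discriminant",
    "project_specimens",
    "crossvalidated_accuracy",
    "choose_k",
    "knn_status_predict",
]

DEFAULT_VARIANCE_THRESHOLD = 0.95

#: Shrinkage weight for the within-group scatter in LDA: Sw is ridged by
#: this fraction of its mean eigenvalue before the generalized eigensolve,
#: stabilizing the whitening when the retained PC count approaches the
#: within-group rank (small two-fold training halves).
LDA_SHRINKAGE = 0.01


class ClassificationError(ValueError):
    pass


@dataclass
class DiscriminantModel:
    """PCA basis plus LDA axes fitted on top of it.

    ``pca_components`` is (m, d) with the grand mean alongside;
    ``ld_axes`` is (m, r) with r <= groups - 1; ``group_means`` maps each
    training group to its centroid in LD space.
    """

    grand_mean: np.ndarray
    pca_components: np.ndarray
    retained_variance: float
    variance_threshold: float
    ld_axes: np.ndarray | None = None
    group_means: dict[str, np.ndarray] | None = None
    training_labels: tuple[str, ...] = ()
    discriminant_eigenvalues: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.pca_components.shape[0]

    def pc_scores(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, float)
        if rows.ndim == 1:
            rows = rows[None, :]
        if rows.shape[1] != self.grand_mean.size:
            raise ClassificationError(
                f"rows have {rows.shape[1]} variables, model expects {self.grand_mean.size}"
            )
        return (rows - self.grand_mean) @ self.pca_components.T


def pca_reduce(
    rows: np.ndarray,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    max_components: int | None = None,
) -> DiscriminantModel:
    """PCA retaining the smallest axis count whose cumulative explained
    variance reaches ``variance_threshold`` (default 95%), optionally capped
    at ``max_components`` (the cap keeps downstream LDA well-posed when the
    threshold alone would retain more axes than the within-group scatter can
    support)."""
    rows = np.asarray(rows, float)
    if rows.shape[0] < 3:
        raise ClassificationError("PCA needs at least 3 rows")
    if not 0 < variance_threshold <= 1:
        raise ClassificationError("variance_threshold must be in (0, 1]")
    pca = PCA(svd_solver="full").fit(rows)
    ratios = pca.explained_variance_ratio_
    positive = int(np.sum(pca.explained_variance_ > max(pca.explained_variance_[0], 1.0) * 1e-12))
    if positive == 0:
        raise ClassificationError("zero total variance")
    if variance_threshold == 1.0:
        m = positive
    else:
        m = int(np.searchsorted(np.cumsum(ratios), variance_threshold) + 1)
        m = min(m, positive)
    if max_components is not None:
        m = max(1, min(m, max_components))
    return DiscriminantModel(
        grand_mean=pca.mean_,
        pca_components=pca.components_[:m],
        retained_variance=float(np.sum(ratios[:m])),
        variance_threshold=variance_threshold,
    )


def fit_lda(model: DiscriminantModel, rows: np.ndarray, labels: np.ndarray) -> DiscriminantModel:
    """Fit LDA axes in the model's PC space.

    Axes maximize the between/within variance ratio (generalized eigenvalue
    problem on the scatter matrices), are ordered by discriminant eigenvalue
    and capped at g-1.  Raises if any group has fewer than 2 rows or the
    within-group covariance is singular in PC space.
    """
    labels = np.asarray(labels)
    scores = model.pc_scores(rows)
    uniq, inv = np.unique(labels, return_inverse=True)
    g = uniq.size
    if g < 2:
        raise ClassificationError("LDA needs at least 2 groups")
    counts = np.bincount(inv)
    if np.any(counts < 2):
        small = uniq[counts < 2]
        raise ClassificationError(f"groups with a single member: {', '.join(map(str, small))}")
    n, m = scores.shape

    grand = scores.mean(axis=0)
    Sw = np.zeros((m, m))
    Sb = np.zeros((m, m))
    for gi in range(g):
        sub = scores[inv == gi]
        mu = sub.mean(axis=0)
        d = sub - mu
        Sw += d.T @ d
        Sb += counts[gi] * np.outer(mu - grand, mu - grand)
    trace = float(np.trace(Sw))
    if trace <= 0:
        raise ClassificationError(
            "singular within-group covariance in PC space; reduce the PCA dimension"
        )
    Sw_reg = Sw + LDA_SHRINKAGE * (trace / m) * np.eye(m)
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise ClassificationError(
            "singular within-group covariance in PC space; reduce the PCA dimension"
        ) from exc
    order = np.argsort(evals)[::-1][: g - 1]
    ld_axes = evecs[:, order]
    evals = evals[order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(ld_axes.shape[1]):
        i = int(np.argmax(np.abs(ld_axes[:, j])))
        if ld_axes[i, j] < 0:
            ld_axes[:, j] = -ld_axes[:, j]

    ld_scores = scores @ ld_axes
    group_means = {str(uniq[gi]): ld_scores[inv == gi].mean(axis=0) for gi in range(g)}
    model.ld_axes = ld_axes
    model.group_means = group_means
    model.training_labels = tuple(str(u) for u in uniq)
    model.discriminant_eigenvalues = evals
    return model


def fit_discriminant(
    rows: np.ndarray,
    labels: np.ndarray,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> DiscriminantModel:
    """PCA reduction followed by LDA on the retained scores.

    The PC count is capped at n - g - 1 so the within-group scatter stays
    invertible.
    """
    labels = np.asarray(labels)
    g = np.unique(labels).size
    cap = max(1, len(labels) - g - 1)
    model = pca_reduce(rows, variance_threshold, max_components=cap)
    return fit_lda(model, rows, labels)


def project_specimens(model: DiscriminantModel, rows: np.ndarray) -> np.ndarray:
    """LD scores of (possibly unknown) specimens: center on the grand mean,
    project through the PCA basis, then through the LD axes."""
    if model.ld_axes is None:
        raise ClassificationError("model has no LDA axes; call fit_lda first")
    return model.pc_scores(rows) @ model.ld_axes


def _classify_nearest_mean(model: DiscriminantModel, rows: np.ndarray) -> np.ndarray:
    scores = project_specimens(model, rows)
    labels = list(model.group_means)
    centroids = np.stack([model.group_means[g] for g in labels])
    nearest = np.argmin(cdist(scores, centroids), axis=1)
    return np.array([labels[i] for i in nearest])


@dataclass(frozen=True)
class ClassificationReport:
    per_group_accuracy: dict[str, float]
    overall_accuracy: float
    n_iterations: int
    fold_scheme: str = "two-fold, stratified"

    def to_dict(self) -> dict:
        return {
            "per_group_accuracy": self.per_group_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "n_iterations": self.n_iterations,
            "fold_scheme": self.fold_scheme,
        }


def crossvalidated_accuracy(
    rows: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 200,
    seed: int | None = None,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    global_pca: bool = False,
    min_n: int | None = None,
) -> ClassificationReport:
    """Repeated stratified two-fold cross-validated classification accuracy.

    Each iteration splits every group at random into two halves (a group's
    odd member alternates between folds across groups and iterations), fits
    PCA+LDA on one fold and classifies the other by nearest group centroid in
    LD space, both ways round.  Percentages are averaged over folds and
    iterations.  ``min_n`` (if given) silently excludes groups smaller than
    it; otherwise any group below 2 members is an error.
    """
    rows = np.asarray(rows, float)
    labels = np.asarray(labels).astype(str)
    if min_n is not None:
        uniq, counts = np.unique(labels, return_counts=True)
        keep_groups = set(uniq[counts >= min_n])
        mask = np.array([l in keep_groups for l in labels])
        rows, labels = rows[mask], labels[mask]
    uniq, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    if uniq.size < 2:
        raise ClassificationError("need at least 2 groups for cross-validation")
    if np.any(counts < 2):
        small = uniq[counts < 2]
        raise ClassificationError(
            f"groups too small for a two-fold split: {', '.join(map(str, small))}"
        )
    if n_iter < 1:
        raise ClassificationError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)

    group_idx = [np.flatnonzero(inv == gi) for gi in range(uniq.size)]
    correct = {str(g): 0 for g in uniq}
    tried = {str(g): 0 for g in uniq}
    toggle = 0

    global_model = pca_reduce(rows, variance_threshold) if global_pca else None

    for _ in range(n_iter):
        fold_a: list[np.ndarray] = []
        fold_b: list[np.ndarray] = []
        for idx in group_idx:
            perm = rng.permutation(idx)
            half = idx.size // 2
            if idx.size % 2 == 1:
                half += toggle  # odd member alternates between folds
                toggle = 1 - toggle
            fold_a.append(perm[:half])
            fold_b.append(perm[half:])
        a = np.concatenate(fold_a)
        b = np.concatenate(fold_b)
        for train, test in ((a, b), (b, a)):
            if global_model is not None:
                cap = max(1, train.size - uniq.size - 1)
                model = DiscriminantModel(
                    grand_mean=global_model.grand_mean,
                    pca_components=global_model.pca_components[:cap],
                    retained_variance=global_model.retained_variance,
                    variance_threshold=global_model.variance_threshold,
                )
                model = fit_lda(model, rows[train], labels[train])
            else:
                model = fit_discriminant(rows[train], labels[train], variance_threshold)
            predicted = _classify_nearest_mean(model, rows[test])
            for lab, pred in zip(labels[test], predicted):
                tried[lab] += 1
                if lab == pred:
                    correct[lab] += 1

    per_group = {g: 100.0 * correct[g] / tried[g] for g in correct}
    overall = 100.0 * sum(correct.values()) / sum(tried.values())
    return ClassificationReport(
        per_group_accuracy=per_group,
        overall_accuracy=overall,
        n_iterations=n_iter,
    )


def choose_k(n_training: int) -> int:
    """Conventional neighbour count for k-NN: floor(sqrt(N)), at least 1."""
    if n_training < 1:
        raise ClassificationError("need at least one training specimen")
    return max(1, int(np.floor(np.sqrt(n_training))))


@dataclass(frozen=True)
class KnnPrediction:
    predicted_class: list[str]
    k: int
    neighbour_indices: list[np.ndarray] = field(repr=False, default=None)
    neighbour_distances: list[np.ndarray] = field(repr=False, default=None)
    tie_broken: list[bool] = None


def knn_status_predict(
    training_scores: np.ndarray,
    training_classes: np.ndarray,
    queries: np.ndarray,
    k: int | None = None,
    seed: int | None = None,
) -> KnnPrediction:
    """k-nearest-neighbour majority vote in (LD) score space.

    Euclidean neighbours; exact distance ties rank by lowest training index.
    A tied vote is broken by decrementing k until it resolves (k = 1 cannot
    tie) and flagged per query.  ``k`` defaults to :func:`choose_k` of the
    training size.  ``seed`` is accepted for interface symmetry; the rule is
    deterministic and never consumes randomness.
    """
    X = np.asarray(training_scores, float)
    classes = np.asarray(training_classes).astype(str)
    Q = np.asarray(queries, float)
    if Q.ndim == 1:
        Q = Q[None, :]
    if Q.shape[0] == 0:
        raise ClassificationError("empty query set")
    if np.unique(classes).size < 2:
        raise ClassificationError("need at least 2 training classes")
    if k is None:
        k = choose_k(X.shape[0])
    if not 1 <= k <= X.shape[0]:
        raise ClassificationError(f"k={k} out of range for {X.shape[0]} training specimens")

    dists = cdist(Q, X)
    order = np.argsort(dists, axis=1, kind="stable")  # stable => lowest index on ties
    predicted: list[str] = []
    tie_broken: list[bool] = []
    nn_idx: list[np.ndarray] = []
    nn_dist: list[np.ndarray] = []
    for qi in range(Q.shape[0]):
        ranked = order[qi]
        nn_idx.append(ranked[:k].copy())
        nn_dist.append(dists[qi, ranked[:k]].copy())
        kk = k
        broke = False
        while True:
            votes: dict[str, int] = {}
            for idx in ranked[:kk]:
                votes[classes[idx]] = votes.get(classes[idx], 0) + 1
            top = max(votes.values())
            winners = sorted(c for c, v in votes.items() if v == top)
            if len(winners) == 1 or kk == 1:
                predicted.append(winners[0])
                tie_broken.append(broke)
                break
            kk -= 1
            broke = True
    return KnnPrediction(
        predicted_class=predicted,
        k=k,
        neighbour_indices=nn_idx,
        neighbour_distances=nn_dist,
        tie_broken=tie_broken,
    )
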