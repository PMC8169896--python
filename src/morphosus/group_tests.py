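"""Permutation tests for size and shape differences between populations.

Shape data are high-dimensional (variables far outnumber specimens), so
group tests use Goodall-type statistics: sums of squared Procrustes/Euclidean
deviations decomposed by term, with an F ratio of mean squares and
significance from permutations rather than from Wilks'-lambda-style
parametric MANOVA, which is undefined when the within-group covariance is
rank deficient.  Permutation p-values are (b + 1)/(n_perm + 1) with b the
count of permuted statistics >= the observed one, hence always in (0, 1].

Four tests are provided:

* :func:`size_group_anova` — one-way ANOVA of log centroid size over groups
  (label permutation), with per-group box-plot summary statistics.
* :func:`allometry_regression` — multivariate regression of shape on log
  centroid size; R^2 = SS_model / SS_total over all coordinates (size
  permutation).
* :func:`common_slope_test` — MANCOVA group x size interaction, comparing
  common-slope against group-specific-slope models by permutation of
  reduced-model residuals (Freedman–Lane).
* :func:`shape_manova` — Goodall F for the group term on shape or form rows.

With a single response column the Goodall F reduces exactly to the classical
one-way ANOVA F.  Sums of squares follow the sequential (Type I) ordering
size -> group -> interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnovaResult",
    "AllometryResult",
    "ManovaResult",
    "GroupTestError",
    "size_group_anova",
    "allometry_regression",
    "common_slope_test",
    "shape_manova",
    "group_boxplot_stats",
]

DEFAULT_N_PERM = 999


class GroupTestError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    df_between: int
    df_within: int
    F: float
    p: float
    n_permutations: int
    group_summary: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "df_between": self.df_between,
            "df_within": self.df_within,
            "F": self.F,
            "p": self.p,
            "n_permutations": self.n_permutations,
        }


@dataclass(frozen=True)
class AllometryResult:
    Rsq: float
    F: float
    p: float
    slope_vector: np.ndarray = field(repr=False, default=None)
    n_permutations: int = 0

    def to_dict(self) -> dict:
        return {"Rsq": self.Rsq, "F": self.F, "p": self.p, "n_permutations": self.n_permutations}


@dataclass(frozen=True)
class ManovaResult:
    df_between: int
    df_within: int
    F: float
    p: float
    term: str
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "F": self.F,
            "p": self.p,
            "n_permutations": self.n_permutations,
        }


def _perm_pvalue(observed: float, permuted: np.ndarray) -> float:
    b = int(np.sum(permuted >= observed))
    return (b + 1) / (permuted.size + 1)


def _check_groups(labels: np.ndarray, min_size: int) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    if uniq.size < 2:
        raise GroupTestError("need at least 2 groups")
    small = uniq[counts < min_size]
    if small.size:
        raise GroupTestError(
            f"groups below the minimum of {min_size} members: {', '.join(map(str, small))}"
        )
    return uniq, inv


def _group_ss(X: np.ndarray, onehot: np.ndarray, counts: np.ndarray) -> float:
    """Between-group SS of (already grand-centered) rows X under one-hot labels."""
    sums = onehot.T @ X  # (g, q)
    return float(np.sum(sums**2 / counts[:, None]))


def group_boxplot_stats(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Tukey box-plot summaries per group: median, quartiles, whiskers (most
    extreme values within 1.5 IQR of the box) and outlier count."""
    rows = []
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    for g in dict.fromkeys(labels.tolist()):
        v = values[labels == g]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo) & (v <= hi)]
        rows.append(
            {
                "group": str(g),
                "n": int(v.size),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "n_outliers": int(v.size - inside.size),
            }
        )
    return pd.DataFrame(rows)


def size_group_anova(
    log_sizes: np.ndarray,
    labels: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> AnovaResult:
    """One-way ANOVA of (log) size over groups with permutation significance.

    The classical F statistic is computed for the observed labels and for
    ``n_perm`` random relabellings; every group needs >= 2 members and the
    sizes must not be constant.
    """
    y = np.asarray(log_sizes, float)
    labels = np.asarray(labels)
    uniq, inv = _check_groups(labels, 2)
    if np.ptp(y) == 0:
        raise GroupTestError("constant sizes: ANOVA undefined")
    res = shape_manova(y[:, None], labels, n_perm=n_perm, seed=seed)
    return AnovaResult(
        df_between=res.df_between,
        df_within=res.df_within,
        F=res.F,
        p=res.p,
        n_permutations=n_perm,
        group_summary=group_boxplot_stats(y, labels),
    )


def shape_manova(
    rows: np.ndarray,
    labels: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> ManovaResult:
    """Goodall-type F for group differences in shape (or form) rows.

    F = (SS_between / (g-1)) / (SS_within / (n-g)) over Euclidean sums of
    squares pooled across all coordinates; the p-value permutes group labels.
    """
    X = np.asarray(rows, float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq, inv = _check_groups(labels, 2)
    n, g = X.shape[0], uniq.size
    if n - g < 1:
        raise GroupTestError("no within-group degrees of freedom")
    rng = np.random.default_rng(seed)

    Xc = X - X.mean(axis=0)
    ss_total = float(np.sum(Xc**2))
    if ss_total <= 0:
        raise GroupTestError("zero total variance")
    onehot = np.eye(g)[inv]
    counts = np.bincount(inv).astype(float)

    def f_stat(ss_between: float) -> float:
        ss_within = ss_total - ss_between
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    observed = f_stat(_group_ss(Xc, onehot, counts))

    # permuting labels == permuting rows of Xc against fixed labels
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    sums = np.einsum("ng,bnq->bgq", onehot, Xc[perms])  # (B, g, q)
    ssb = np.sum(sums**2 / counts[None, :, None], axis=(1, 2))
    permuted = (ssb / (g - 1)) / ((ss_total - ssb) / (n - g))

    return ManovaResult(
        df_between=g - 1,
        df_within=n - g,
        F=observed,
        p=_perm_pvalue(observed, permuted),
        term="group",
        n_permutations=n_perm,
    )


def allometry_regression(
    shape_rows: np.ndarray,
    log_sizes: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> AllometryResult:
    """Procrustes ANOVA of allometry: multivariate regression of shape
    coordinates on log centroid size.

    R^2 = SS_model / SS_total pooled over all coordinates; F uses 1 and n-2
    degrees of freedom; significance permutes the size vector against the
    shape rows.  Requires n >= 3 and non-constant sizes.
    """
    X = np.asarray(shape_rows, float)
    x = np.asarray(log_sizes, float)
    n = X.shape[0]
    if n < 3:
        raise GroupTestError("allometry regression needs at least 3 specimens")
    if x.shape != (n,):
        raise GroupTestError("log_sizes must match the number of shape rows")
    if np.ptp(x) == 0:
        raise GroupTestError("constant sizes: allometry undefined")
    rng = np.random.default_rng(seed)

    Xc = X - X.mean(axis=0)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    ss_total = float(np.sum(Xc**2))
    if ss_total <= 0:
        raise GroupTestError("zero shape variance")

    beta = (xc @ Xc) / sxx  # (q,) slope per unit log size
    ss_model = float(np.sum(beta**2) * sxx)
    ss_res = ss_total - ss_model
    rsq = ss_model / ss_total
    F = (ss_model / 1.0) / (ss_res / (n - 2))

    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    xp = xc[perms]  # (B, n)
    ssm = np.sum((xp @ Xc) ** 2, axis=1) / sxx
    permuted = ssm / ((ss_total - ssm) / (n - 2))

    return AllometryResult(
        Rsq=rsq,
        F=F,
        p=_perm_pvalue(F, permuted),
        slope_vector=beta,
        n_permutations=n_perm,
    )


def _hat(design: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of the design (via pinv for
    rank safety)."""
    return design @ np.linalg.pinv(design)


def common_slope_test(
    shape_rows: np.ndarray,
    log_sizes: np.ndarray,
    labels: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> ManovaResult:
    """MANCOVA test of the group x log-size interaction.

    Compares the common-slope model (group intercepts + one shared allometric
    slope) against group-specific slopes; the Goodall-type F pools the extra
    explained SS over all coordinates.  A non-significant interaction supports
    shared allometry across groups.  Significance is by Freedman–Lane
    permutation of the reduced (common-slope) model residuals.  Every group
    needs >= 3 members and within-group size variance.
    """
    X = np.asarray(shape_rows, float)
    x = np.asarray(log_sizes, float)
    labels = np.asarray(labels)
    uniq, inv = _check_groups(labels, 3)
    n, g = X.shape[0], uniq.size
    for gi, glab in enumerate(uniq):
        if np.ptp(x[inv == gi]) == 0:
            raise GroupTestError(f"group {glab!r} has zero size variance")
    rng = np.random.default_rng(seed)

    onehot = np.eye(g)[inv]
    xc = x - x.mean()
    reduced = np.column_stack([onehot, xc])  # group intercepts + common slope
    full = np.column_stack([onehot, onehot * xc[:, None]])  # group-specific slopes

    df_int = g - 1
    df_resid = n - 2 * g
    if df_resid < 1:
        raise GroupTestError("no residual degrees of freedom for group-specific slopes")

    H_red = _hat(reduced)
    H_full = _hat(full)
    In = np.eye(n)

    def f_stat(Y: np.ndarray) -> float:
        rss_red = float(np.sum(((In - H_red) @ Y) ** 2))
        rss_full = float(np.sum(((In - H_full) @ Y) ** 2))
        return ((rss_red - rss_full) / df_int) / (rss_full / df_resid)

    observed = f_stat(X)

    # Freedman–Lane: Y* = fitted_red + permuted residuals; fitted_red is
    # annihilated by both residual makers, so only residuals matter.
    E = (In - H_red) @ X
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Ep = E[perms]  # (B, n, q)
    R_red = Ep - np.einsum("nm,bmq->bnq", H_red, Ep)
    R_full = Ep - np.einsum("nm,bmq->bnq", H_full, Ep)
    rss_red = np.sum(R_red**2, axis=(1, 2))
    rss_full = np.sum(R_full**2, axis=(1, 2))
    permuted = ((rss_red - rss_full) / df_int) / (rss_full / df_resid)

    return ManovaResult(
        df_between=df_int,
        df_within=df_resid,
        F=observed,
        p=_perm_pvalue(observed, permuted),
        term="group_x_size",
        n_permutations=n_perm,
    )
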