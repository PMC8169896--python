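"""Population-structure inference: size mixtures and phenotypic trees.

Whether an insular sample represents one population or several is read from
the distribution of log centroid size: univariate Gaussian finite mixtures
are fitted by EM for each candidate component count under an equal-variance
and a free-variance family, and the model minimizing BIC
(-2 log L + params ln n) is selected.  Phenotypic affinity between
population samples is summarized by an unrooted neighbour-joining tree on
the Euclidean distances between group mean forms (mean shapes with the
``shape`` metric), serialized as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import logsumexp
from scipy.stats import norm

from .classify import pca_reduce

__all__ = [
    "MixtureFit",
    "PhenotypicTree",
    "PopulationError",
    "fit_size_mixture",
    "mixture_density_curve",
    "mean_form_distance_matrix",
    "neighbor_joining",
    "tree_to_newick",
    "pca_of_group_means",
]

MIN_MIXTURE_N = 10
DEFAULT_MAX_G = 5
_N_INIT = 10  # seeded restarts per (G, family)
_EM_TOL = 1e-8


class PopulationError(ValueError):
    pass


@dataclass(frozen=True)
class MixtureFit:
    """BIC-selected univariate Gaussian mixture of log sizes; components are
    relabelled in increasing order of mean so output is deterministic."""

    G: int
    family: str  # "equal" or "free" variance
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic_by_model: pd.DataFrame = field(repr=False, default=None)
    assignments: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "G": self.G,
            "family": self.family,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "bic_table": self.bic_by_model.to_dict(orient="records"),
        }


def _em_1d(
    y: np.ndarray,
    G: int,
    equal_variance: bool,
    sd_floor: float,
    rng: np.random.Generator,
    n_init: int = _N_INIT,
    tol: float = _EM_TOL,
    max_iter: int = 500,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Best-of-``n_init`` EM fit of a univariate G-component Gaussian mixture.

    All restarts run in parallel as one vectorized EM; each starts from a
    k-means-style partition (points assigned to G randomly chosen distinct
    observations).  Returns (loglik, weights, means, sds, converged) of the
    best restart.  The variance floor guards against components collapsing
    onto single points.
    """
    n = y.size
    R = n_init
    var_floor = sd_floor**2

    if G == 1:  # closed form, no EM needed
        mu = float(y.mean())
        var = max(float(y.var()), var_floor)
        ll = float(np.sum(norm.logpdf(y, mu, np.sqrt(var))))
        return ll, np.array([1.0]), np.array([mu]), np.array([np.sqrt(var)]), True

    # k-means-style seeded initial partitions
    means = np.empty((R, G))
    variances = np.empty((R, G))
    weights = np.empty((R, G))
    for r in range(R):
        centers = np.sort(rng.choice(y, size=G, replace=False))
        assign = np.argmin(np.abs(y[:, None] - centers[None, :]), axis=1)
        for g in range(G):
            sel = y[assign == g]
            if sel.size == 0:
                means[r, g] = centers[g]
                variances[r, g] = y.var()
                weights[r, g] = 1.0 / n
            else:
                means[r, g] = sel.mean()
                variances[r, g] = max(sel.var(), var_floor) if sel.size > 1 else y.var()
                weights[r, g] = sel.size / n
        weights[r] /= weights[r].sum()
        if equal_variance:
            variances[r] = variances[r].mean()

    yy = y[None, :, None]

    def em_iterations(w, mu, var, iters, tol_):
        """Vectorized EM on a (R', G) parameter block; returns loglik and a
        converged flag per restart."""
        prev = np.full(w.shape[0], -np.inf)
        ll_ = prev.copy()
        conv = np.zeros(w.shape[0], bool)
        for _ in range(iters):
            logp = (
                -0.5 * np.log(2 * np.pi * var[:, None, :])
                - 0.5 * (yy - mu[:, None, :]) ** 2 / var[:, None, :]
                + np.log(w[:, None, :])
            )
            norm_ = logsumexp(logp, axis=2)
            ll_ = norm_.sum(axis=1)
            resp = np.exp(logp - norm_[:, :, None])
            nk = np.maximum(resp.sum(axis=1), 1e-12)
            w[:] = nk / n
            mu[:] = np.einsum("rng,n->rg", resp, y) / nk
            sq = (yy - mu[:, None, :]) ** 2
            newvar = np.einsum("rng,rng->rg", resp, sq) / nk
            if equal_variance:
                pooled = np.einsum("rng,rng->r", resp, sq) / n
                newvar = np.repeat(pooled[:, None], w.shape[1], axis=1)
            var[:] = np.maximum(newvar, var_floor)
            conv = np.abs(ll_ - prev) < tol_
            prev = ll_
            if conv.all():
                break
        return ll_, conv

    def valid_mask(w, var):
        # a component collapsed onto the variance floor or carrying fewer
        # than two effective members is a likelihood spike, not a population
        return np.all(var > (2.0 * sd_floor) ** 2, axis=1) & np.all(w * n >= 2.0, axis=1)

    # stage 1: short burn-in on every seeded restart
    burn = 40
    ll, conv = em_iterations(weights, means, variances, burn, tol)
    valid = valid_mask(weights, variances)
    pool = np.flatnonzero(valid) if valid.any() else np.arange(R)
    best = int(pool[np.argmax(ll[pool])])
    # stage 2: refine the winning restart to full tolerance
    w = weights[best : best + 1].copy()
    mu = means[best : best + 1].copy()
    var = variances[best : best + 1].copy()
    ll2, conv2 = em_iterations(w, mu, var, max_iter - burn, tol)
    if valid_mask(w, var)[0]:
        final = (float(ll2[0]), w[0], mu[0], np.sqrt(var[0]), bool(conv2[0]))
    else:  # refinement drifted into a spike; report the burn-in solution
        final = (float(ll[best]), weights[best], means[best], np.sqrt(variances[best]), False)
    return final


def fit_size_mixture(
    log_sizes: np.ndarray, max_G: int = DEFAULT_MAX_G, seed: int | None = None
) -> MixtureFit:
    """Fit Gaussian mixtures with 1..max_G components under equal- and
    free-variance families; select the (G, family) minimizing
    BIC = -2 loglik + params ln(n).

    Each candidate runs EM from 10 seeded k-means-style initial partitions
    with a standard-deviation floor of 1e-6 x data range against singular
    spikes.  Requires n >= 10 and non-degenerate input; deterministic for a
    fixed seed.
    """
    y = np.asarray(log_sizes, float).reshape(-1)
    n = y.size
    if n < MIN_MIXTURE_N:
        raise PopulationError(f"mixture fitting needs n >= {MIN_MIXTURE_N}, got {n}")
    if np.ptp(y) == 0:
        raise PopulationError("degenerate (zero-variance) size vector")
    if max_G < 1:
        raise PopulationError("max_G must be >= 1")
    sd_floor = 1e-6 * np.ptp(y)
    rng = np.random.default_rng(seed)

    rows = []
    best = None
    for G in range(1, max_G + 1):
        for family in ("equal", "free"):
            ll, w, mu, sd, conv = _em_1d(y, G, family == "equal", sd_floor, rng)
            params = (G - 1) + G + (1 if family == "equal" else G)
            bic = -2.0 * ll + params * np.log(n)
            rows.append({"G": G, "family": family, "bic": float(bic), "converged": conv})
            if best is None or bic < best[0]:
                best = (bic, G, family, ll, w, mu, sd)

    _, G, family, loglik, weights, means, sds = best
    order = np.argsort(means)
    means = means[order]
    sds = sds[order]
    weights = weights[order]
    weights = weights / weights.sum()
    # hard assignments by maximum posterior under the selected model
    logp = norm.logpdf(y[:, None], means[None, :], sds[None, :]) + np.log(weights[None, :])
    assignments = np.argmax(logp, axis=1)

    return MixtureFit(
        G=G,
        family=family,
        weights=weights,
        means=means,
        sds=sds,
        loglik=loglik,
        bic_by_model=pd.DataFrame(rows),
        assignments=assignments,
    )


def mixture_density_curve(fit: MixtureFit, grid: np.ndarray) -> np.ndarray:
    """Mixture density sum(w_g N(x; mu_g, sd_g)) on a grid of points."""
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise PopulationError("empty density grid")
    return np.sum(
        fit.weights[:, None] * norm.pdf(grid[None, :], fit.means[:, None], fit.sds[:, None]),
        axis=0,
    )


def mean_form_distance_matrix(group_means: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Pairwise Euclidean distances between group mean vectors; returns the
    symmetric matrix and the label order."""
    labels = list(group_means)
    if len(labels) < 2:
        raise PopulationError("need at least 2 groups for a distance matrix")
    vecs = [np.asarray(group_means[g], float) for g in labels]
    lengths = {v.size for v in vecs}
    if len(lengths) != 1:
        raise PopulationError(f"mean vectors differ in length: {sorted(lengths)}")
    return squareform(pdist(np.stack(vecs))), labels


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    label: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)  # (child, edge length)


@dataclass(frozen=True)
class PhenotypicTree:
    distance_matrix: np.ndarray
    leaf_labels: tuple[str, ...]
    newick: str
    #: exact leaf-to-leaf path lengths in the fitted tree (same label order);
    #: equals the input matrix whenever it is additive
    patristic: np.ndarray = None


def _patristic_from_root(root: _Node, labels: list[str]) -> np.ndarray:
    """Exact pairwise path lengths between leaves of the built tree."""
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))

    def leaf_depths(node: _Node, depth: float) -> dict[int, float]:
        if not node.children:
            return {index[node.label]: depth}
        out: dict[int, float] = {}
        for ch, ln in node.children:
            out.update(leaf_depths(ch, depth + ln))
        return out

    def collect(node: _Node) -> None:
        if not node.children:
            return
        subs = [leaf_depths(ch, ln) for ch, ln in node.children]
        for ch, _ in node.children:
            collect(ch)
        for si in range(len(subs)):
            for sj in range(si + 1, len(subs)):
                for a, da in subs[si].items():
                    for b, db in subs[sj].items():
                        D[a, b] = D[b, a] = da + db

    collect(root)
    return D


def _format_len(x: float) -> str:
    return f"{x:.6f}"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_newick(node: _Node) -> str:
    if not node.children:
        return _quote(node.label or "")
    inner = ",".join(f"{_node_newick(ch)}:{_format_len(ln)}" for ch, ln in node.children)
    return f"({inner})"


def neighbor_joining(distances: np.ndarray, labels: list[str]) -> PhenotypicTree:
    """Saitou–Nei neighbour joining with the Studier–Keppler Q criterion.

    Input must be a symmetric, zero-diagonal, nonnegative distance matrix;
    additive matrices are recovered exactly (topology and branch lengths).
    Negative estimated branch lengths are reported as computed.  The result
    is an unrooted tree serialized as Newick (internal trifurcation at the
    last join; a 2-taxon input yields a single edge of the full distance).
    """
    D = np.asarray(distances, float)
    labels = [str(l) for l in labels]
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise PopulationError("distance matrix / label length mismatch")
    if n < 2:
        raise PopulationError("need at least 2 taxa")
    if np.any(np.isnan(D)):
        raise PopulationError("NaN in distance matrix")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise PopulationError("distance matrix is not symmetric")
    if np.any(np.diag(D) != 0):
        raise PopulationError("distance matrix has a nonzero diagonal")
    if np.any(D < 0):
        raise PopulationError("negative distances")

    nodes: list[_Node] = [_Node(label=l) for l in labels]
    D = D.copy()
    original = np.asarray(distances, float).copy()

    if n == 2:
        root = _Node(children=[(nodes[0], 0.0), (nodes[1], float(D[0, 1]))])
        # serialize as (A:d1,B:d2); with d1 + d2 = d12, split evenly
        half = float(D[0, 1]) / 2.0
        root = _Node(children=[(nodes[0], half), (nodes[1], half)])
        newick = _node_newick(root) + ";"
        return PhenotypicTree(original, tuple(labels), newick, _patristic_from_root(root, labels))

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(Q), Q.shape)  # first minimum: lowest indices
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        d_ij = sub[i_s, j_s]
        li = 0.5 * d_ij + (r[i_s] - r[j_s]) / (2 * (m - 2))
        lj = d_ij - li
        new = _Node(children=[(nodes[i], float(li)), (nodes[j], float(lj))])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for a_s, a in enumerate(active):
            if a in (i, j):
                continue
            new_row[a] = 0.5 * (D[i, a] + D[j, a] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # terminal join: star over the last 3 nodes (closed-form branch lengths)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = _Node(children=[(nodes[a], float(la)), (nodes[b], float(lb)), (nodes[c], float(lc))])
    newick = _node_newick(root) + ";"
    return PhenotypicTree(original, tuple(labels), newick, _patristic_from_root(root, labels))


def tree_to_newick(tree: PhenotypicTree) -> str:
    """Newick serialization (branch lengths at 6 decimals; labels containing
    spaces or Newick metacharacters are quoted)."""
    return tree.newick


def pca_of_group_means(group_means: dict[str, np.ndarray]) -> pd.DataFrame:
    """Principal-component ordination of the group mean vectors.

    Needs >= 3 groups.  Subsetting the groups and refitting recomputes the
    ordination; it is not a subset of the full-scores table.
    """
    labels = list(group_means)
    if len(labels) < 3:
        raise PopulationError("PCA of group means needs at least 3 groups")
    M = np.stack([np.asarray(group_means[g], float) for g in labels])
    model = pca_reduce(M, variance_threshold=1.0)
    scores = model.pc_scores(M)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=labels, columns=cols)
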