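"""Size mixtures, distance matrices, neighbour joining and Newick output."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from morphosus.population import (
    PopulationError,
    fit_size_mixture,
    mean_form_distance_matrix,
    mixture_density_curve,
    neighbor_joining,
    pca_of_group_means,
    tree_to_newick,
)
from morphosus.synthetic import SizeModel, simulate_size_mixture


def test_mixture_recovers_two_components_and_matches_sklearn():
    y1, _ = simulate_size_mixture(SizeModel((1.0,), (0.0,), (0.05,)), 100, seed=21)
    y2, _ = simulate_size_mixture(SizeModel((1.0,), (1.0,), (0.05,)), 100, seed=22)
    y = np.concatenate([y1, y2])
    fit = fit_size_mixture(y, max_G=5, seed=0)
    assert fit.G == 2
    assert fit.means == pytest.approx([0.0, 1.0], abs=0.02)
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert (fit.sds > 0).all()
    # independent EM implementation agrees on the component means
    ref = GaussianMixture(2, n_init=5, random_state=0).fit(y[:, None])
    assert np.sort(ref.means_.ravel()) == pytest.approx(fit.means, abs=0.01)
    # hard assignments split at the midpoint
    assert (fit.assignments[:100] == 0).mean() > 0.98
    assert (fit.assignments[100:] == 1).mean() > 0.98


def test_mixture_selects_single_component_on_unimodal_data():
    y, _ = simulate_size_mixture(SizeModel((1.0,), (3.0,), (0.05,)), 200, seed=33)
    fit = fit_size_mixture(y, max_G=5, seed=1)
    assert fit.G == 1
    assert fit.means[0] == pytest.approx(3.0, abs=0.02)


def test_mixture_validation():
    with pytest.raises(PopulationError, match="n >= 10"):
        fit_size_mixture(np.arange(5.0), seed=0)
    with pytest.raises(PopulationError, match="degenerate"):
        fit_size_mixture(np.full(20, 2.0), seed=0)


def test_density_curve_closed_form_and_integral():
    fit = fit_size_mixture(np.random.default_rng(1).normal(size=100), max_G=1, seed=0)
    # compare against the fitted component's exact normal density at its mean
    peak = mixture_density_curve(fit, np.array([fit.means[0]]))[0]
    assert peak == pytest.approx(1.0 / (fit.sds[0] * np.sqrt(2 * np.pi)), rel=1e-9)
    grid = np.linspace(fit.means[0] - 8 * fit.sds[0], fit.means[0] + 8 * fit.sds[0], 2001)
    dens = mixture_density_curve(fit, grid)
    assert (dens >= 0).all()
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(PopulationError, match="empty"):
        mixture_density_curve(fit, np.array([]))


def test_distance_matrix_cases_and_oracle():
    D, labels = mean_form_distance_matrix({"a": np.zeros(2), "b": np.array([3.0, 4.0])})
    assert D[0, 1] == pytest.approx(5.0)
    same, _ = mean_form_distance_matrix({"a": np.ones(4), "b": np.ones(4)})
    assert same[0, 1] == 0.0
    rng = np.random.default_rng(5)
    means = {f"g{i}": rng.normal(size=6) for i in range(4)}
    D, labels = mean_form_distance_matrix(means)
    for i, j in itertools.combinations(range(4), 2):  # double-loop oracle
        expected = np.sqrt(np.sum((means[labels[i]] - means[labels[j]]) ** 2))
        assert D[i, j] == pytest.approx(expected, abs=1e-12)
        assert D[j, i] == D[i, j]
    with pytest.raises(PopulationError, match="length"):
        mean_form_distance_matrix({"a": np.zeros(2), "b": np.zeros(3)})


def _random_additive_matrix(rng, n):
    """Distance matrix of a random binary tree with uniform branch lengths."""
    children: dict[int, list[tuple[int, float]]] = {}
    nxt, active = n, list(range(n))
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[i], active[j]
        children[nxt] = [(a, float(rng.uniform(0.5, 5))), (b, float(rng.uniform(0.5, 5)))]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    D = np.zeros((n, n))

    def depths(node, dist):
        if node < n:
            return {node: dist}
        out = {}
        for ch, ln in children[node]:
            out.update(depths(ch, dist + ln))
        return out

    def collect(node):
        if node < n:
            return
        subs = [depths(ch, ln) for ch, ln in children[node]]
        for ch, _ in children[node]:
            collect(ch)
        for s1, s2 in itertools.combinations(subs, 2):
            for a, da in s1.items():
                for b, db in s2.items():
                    D[a, b] = D[b, a] = da + db

    collect(active[0])
    return D


def test_nj_recovers_random_additive_trees_exactly():
    rng = np.random.default_rng(14)
    for _ in range(15):
        n = int(rng.integers(4, 9))
        D = _random_additive_matrix(rng, n)
        tree = neighbor_joining(D, [f"T{i}" for i in range(n)])
        assert np.max(np.abs(tree.patristic - D)) < 1e-9


def test_nj_small_cases_closed_form():
    D3 = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
    tree = neighbor_joining(D3, ["a", "b", "c"])
    # star branches: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
    assert np.max(np.abs(tree.patristic - D3)) < 1e-12
    assert tree.newick.count(",") == 2

    two = neighbor_joining(np.array([[0.0, 2.5], [2.5, 0]]), ["A", "B"])
    assert two.patristic[0, 1] == pytest.approx(2.5)


def test_nj_input_validation():
    with pytest.raises(PopulationError, match="symmetric"):
        neighbor_joining(np.array([[0.0, 1], [2, 0]]), ["a", "b"])
    bad = np.array([[0.0, np.nan], [np.nan, 0]])
    with pytest.raises(PopulationError, match="NaN"):
        neighbor_joining(bad, ["a", "b"])


def test_newick_round_trip_through_dendropy():
    rng = np.random.default_rng(15)
    D = _random_additive_matrix(rng, 6)
    labels = [f"grp {i}" for i in range(6)]  # spaces force quoting
    tree = neighbor_joining(D, labels)
    nwk = tree_to_newick(tree)
    assert "'grp 0'" in nwk
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    for i, j in itertools.combinations(range(6), 2):
        d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        assert d == pytest.approx(D[i, j], abs=5e-5)  # 6-decimal serialization


def test_pca_of_group_means_collinear_and_rotation_invariance():
    means = {f"g{i}": np.array([i, 2.0 * i, -i]) for i in range(4)}
    scores = pca_of_group_means(means)
    assert np.allclose(scores.iloc[:, 1:], 0.0, atol=1e-9)  # all variance on PC1
    rng = np.random.default_rng(16)
    M = {f"g{i}": rng.normal(size=4) for i in range(5)}
    Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    rotated = {g: Q @ v for g, v in M.items()}
    s1 = pca_of_group_means(M).to_numpy()
    s2 = pca_of_group_means(rotated).to_numpy()
    for j in range(s1.shape[1]):  # per-axis sign freedom only
        assert np.allclose(s1[:, j], s2[:, j], atol=1e-8) or np.allclose(
            s1[:, j], -s2[:, j], atol=1e-8
        )
    with pytest.raises(PopulationError, match="3 groups"):
        pca_of_group_means({"a": np.zeros(3), "b": np.ones(3)})
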