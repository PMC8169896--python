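"""GPA, centroid size, Procrustes distances and form-space construction."""

from __future__ import annotations

import numpy as np
import pytest

from morphosus.dataset_io import LandmarkConfiguration
from morphosus.superimposition import (
    AlignedDataset,
    SuperimpositionError,
    build_form_matrix,
    centroid_size,
    generalized_procrustes,
    group_mean_shape,
    optimal_rotation,
    procrustes_distance,
)
from morphosus.synthetic import make_template

from conftest import small_template


def rot2(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def test_centroid_size_square_homogeneity_and_degenerate(unit_square):
    assert centroid_size(unit_square) == pytest.approx(np.sqrt(2), abs=1e-9)
    pts = unit_square.points
    for c in (0.5, 3.0, -2.0):
        assert centroid_size(pts * c) == pytest.approx(abs(c) * np.sqrt(2), abs=1e-9)
    assert centroid_size(pts + [17.0, -4.0]) == pytest.approx(np.sqrt(2), abs=1e-9)
    assert centroid_size(np.ones((5, 2))) == 0.0


def _centered_unit(pts):
    pts = pts - pts.mean(axis=0)
    return pts / np.sqrt(np.sum(pts**2))


def test_optimal_rotation_exact_recovery():
    src = _centered_unit(small_template(7).points)
    tgt = src @ rot2(np.pi / 6).T
    R, residual, ambiguous = optimal_rotation(src, tgt)
    assert residual < 1e-10
    assert not ambiguous
    assert np.allclose(src @ R, tgt, atol=1e-12)
    assert abs(np.arctan2(R[1, 0], R[0, 0])) == pytest.approx(np.pi / 6, abs=1e-10)


def test_optimal_rotation_excludes_reflection():
    tri = _centered_unit(np.array([[0.0, 0], [3, 0], [0.5, 2]]))
    mirrored = _centered_unit(tri * [-1.0, 1.0])
    _, residual, _ = optimal_rotation(tri, mirrored)
    assert residual > 0.05  # reflection would fit exactly; rotations cannot
    assert np.linalg.det(optimal_rotation(tri, mirrored)[0]) == pytest.approx(1.0)


def test_optimal_rotation_matches_grid_search_oracle():
    rng = np.random.default_rng(4)
    for _ in range(5):
        a = _centered_unit(rng.normal(size=(5, 2)))
        b = _centered_unit(rng.normal(size=(5, 2)))
        _, residual, _ = optimal_rotation(a, b)
        thetas = np.deg2rad(np.arange(0, 360, 0.01))
        c, s = np.cos(thetas), np.sin(thetas)
        # residual^2 = |a|^2 + |b|^2 - 2 trace(R^T a^T b)
        H = a.T @ b
        tr = (H[0, 0] + H[1, 1]) * c + (H[1, 0] - H[0, 1]) * s
        grid_min = np.sqrt(np.min(2.0 - 2.0 * tr))
        assert residual == pytest.approx(grid_min, abs=1e-6)


def test_gpa_orbit_of_one_shape_collapses():
    rng = np.random.default_rng(7)
    base = small_template(8).points
    configs = []
    for _ in range(20):
        R = rot2(rng.uniform(0, 2 * np.pi))
        configs.append(rng.uniform(0.5, 3.0) * base @ R.T + rng.normal(size=2) * 5)
    aligned = generalized_procrustes(configs)
    assert aligned.converged
    spread = aligned.shape_coordinates - aligned.shape_coordinates[0]
    assert np.max(np.abs(spread)) < 1e-8
    assert procrustes_distance(aligned.consensus.reshape(8, 2), base) < 1e-8


def test_gpa_postconditions_unit_size_and_centered():
    rng = np.random.default_rng(8)
    configs = [small_template(6).points + rng.normal(scale=0.05, size=(6, 2)) for _ in range(9)]
    aligned = generalized_procrustes(configs)
    for i in range(len(configs)):
        c = aligned.configuration(i)
        assert np.sqrt(np.sum((c - c.mean(axis=0)) ** 2)) == pytest.approx(1.0, abs=1e-9)
    cons = aligned.consensus.reshape(6, 2)
    assert np.allclose(cons.mean(axis=0), 0, atol=1e-9)


def test_gpa_distances_invariant_under_common_rotation():
    rng = np.random.default_rng(9)
    configs = [small_template(6).points + rng.normal(scale=0.03, size=(6, 2)) for _ in range(8)]
    R = rot2(1.234)
    rotated = [c @ R.T for c in configs]
    a1 = generalized_procrustes(configs)
    a2 = generalized_procrustes(rotated)

    def pairwise(aligned):
        rows = aligned.shape_coordinates
        n = rows.shape[0]
        return np.array(
            [
                procrustes_distance(rows[i].reshape(6, 2), rows[j].reshape(6, 2))
                for i in range(n)
                for j in range(i + 1, n)
            ]
        )

    assert np.allclose(pairwise(a1), pairwise(a2), atol=1e-8)


def test_gpa_zero_size_specimen_rejected():
    configs = [small_template(6).points, np.zeros((6, 2))]
    with pytest.raises(SuperimpositionError, match="zero centroid size"):
        generalized_procrustes(configs)


def test_procrustes_distance_properties():
    base = small_template(7).points
    assert procrustes_distance(base, base @ rot2(2.1).T) < 1e-9
    rng = np.random.default_rng(11)
    other = base + rng.normal(scale=0.2, size=base.shape)
    assert procrustes_distance(base, other) == pytest.approx(
        procrustes_distance(other, base), abs=1e-9
    )
    assert procrustes_distance(base, other) > 0


def test_form_matrix_columns_and_log_sizes():
    rng = np.random.default_rng(12)
    template = make_template("M2")
    configs = [
        (template.points + rng.normal(scale=0.01, size=template.points.shape)) * s
        for s in (1.0, 2.0, 3.0)
    ]
    aligned = generalized_procrustes(configs)
    form = build_form_matrix(aligned)
    assert form.values.shape[1] == 2 * 75 + 1  # M/2 protocol: k*p + 1 = 151
    assert form.columns()[-1] == "logCS"
    assert np.allclose(form.values[:, -1], np.log(aligned.centroid_sizes))

    unit = AlignedDataset(
        shape_coordinates=aligned.shape_coordinates[:2],
        centroid_sizes=np.array([1.0, 0.0]),
        consensus=aligned.consensus,
        p=aligned.p,
        k=aligned.k,
        iterations=1,
        converged=True,
    )
    with pytest.raises(SuperimpositionError, match="centroid size"):
        build_form_matrix(unit)
    ok = AlignedDataset(
        shape_coordinates=aligned.shape_coordinates[:2],
        centroid_sizes=np.array([1.0, 2.0]),
        consensus=aligned.consensus,
        p=aligned.p,
        k=aligned.k,
        iterations=1,
        converged=True,
    )
    assert build_form_matrix(ok).values[0, -1] == 0.0


def test_group_mean_shape_matches_columnwise_oracle():
    rng = np.random.default_rng(13)
    rows = rng.normal(size=(6, 10))
    labels = np.array(["a", "a", "b", "b", "b", "c"])
    means = group_mean_shape(rows, labels)
    for g in ("a", "b", "c"):
        expected = rows[labels == g].mean(axis=0)  # independent recomputation
        assert np.allclose(means[g], expected)
    assert np.allclose(means["c"], rows[5])
    two = group_mean_shape(rows[:2], np.array(["x", "x"]))
    assert np.allclose(two["x"], (rows[0] + rows[1]) / 2)
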