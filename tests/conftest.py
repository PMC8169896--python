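"""Shared fixtures: small deterministic configurations and truths that keep
simulation-heavy tests fast."""

from __future__ import annotations

import numpy as np
import pytest

from morphosus.dataset_io import LandmarkConfiguration
from morphosus.synthetic import SizeModel, SyntheticTruth, orthogonalize_to_similarity


@pytest.fixture
def unit_square() -> LandmarkConfiguration:
    return LandmarkConfiguration(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


def small_template(p: int = 6) -> LandmarkConfiguration:
    """Small irregular 2D configuration with unit centroid size (asymmetric,
    so rotations are uniquely recoverable)."""
    t = np.linspace(0, 2 * np.pi, p, endpoint=False)
    pts = np.column_stack([np.cos(t) * (1 + 0.3 * np.sin(3 * t)), np.sin(t) * (1 - 0.2 * np.cos(2 * t))])
    pts -= pts.mean(axis=0)
    pts /= np.sqrt(np.sum(pts**2))
    return LandmarkConfiguration(pts)


def small_truth(
    groups: dict[str, float],
    p: int = 6,
    noise_sd: float = 0.01,
    slope_mag: float = 0.0,
    size_means: dict[str, float] | None = None,
    size_sd: float = 0.08,
    seed: int = 0,
) -> SyntheticTruth:
    """Build a compact synthetic truth: ``groups`` maps group label to the
    magnitude of its mean-shape offset."""
    template = small_template(p)
    tmpl = template.points
    q = p * 2
    rng = np.random.default_rng(seed + 131)
    offsets = {}
    for g, mag in groups.items():
        if mag == 0:
            offsets[g] = np.zeros(q)
        else:
            v = orthogonalize_to_similarity(rng.normal(size=q), tmpl)
            offsets[g] = mag * v / np.linalg.norm(v)
    if slope_mag:
        v = orthogonalize_to_similarity(rng.normal(size=q), tmpl)
        slope = slope_mag * v / np.linalg.norm(v)
    else:
        slope = np.zeros(q)
    size_means = size_means or {g: 3.0 for g in groups}
    return SyntheticTruth(
        template=template,
        element="M2",
        group_offsets=offsets,
        size_models={g: SizeModel((1.0,), (size_means[g],), (size_sd,)) for g in groups},
        allometry_slope=slope,
        noise_sd=noise_sd,
        seed=seed,
    )
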