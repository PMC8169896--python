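"""Generalized Procrustes Analysis and the shape/form variable construction.

Procrustes superimposition removes position, scale and orientation from the
raw landmark coordinates: each configuration is centered, scaled to unit
centroid size, and rotated to a consensus that is iteratively refined until
it stops moving.  The resulting Procrustes coordinates are the shape
variables of every downstream analysis; centroid size — the square root of
the summed squared distances of the landmarks to their centroid — is the
size variable.  The form matrix concatenates the shape coordinates with the
natural log of centroid size, giving a single specimens-by-(k*p + 1) matrix.

Reflections are excluded from the rotation solver (determinant forced to
+1): left/right identity must never be destroyed silently; mirror antimeres
are handled at ingest.  Fitting is partial Procrustes (unit-size, no extra
rescaling to cos(rho)), and residuals are used directly without a tangent
projection — shape variation at intra-specific scale is small enough that
the distinction is numerically negligible here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import LandmarkConfiguration, MorphometricDataset

__all__ = [
    "AlignedDataset",
    "FormMatrix",
    "SuperimpositionError",
    "centroid_size",
    "optimal_rotation",
    "generalized_procrustes",
    "procrustes_distance",
    "build_form_matrix",
    "group_mean_shape",
]

GPA_TOLERANCE = 1e-10
GPA_MAX_ITER = 100


class SuperimpositionError(ValueError):
    pass


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """sqrt of the summed squared distances of all landmarks to their centroid.

    Translation-invariant and absolutely homogeneous of degree 1; an
    all-coincident configuration returns 0.
    """
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _as_points(x: LandmarkConfiguration | np.ndarray) -> np.ndarray:
    return x.points if isinstance(x, LandmarkConfiguration) else np.asarray(x, dtype=float)


def optimal_rotation(
    source: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """Least-squares proper rotation of ``source`` (p, k) onto ``target``.

    Both inputs are expected centered and unit-size.  Returns ``(R, residual,
    ambiguous)`` where ``source @ R`` minimizes the summed squared distance to
    the target over rotations with det(R) = +1 (reflections excluded),
    ``residual`` is the square root of that minimum, and ``ambiguous`` flags a
    rank-deficient cross-covariance whose solution is not unique (a
    deterministic SVD sign convention is still applied).
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.shape != target.shape:
        raise SuperimpositionError(f"shape mismatch: {source.shape} vs {target.shape}")
    k = source.shape[1]
    H = source.T @ target
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.eye(k)
    D[-1, -1] = d
    R = U @ D @ Vt
    # unique iff the smallest singular value is simple and (for d<0) nonzero
    tol = max(s[0], 1.0) * 1e-12
    ambiguous = bool(s[-1] < tol or (k > 1 and s[-2] - s[-1] < tol and d < 0))
    residual = float(np.sqrt(max(np.sum((source @ R - target) ** 2), 0.0)))
    return R, residual, ambiguous


@dataclass(frozen=True)
class AlignedDataset:
    """Procrustes shape coordinates plus the sizes removed by alignment.

    ``shape_coordinates`` is (n, k*p), row-major per landmark, each row unit
    centroid size and centered at the origin; ``centroid_sizes`` holds the
    original sizes in input units; ``consensus`` is the mean shape.
    """

    shape_coordinates: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    p: int
    k: int
    iterations: int
    converged: bool
    specimen_ids: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.shape_coordinates.shape[0]

    def configuration(self, i: int) -> np.ndarray:
        return self.shape_coordinates[i].reshape(self.p, self.k)

    def coordinate_columns(self) -> list[str]:
        axes = "xyz"[: self.k]
        return [f"{a}{i + 1}" for i in range(self.p) for a in axes]


def generalized_procrustes(dataset: MorphometricDataset | list[np.ndarray]) -> AlignedDataset:
    """Iterative GPA: center, scale to unit centroid size, rotate each
    configuration to the consensus, update the consensus, and repeat until the
    consensus RMS change drops below 1e-10 (or 100 iterations).

    The summed squared residual to the consensus is non-increasing across
    iterations; original centroid sizes are stored before scaling.
    """
    if isinstance(dataset, MorphometricDataset):
        configs = [r.configuration.points for r in dataset.records]
        ids = tuple(dataset.specimen_ids)
        groups = tuple(dataset.groups)
    else:
        configs = [np.asarray(c, float) for c in dataset]
        ids = tuple(f"spec_{i}" for i in range(len(configs)))
        groups = ("all",) * len(configs)
    n = len(configs)
    if n < 2:
        raise SuperimpositionError("GPA needs at least 2 specimens")
    p, k = configs[0].shape

    sizes = np.empty(n)
    scaled = np.empty((n, p, k))
    for i, c in enumerate(configs):
        if c.shape != (p, k):
            raise SuperimpositionError(f"specimen {ids[i]}: shape {c.shape} != {(p, k)}")
        centered = c - c.mean(axis=0)
        cs = float(np.sqrt(np.sum(centered**2)))
        if cs <= 0:
            raise SuperimpositionError(f"specimen {ids[i]}: zero centroid size")
        sizes[i] = cs
        scaled[i] = centered / cs

    consensus = scaled[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, GPA_MAX_ITER + 1):
        for i in range(n):
            R, _, _ = optimal_rotation(scaled[i], consensus)
            scaled[i] = scaled[i] @ R
        new_consensus = scaled.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        ncs = np.sqrt(np.sum(new_consensus**2))
        if ncs <= 0:
            raise SuperimpositionError("degenerate consensus (all shapes cancel)")
        new_consensus /= ncs
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < GPA_TOLERANCE:
            converged = True
            break
    if not converged:
        raise SuperimpositionError(
            f"GPA did not converge in {GPA_MAX_ITER} iterations "
            f"(last consensus RMS change {change:.3e})"
        )
    # final alignment to the converged consensus
    for i in range(n):
        R, _, _ = optimal_rotation(scaled[i], consensus)
        scaled[i] = scaled[i] @ R

    return AlignedDataset(
        shape_coordinates=scaled.reshape(n, p * k),
        centroid_sizes=sizes,
        consensus=consensus.reshape(p * k),
        p=p,
        k=k,
        iterations=iterations,
        converged=converged,
        specimen_ids=ids,
        groups=groups,
    )


def procrustes_distance(
    a: LandmarkConfiguration | np.ndarray, b: LandmarkConfiguration | np.ndarray
) -> float:
    """Partial Procrustes distance: both configurations are centered and
    scaled to unit centroid size, optimally rotated, and the root summed
    squared difference returned.  Zero iff the shapes coincide up to a
    similarity transform; symmetric."""
    pa, pb = _as_points(a), _as_points(b)
    if pa.shape != pb.shape:
        raise SuperimpositionError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    ca = pa - pa.mean(axis=0)
    cb = pb - pb.mean(axis=0)
    sa, sb = np.sqrt(np.sum(ca**2)), np.sqrt(np.sum(cb**2))
    if sa <= 0 or sb <= 0:
        raise SuperimpositionError("zero centroid size")
    _, residual, _ = optimal_rotation(ca / sa, cb / sb)
    return residual


@dataclass(frozen=True)
class FormMatrix:
    """specimens x (k*p + 1) matrix: Procrustes coordinates with ln(centroid
    size) appended as the last column."""

    values: np.ndarray
    aligned: AlignedDataset

    def columns(self) -> list[str]:
        return self.aligned.coordinate_columns() + ["logCS"]


def build_form_matrix(aligned: AlignedDataset) -> FormMatrix:
    """Concatenate the log centroid-size vector with the Procrustes
    coordinates into the form (size + shape) dataset."""
    if np.any(aligned.centroid_sizes <= 0):
        bad = np.flatnonzero(aligned.centroid_sizes <= 0)
        raise SuperimpositionError(f"non-positive centroid size at rows {bad.tolist()}")
    values = np.column_stack([aligned.shape_coordinates, np.log(aligned.centroid_sizes)])
    return FormMatrix(values=values, aligned=aligned)


def group_mean_shape(rows: np.ndarray, labels: np.ndarray | list[str]) -> dict[str, np.ndarray]:
    """Per-group arithmetic mean of coordinate rows (shape or form vectors),
    keyed by group label in first-appearance order."""
    rows = np.asarray(rows, float)
    labels = np.asarray(labels)
    if labels.size == 0 or rows.shape[0] != labels.size:
        raise SuperimpositionError("labels must match rows and be non-empty")
    means: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(labels.tolist()):
        means[str(g)] = rows[labels == g].mean(axis=0)
    return means
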