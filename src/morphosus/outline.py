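"""Equidistant semilandmark extraction along digitized tooth outlines.

The dental protocol places a fixed set of anatomical landmarks on the
occlusal surface, with the last landmark sitting on the external outline of
the crown and anchoring the outline curve.  The curve itself is converted to
a fixed number of semilandmarks spaced equally by arc length: 67 for the
lower second molar (M/2, 8 landmarks) and 99 for the lower third molar
(M/3, 9 landmarks), giving 75- and 108-point configurations.

Outlines are normalized to counter-clockwise winding (signed-area test)
before resampling so that left/right antimeres and y-flipped images remain
comparable.  Semilandmarks are fixed once placed: there is no bending-energy
or perpendicular-projection sliding during alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import ANATOMICAL, SEMILANDMARK, LandmarkConfiguration, ProtocolTemplate

__all__ = [
    "OutlineCurve",
    "OutlineError",
    "PROTOCOLS",
    "polyline_arclength",
    "resample_equidistant",
    "ensure_counterclockwise",
    "apply_tooth_protocol",
]

#: Published dental digitizing protocols: anatomical landmark count,
#: semilandmark count, and the landmark anchoring the outline (the last one).
PROTOCOLS: dict[str, ProtocolTemplate] = {
    "M2": ProtocolTemplate(element="M2", n_anatomical=8, n_semilandmarks=67, start_landmark_index=7),
    "M3": ProtocolTemplate(element="M3", n_anatomical=9, n_semilandmarks=99, start_landmark_index=8),
}

#: Snap tolerance for the outline start point, as a fraction of arc length.
START_SNAP_TOLERANCE = 0.02


class OutlineError(ValueError):
    pass


@dataclass(frozen=True)
class OutlineCurve:
    """An open or closed 2D polyline with distinct consecutive vertices."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise OutlineError(f"vertices must be (m, 2), got {v.shape}")
        if v.shape[0] < 3:
            raise OutlineError("a curve needs at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise OutlineError("non-finite vertex")
        seg = np.diff(v, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            idx = int(np.flatnonzero(np.all(seg == 0.0, axis=1))[0])
            raise OutlineError(f"repeated consecutive vertex at index {idx}")
        if self.closed and np.all(v[0] == v[-1]):
            # drop an explicit closing vertex; closure is implied by the flag
            v = v[:-1]
        object.__setattr__(self, "vertices", v)
        if polyline_arclength(self)[-1] <= 0:
            raise OutlineError("zero-length curve")

    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise winding."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polyline_arclength(curve: OutlineCurve) -> np.ndarray:
    """Cumulative arc length at each vertex, from 0 to the total length
    (a closed curve appends the last-to-first closing segment)."""
    v = curve.vertices
    pts = np.vstack([v, v[:1]]) if curve.closed else v
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _project_onto_polyline(curve: OutlineCurve, point: np.ndarray) -> tuple[float, float]:
    """Return (arc position, distance) of the closest point on the polyline."""
    v = curve.vertices
    pts = np.vstack([v, v[:1]]) if curve.closed else v
    a, b = pts[:-1], pts[1:]
    ab = b - a
    seg_len2 = np.sum(ab**2, axis=1)
    t = np.clip(np.sum((point - a) * ab, axis=1) / seg_len2, 0.0, 1.0)
    proj = a + t[:, None] * ab
    dist = np.linalg.norm(proj - point, axis=1)
    i = int(np.argmin(dist))
    cum = np.concatenate([[0.0], np.cumsum(np.sqrt(seg_len2))])
    return float(cum[i] + t[i] * np.sqrt(seg_len2[i])), float(dist[i])


def _point_at_arclength(curve: OutlineCurve, s: np.ndarray) -> np.ndarray:
    v = curve.vertices
    pts = np.vstack([v, v[:1]]) if curve.closed else v
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    total = cum[-1]
    s = np.mod(s, total) if curve.closed else np.clip(s, 0.0, total)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2)
    seg = pts[idx + 1] - pts[idx]
    seg_len = cum[idx + 1] - cum[idx]
    t = (s - cum[idx]) / seg_len
    return pts[idx] + t[:, None] * seg


def resample_equidistant(
    curve: OutlineCurve, n: int, start_point: np.ndarray
) -> np.ndarray:
    """Place ``n`` points on the polyline at equal arc-length spacing.

    The first point is the projection of ``start_point`` onto the curve
    (which must lie within :data:`START_SNAP_TOLERANCE` of it, as a fraction
    of total arc length); spacing is perimeter/n for a closed curve and
    length/(n-1) for an open one (whose start must project onto an
    endpoint).  Traversal follows the curve's stored orientation; points are
    linearly interpolated within segments.
    """
    if n < 2:
        raise OutlineError(f"need n >= 2 resampled points, got {n}")
    start_point = np.asarray(start_point, dtype=float)
    total = polyline_arclength(curve)[-1]
    s0, dist = _project_onto_polyline(curve, start_point)
    if dist > START_SNAP_TOLERANCE * total:
        raise OutlineError(
            f"start point {start_point.tolist()} is {dist:.4g} from the curve "
            f"(tolerance {START_SNAP_TOLERANCE * total:.4g})"
        )
    if curve.closed:
        s = s0 + np.arange(n) * total / n
        return _point_at_arclength(curve, s)
    # open curve: the start must be (within tolerance) an endpoint
    work = curve
    if s0 > total / 2:  # nearer the far end: traverse in reverse
        work = OutlineCurve(curve.vertices[::-1].copy(), closed=False)
        s0 = total - s0
    if s0 > START_SNAP_TOLERANCE * total:
        raise OutlineError("open-curve resampling must start at an endpoint")
    s = np.arange(n) * total / (n - 1)
    return _point_at_arclength(work, s)


def ensure_counterclockwise(curve: OutlineCurve) -> OutlineCurve:
    """Return the curve with counter-clockwise winding (closed curves only)."""
    if curve.closed and curve.signed_area() < 0:
        return OutlineCurve(curve.vertices[::-1].copy(), closed=True)
    return curve


def apply_tooth_protocol(
    landmarks: LandmarkConfiguration,
    curve: OutlineCurve,
    template: ProtocolTemplate,
) -> LandmarkConfiguration:
    """Build the full protocol configuration: anatomical landmarks followed by
    equidistant outline semilandmarks anchored at the template's start landmark.

    The outline is normalized to counter-clockwise winding first.  Output has
    ``template.n_anatomical + template.n_semilandmarks`` points with roles
    tagged anatomical-first.
    """
    if landmarks.p != template.n_anatomical:
        raise OutlineError(
            f"protocol {template.element} expects {template.n_anatomical} landmarks, "
            f"got {landmarks.p}"
        )
    if landmarks.dimension != 2:
        raise OutlineError("the tooth outline protocol is 2D")
    oriented = ensure_counterclockwise(curve)
    start = landmarks.points[template.start_landmark_index]
    semis = resample_equidistant(oriented, template.n_semilandmarks, start)
    points = np.vstack([landmarks.points, semis])
    roles = (ANATOMICAL,) * template.n_anatomical + (SEMILANDMARK,) * template.n_semilandmarks
    return LandmarkConfiguration(points, roles)
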