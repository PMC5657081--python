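"""Marker kinematics: rotation about the torsion axis via the Law of Cosines.

A marker's rotational displacement between two instants is computed by
projecting both positions onto the plane perpendicular to the torsion axis
(removing the axial translation induced by the 20 N preload), taking the
projected radii r1, r2 and the Euclidean chord d between the projections,
and applying the Law of Cosines:

    angle = arccos((r1^2 + r2^2 - d^2) / (2 r1 r2))

The result is unsigned (a chord cannot carry direction); displacements are
reported as magnitudes.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError
from .types import MarkerTrajectory, TorsionAxis

__all__ = [
    "estimate_axis",
    "rotation_angle",
    "marker_cycle_displacement",
    "relative_displacement",
    "angular_coordinate",
]

MIN_RADIUS_MM = 1.0


def estimate_axis(static_markers: list[MarkerTrajectory] | dict[str, MarkerTrajectory]) -> TorsionAxis:
    """Torsion axis from static (reference/diaphyseal) markers.

    Direction is the machine vertical (+z); the axis point is the
    time-averaged centroid of the static marker positions.  Equivariant under
    rigid translation of the whole marker set.
    """
    if isinstance(static_markers, dict):
        static_markers = list(static_markers.values())
    if len(static_markers) < 3:
        raise ConfigurationError("axis estimation needs >= 3 static markers")
    centroid = np.mean([m.position.mean(axis=0) for m in static_markers], axis=0)
    return TorsionAxis(point=tuple(float(c) for c in centroid))


def _project(p: np.ndarray, axis: TorsionAxis) -> np.ndarray:
    """Component of p - axis.point perpendicular to the axis direction."""
    d = np.asarray(axis.direction, dtype=float)
    rel = np.asarray(p, dtype=float) - np.asarray(axis.point, dtype=float)
    return rel - np.outer(rel @ d if rel.ndim > 1 else np.atleast_1d(rel @ d), d).reshape(rel.shape)


def rotation_angle(
    p_a, p_b, axis: TorsionAxis, min_radius: float = MIN_RADIUS_MM
) -> float:
    """Unsigned rotation (degrees) of a point about the axis between two instants."""
    qa = _project(np.asarray(p_a, dtype=float), axis)
    qb = _project(np.asarray(p_b, dtype=float), axis)
    r1 = float(np.linalg.norm(qa))
    r2 = float(np.linalg.norm(qb))
    if r1 < min_radius or r2 < min_radius:
        raise DegenerateGeometryError(
            f"projected radius below {min_radius} mm: rotation angle undefined"
        )
    dsq = float(np.sum((qa - qb) ** 2))
    cosang = (r1 * r1 + r2 * r2 - dsq) / (2.0 * r1 * r2)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def angular_coordinate(traj: MarkerTrajectory, axis: TorsionAxis) -> np.ndarray:
    """Unwrapped azimuth (degrees) of the marker about the axis, per sample."""
    d = np.asarray(axis.direction, dtype=float)
    # orthonormal basis of the projection plane
    seed = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    rel = traj.position - np.asarray(axis.point, dtype=float)
    phi = np.arctan2(rel @ e2, rel @ e1)
    return np.degrees(np.unwrap(phi))


def marker_cycle_displacement(
    traj: MarkerTrajectory,
    t_start: float,
    t_end: float,
    axis: TorsionAxis,
    min_radius: float = MIN_RADIUS_MM,
) -> float:
    """Full-cycle peak-to-peak marker rotation (degrees) within [t_start, t_end).

    The two within-cycle extremes are taken on the marker's own angular
    coordinate about the axis — not on actuator phase — so slippage-induced
    phase lag between machine and bone does not bias the measurement.
    """
    mask = (traj.time >= t_start) & (traj.time < t_end)
    idx = np.nonzero(mask)[0]
    if len(idx) < 4:
        raise ConfigurationError(
            f"marker {traj.marker_id}: fewer than 4 samples in [{t_start}, {t_end})"
        )
    sub = MarkerTrajectory(
        traj.marker_id, traj.label, traj.segment, traj.time[idx], traj.position[idx]
    )
    phi = angular_coordinate(sub, axis)
    i_hi = int(np.argmax(phi))
    i_lo = int(np.argmin(phi))
    if i_hi == i_lo:
        return 0.0
    return rotation_angle(sub.position[i_hi], sub.position[i_lo], axis, min_radius)


def relative_displacement(epi_angle: float, dia_angle: float) -> float:
    """Epiphysis-relative-to-diaphysis rotation, degrees (isolates the fracture)."""
    return epi_angle - dia_angle
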