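"""Planar track geometry: ranges, bearings, courses, turning angles, tortuosity.

All coordinates are projected planar metres (e.g. UTM); geometry is strictly
2-D — altitude is carried alongside but never enters range or bearing, so
ranges are horizontal ground ranges, not slant ranges. Bearings and courses
are degrees clockwise from grid north; trigonometry is done in radians
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrackPoint",
    "RadarOrigin",
    "range_bearing",
    "course",
    "turning_angle",
    "tortuosity",
    "orientation_class",
]


@dataclass(frozen=True)
class TrackPoint:
    """A timestamped planar position.

    Parameters
    ----------
    t : float
        Seconds since epoch (fractional allowed).
    x, y : float
        Projected planar coordinates in metres.
    alt : float
        Metres above ground level; ``nan`` when unknown (radar plots carry
        no altitude on a horizontally scanning fan-beam radar).
    """

    t: float
    x: float
    y: float
    alt: float = float("nan")

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t) and np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("TrackPoint t, x, y must be finite")


@dataclass(frozen=True)
class RadarOrigin:
    """Radar antenna location and height above local ground."""

    x: float
    y: float
    antenna_height: float = 0.0

    def __post_init__(self) -> None:
        if self.antenna_height < 0:
            raise ValueError("antenna_height must be >= 0")


def _bearing_deg(dx, dy):
    """Bearing of the vector (dx, dy), degrees clockwise from grid north."""
    return np.mod(np.degrees(np.arctan2(dx, dy)), 360.0)


def range_bearing(origin: RadarOrigin, x, y):
    """Horizontal range (m) and bearing (deg, clockwise from north) from the radar.

    Accepts scalars or arrays. Zero range maps to bearing 0 by convention.
    """
    dx = np.asarray(x, dtype=float) - origin.x
    dy = np.asarray(y, dtype=float) - origin.y
    rng = np.hypot(dx, dy)
    brg = np.where(rng > 0, _bearing_deg(dx, dy), 0.0)
    if np.ndim(rng) == 0:
        return float(rng), float(brg)
    return rng, brg


def course(x, y):
    """Course over ground of each step of a polyline, degrees in [0, 360).

    ``x, y`` are sequences of at least two positions; returns one course per
    step (length n-1). Coincident consecutive points yield ``nan``
    (undefined-course signal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.diff(x)
    dy = np.diff(y)
    moving = (dx != 0) | (dy != 0)
    c = _bearing_deg(dx, dy)
    return np.where(moving, c, np.nan)


def turning_angle(courses):
    """Change in heading between consecutive courses, wrapped to (-180, 180]."""
    d = np.diff(np.asarray(courses, dtype=float))
    wrapped = -np.mod(-d + 180.0, 360.0) + 180.0  # maps to (-180, 180]
    return wrapped


def tortuosity(dh_deg):
    """Normalized-cosine turn statistic S = 1 - ((cos dH + 1) / 2).

    S is 0 for straight flight, 1 for a full reversal, and symmetric in turn
    direction. ``dh_deg`` is the turning angle in degrees (scalar or array);
    ``nan`` propagates (undefined at track ends / stationary points).
    """
    dh = np.radians(np.asarray(dh_deg, dtype=float))
    s = 1.0 - (np.cos(dh) + 1.0) / 2.0
    return np.clip(s, 0.0, 1.0) if np.ndim(s) else float(min(max(s, 0.0), 1.0))


def track_tortuosity(x, y):
    """Per-point tortuosity along a polyline.

    Returns an array of length n with ``nan`` at the two ends (no turning
    angle defined there) and at points flanked by a zero-length segment.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.full(n, np.nan)
    if n < 3:
        return out
    c = course(x, y)
    dh = turning_angle(c)
    out[1:-1] = tortuosity(dh)
    return out


def point_course(p_prev: TrackPoint, p: TrackPoint) -> float:
    """Course over ground from one track point to the next, degrees [0, 360)."""
    if p.x == p_prev.x and p.y == p_prev.y:
        raise ValueError("undefined course: coincident points")
    return float(_bearing_deg(p.x - p_prev.x, p.y - p_prev.y))


def point_tortuosity(p_prev: TrackPoint, p: TrackPoint, p_next: TrackPoint) -> float:
    """Turn statistic at the middle of three consecutive track points."""
    c1 = point_course(p_prev, p)
    c2 = point_course(p, p_next)
    dh = float(turning_angle([c1, c2])[0])
    return tortuosity(dh)


def orientation_class(course_deg, radial_bearing_deg, boundary: float = 45.0,
                      mode: str = "radial"):
    """Classify motion as "along" or "across" the radar beam.

    Let alpha be the angle between the course over ground and the radial
    direction from the radar. The segment is "along" the beam when
    ``|cos(alpha)| > cos(boundary)`` and "across" otherwise; the boundary tie
    ``|cos(alpha)| == cos(boundary)`` classifies as "across" (the inequality
    is strict). Flying directly toward and directly away are both "along".

    ``mode="tangent"`` measures alpha against the beam tangent instead
    (i.e. swaps the classes), for sensitivity analysis.
    """
    if mode not in ("radial", "tangent"):
        raise ValueError("mode must be 'radial' or 'tangent'")
    a = np.radians(np.asarray(course_deg, dtype=float)
                   - np.asarray(radial_bearing_deg, dtype=float))
    proj = np.abs(np.cos(a)) if mode == "radial" else np.abs(np.sin(a))
    along = proj > np.cos(np.radians(boundary))
    lab = np.where(along, "along", "across")
    return str(lab) if np.ndim(lab) == 0 else lab
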