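"""Planar geometry for local GPS track analysis.

A trial takes place within a few kilometres of forest, so tracks are
projected onto a local tangent plane with a simple equirectangular
projection around a per-dataset reference point.  At these extents the
projection error is far below the GPS position error, and the mapping is
exactly invertible, which keeps round-trip tests honest.

All bearings are compass bearings: degrees clockwise from north, in
[0, 360).  Magnetic bearings are true bearings minus the local magnetic
declination (east-positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "LocalFrame",
    "PlanarTrack",
    "true_bearing",
    "magnetic_bearing",
    "circular_difference",
    "step_lengths",
    "cumulative_path",
    "path_length",
    "min_distance_to_polyline",
    "points_to_polyline_distances",
]


class FrameError(ValueError):
    """A point lies outside the validity region of a local frame."""


@dataclass(frozen=True)
class LocalFrame:
    """Local equirectangular projection centred on ``(ref_lat, ref_lon)``.

    x is metres east of the reference, y metres north.  Valid for points
    within ~50 km of the reference.
    """

    ref_lat: float
    ref_lon: float
    earth_radius: float = EARTH_RADIUS_M

    # maximum supported distance from the reference point, metres
    MAX_EXTENT_M = 50_000.0

    def project(self, lat, lon):
        """Project geographic coordinates (degrees) to planar metres."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        dphi = np.radians(lat - self.ref_lat)
        dlam = np.radians(lon - self.ref_lon)
        x = self.earth_radius * dlam * np.cos(np.radians(self.ref_lat))
        y = self.earth_radius * dphi
        if np.any(np.hypot(x, y) > self.MAX_EXTENT_M):
            raise FrameError(
                f"point beyond {self.MAX_EXTENT_M / 1000:.0f} km of frame "
                f"reference ({self.ref_lat}, {self.ref_lon})"
            )
        return x, y

    def unproject(self, x, y):
        """Inverse of :meth:`project`; returns (lat, lon) in degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat = self.ref_lat + np.degrees(y / self.earth_radius)
        lon = self.ref_lon + np.degrees(
            x / (self.earth_radius * np.cos(np.radians(self.ref_lat)))
        )
        return lat, lon


@dataclass
class PlanarTrack:
    """A projected track: time (s), x (m east), y (m north) arrays."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.time) == len(self.x) == len(self.y)):
            raise ValueError("time/x/y arrays must have equal length")

    def __len__(self) -> int:
        return len(self.time)


def true_bearing(ax, ay, bx, by):
    """Compass bearing of the vector a->b, degrees in [0, 360).

    Raises ValueError for a zero displacement (scalar inputs only);
    vectorised calls return NaN for zero-length steps.
    """
    dx = np.asarray(bx, dtype=float) - np.asarray(ax, dtype=float)
    dy = np.asarray(by, dtype=float) - np.asarray(ay, dtype=float)
    if np.ndim(dx) == 0:
        if dx == 0.0 and dy == 0.0:
            raise ValueError("bearing undefined for coincident points")
        return float(np.degrees(np.arctan2(dx, dy)) % 360.0)
    zero = (dx == 0.0) & (dy == 0.0)
    with np.errstate(invalid="ignore"):
        b = np.degrees(np.arctan2(dx, dy)) % 360.0
    return np.where(zero, np.nan, b)


def magnetic_bearing(true_deg, declination_deg):
    """Convert a true bearing to magnetic: (true - declination) mod 360."""
    out = (np.asarray(true_deg, dtype=float) - declination_deg) % 360.0
    # tiny negative inputs can wrap to exactly 360.0 in floating point
    return out % 360.0 if np.ndim(out) else (0.0 if out >= 360.0 else float(out))


def circular_difference(a_deg, b_deg):
    """Signed smallest angular difference a - b, in (-180, 180]."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d) if np.ndim(d) else (
        d - 360.0 if d > 180.0 else d
    )


def step_lengths(x, y):
    """Euclidean lengths of consecutive steps; length n-1."""
    return np.hypot(np.diff(np.asarray(x, float)), np.diff(np.asarray(y, float)))


def cumulative_path(x, y):
    """Cumulative path length at each point, starting at 0; length n."""
    steps = step_lengths(x, y)
    out = np.empty(len(steps) + 1)
    out[0] = 0.0
    np.cumsum(steps, out=out[1:])
    return out


def path_length(x, y, i: int = 0, j: int | None = None) -> float:
    """Path length along the polyline from point ``i`` to point ``j``."""
    n = len(x)
    if j is None:
        j = n - 1
    if not (0 <= i < j < n):
        raise IndexError(f"invalid path slice [{i}, {j}] for {n} points")
    return float(np.sum(step_lengths(x[i : j + 1], y[i : j + 1])))


def points_to_polyline_distances(px, py, line_x, line_y):
    """Minimum distance from each query point to a polyline.

    Vectorised point-to-segment distance: the foot of the perpendicular
    is clamped to each segment, so endpoints are handled exactly.
    """
    px = np.atleast_1d(np.asarray(px, dtype=float))
    py = np.atleast_1d(np.asarray(py, dtype=float))
    lx = np.asarray(line_x, dtype=float)
    ly = np.asarray(line_y, dtype=float)
    if len(lx) < 2:
        raise ValueError("polyline needs at least 2 points")
    ax, ay = lx[:-1], ly[:-1]
    dxs, dys = np.diff(lx), np.diff(ly)
    seg_sq = dxs * dxs + dys * dys
    # degenerate (zero-length) segments: treat as their start point
    safe = np.where(seg_sq > 0.0, seg_sq, 1.0)
    # (n_points, n_segments) projection parameter, clamped to [0, 1]
    tx = px[:, None] - ax[None, :]
    ty = py[:, None] - ay[None, :]
    t = np.clip((tx * dxs[None, :] + ty * dys[None, :]) / safe[None, :], 0.0, 1.0)
    t = np.where(seg_sq[None, :] > 0.0, t, 0.0)
    fx = tx - t * dxs[None, :]
    fy = ty - t * dys[None, :]
    return np.sqrt(np.min(fx * fx + fy * fy, axis=1))


def min_distance_to_polyline(px: float, py: float, line_x, line_y) -> float:
    """Minimum distance from a single point to a polyline, metres."""
    return float(points_to_polyline_distances([px], [py], line_x, line_y)[0])
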