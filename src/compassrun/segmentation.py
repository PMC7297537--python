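"""Excursion detection and turning-point location.

An *excursion* is the dog's track from the moment its straight-line
separation from the owner first reaches the opening distance (100 m by
default; the owner's interpolated position at that instant becomes the
frozen goal) until the dog first comes back within the return radius
(10 m) of that goal.  Excursions whose total path length is below the
minimum (200 m) are discarded, as are excursions the dog never closed.

The excursion is then divided into ten equal path-length deciles; the
slowest decile is the *turning trajectory* (with fallbacks when the
slowest decile is improbable), and the slowest consecutive-fix pair
inside it marks the *turning point* where the return begins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .geometry import PlanarTrack, cumulative_path

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Input too degenerate to analyse (e.g. zero-duration segment)."""


@dataclass
class Excursion:
    """One detected excursion of a dog track.

    ``track`` is the planar dog sub-track from opening to closure;
    ``start_index``/``end_index`` index the full dog track;
    ``owner_pos`` is the frozen owner location (the excursion start /
    goal).  ``turning_point_index`` indexes ``track``.
    """

    track: PlanarTrack
    start_index: int
    end_index: int
    owner_pos: tuple[float, float]
    trial_id: str = ""
    dog_id: str = ""
    turning_segment: int | None = None
    turning_point_index: int | None = None
    cum: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.cum is None:
            self.cum = cumulative_path(self.track.x, self.track.y)

    @property
    def total_length(self) -> float:
        return float(self.cum[-1])

    @property
    def n_points(self) -> int:
        return len(self.track)

    def beeline(self) -> float:
        """Straight-line distance turning point -> goal (owner)."""
        i = self._require_turning()
        return float(np.hypot(self.track.x[i] - self.owner_pos[0],
                              self.track.y[i] - self.owner_pos[1]))

    def inbound_length(self) -> float:
        i = self._require_turning()
        return float(self.cum[-1] - self.cum[i])

    def inbound_duration(self) -> float:
        i = self._require_turning()
        return float(self.track.time[-1] - self.track.time[i])

    def _require_turning(self) -> int:
        if self.turning_point_index is None:
            raise ValueError("turning point not located yet")
        return self.turning_point_index


@dataclass
class SegmentProfile:
    """Decile profile of an excursion.

    boundaries: 11 cumulative path positions (0, L/10, ..., L);
    boundary_times: times at those positions (linear within fixes);
    speeds: 10 mean decile speeds (m/s); distances_from_start: maximal
    straight-line distance of each decile from the excursion start.
    """

    boundaries: np.ndarray
    boundary_times: np.ndarray
    speeds: np.ndarray
    distances_from_start: np.ndarray


def _interp_owner(owner: PlanarTrack, at_times: np.ndarray):
    ox = np.interp(at_times, owner.time, owner.x)
    oy = np.interp(at_times, owner.time, owner.y)
    return ox, oy


def detect_excursions(dog: PlanarTrack, owner: PlanarTrack,
                      cfg: AnalysisConfig = DEFAULT_CONFIG,
                      trial_id: str = "", dog_id: str = "") -> list[Excursion]:
    """Scan a trial for excursions.

    The owner track is linearly interpolated in time to the dog's fix
    times; outside its time span the owner is held at the nearest fix
    (the owner stands still once the dog is away).
    """
    if len(dog) < 2 or len(owner) < 2:
        raise DegenerateDataError("dog and owner tracks need >= 2 points")
    ox, oy = _interp_owner(owner, dog.time)
    separation = np.hypot(dog.x - ox, dog.y - oy)
    excursions: list[Excursion] = []
    cursor = 0
    n = len(dog)
    while cursor < n:
        open_candidates = np.nonzero(separation[cursor:] >= cfg.open_distance_m)[0]
        if open_candidates.size == 0:
            break
        i = cursor + int(open_candidates[0])
        owner_pos = (float(ox[i]), float(oy[i]))
        back = np.hypot(dog.x[i + 1:] - owner_pos[0],
                        dog.y[i + 1:] - owner_pos[1])
        close_candidates = np.nonzero(back <= cfg.close_distance_m)[0]
        if close_candidates.size == 0:
            logger.info("trial %s: excursion opened at t=%.1f s never closed; "
                        "excluded", trial_id, dog.time[i])
            break
        j = i + 1 + int(close_candidates[0])
        sub = PlanarTrack(dog.time[i:j + 1].copy(),
                          dog.x[i:j + 1].copy(), dog.y[i:j + 1].copy())
        exc = Excursion(sub, i, j, owner_pos, trial_id=trial_id, dog_id=dog_id)
        if exc.total_length >= cfg.min_excursion_length_m:
            excursions.append(exc)
        else:
            logger.info("trial %s: excursion of %.0f m below %.0f m minimum; "
                        "excluded", trial_id, exc.total_length,
                        cfg.min_excursion_length_m)
        cursor = j + 1
    return excursions


def segment_profile(exc: Excursion,
                    cfg: AnalysisConfig = DEFAULT_CONFIG) -> SegmentProfile:
    """Split the excursion into equal path-length deciles and profile them."""
    k = cfg.n_segments
    cum, t = exc.cum, exc.track.time
    total = exc.total_length
    if total <= 0:
        raise DegenerateDataError("zero-length excursion")
    boundaries = np.linspace(0.0, total, k + 1)
    boundary_times = np.interp(boundaries, cum, t)
    durations = np.diff(boundary_times)
    if np.any(durations <= 0):
        raise DegenerateDataError("zero-duration decile")
    speeds = (total / k) / durations

    bx = np.interp(boundaries, cum, exc.track.x)
    by = np.interp(boundaries, cum, exc.track.y)
    dist = np.hypot(exc.track.x - exc.owner_pos[0],
                    exc.track.y - exc.owner_pos[1])
    bdist = np.hypot(bx - exc.owner_pos[0], by - exc.owner_pos[1])
    seg_of_point = np.clip(
        np.searchsorted(boundaries, cum, side="right") - 1, 0, k - 1)
    far = np.zeros(k)
    for s in range(k):
        inside = dist[seg_of_point == s]
        far[s] = max(inside.max() if inside.size else 0.0,
                     bdist[s], bdist[s + 1])
    return SegmentProfile(boundaries, boundary_times, speeds, far)


def _pair_mask(exc: Excursion, boundaries: np.ndarray, segment: int):
    """Consecutive-fix pairs whose midpoint path position is in a decile."""
    mid = 0.5 * (exc.cum[:-1] + exc.cum[1:])
    lo, hi = boundaries[segment - 1], boundaries[segment]
    return (mid >= lo) & (mid <= hi)


def _is_improbable(exc: Excursion, profile: SegmentProfile, segment: int,
                   cfg: AnalysisConfig) -> bool:
    """A decile is improbable as the turning trajectory if it sits at the
    start/goal end of the excursion or contains one very long pause."""
    if segment in cfg.edge_segments:
        return True
    mask = _pair_mask(exc, profile.boundaries, segment)
    if not mask.any():
        return False
    gaps = np.diff(exc.track.time)[mask]
    return bool(gaps.max() > cfg.long_pause_gap_s)


def locate_turning_trajectory(profile: SegmentProfile, exc: Excursion,
                              cfg: AnalysisConfig = DEFAULT_CONFIG) -> int:
    """Pick the turning trajectory decile (1-based index).

    Rule: the slowest decile; if improbable, the second slowest; if that
    is improbable too, the slowest remaining decile whose maximal
    straight-line distance from the excursion start exceeds the median
    point distance (fallback: the farthest remaining decile).
    """
    order = np.argsort(profile.speeds, kind="stable") + 1  # 1-based
    first, second = int(order[0]), int(order[1])
    if not _is_improbable(exc, profile, first, cfg):
        return first
    if not _is_improbable(exc, profile, second, cfg):
        return second
    dist = np.hypot(exc.track.x - exc.owner_pos[0],
                    exc.track.y - exc.owner_pos[1])
    median_dist = float(np.median(dist))
    remaining = [int(s) for s in order[2:]]
    for s in remaining:
        if profile.distances_from_start[s - 1] > median_dist:
            return s
    return max(remaining, key=lambda s: profile.distances_from_start[s - 1])


def locate_turning_point(exc: Excursion, segment: int,
                         cfg: AnalysisConfig = DEFAULT_CONFIG,
                         profile: SegmentProfile | None = None) -> int:
    """Slowest consecutive-fix pair in the turning trajectory.

    Returns the index (into the excursion track) of the first fix of the
    slowest pair; ties break to the earliest pair.
    """
    if profile is None:
        profile = segment_profile(exc, cfg)
    mask = _pair_mask(exc, profile.boundaries, segment)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise DegenerateDataError(
            f"turning trajectory decile {segment} contains no fix pair")
    steps = np.hypot(np.diff(exc.track.x), np.diff(exc.track.y))[idx]
    dts = np.diff(exc.track.time)[idx]
    speeds = steps / dts
    return int(idx[int(np.argmin(speeds))])


def analyze_excursion(exc: Excursion,
                      cfg: AnalysisConfig = DEFAULT_CONFIG) -> SegmentProfile:
    """Locate the turning trajectory and turning point, in place."""
    profile = segment_profile(exc, cfg)
    seg = locate_turning_trajectory(profile, exc, cfg)
    tp = locate_turning_point(exc, seg, cfg, profile=profile)
    if not (0 < tp < exc.n_points - 1):
        tp = min(max(tp, 1), exc.n_points - 2)
    exc.turning_segment = seg
    exc.turning_point_index = tp
    return profile
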