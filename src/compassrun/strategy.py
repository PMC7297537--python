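"""Return-strategy classification: tracking vs scouting vs combined.

A *tracking* return stays within a +-30 m corridor of the outbound
track at every evaluated point; a *scouting* return is separated from
the outbound track by more than 30 m throughout.  Returns that do both
in sequence are *combined* and are split into sub-tracks, one per
strategy.  The first and last 50 m of the inbound path are excluded
from evaluation (the endpoints coincide with the outbound track by
construction), and runs shorter than 100 m of path are merged into
their neighbours so that GPS noise cannot flip a label.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .geometry import points_to_polyline_distances
from .segmentation import DegenerateDataError, Excursion


class StrategyLabel(str, Enum):
    TRACKING = "tracking"
    SCOUTING = "scouting"
    COMBINED = "combined"


@dataclass
class CorridorProfile:
    """Distances of inbound fixes to the outbound polyline.

    ``distances[k]`` is the minimum distance of inbound fix k (index
    ``inbound_offset + k`` in the excursion track) to the outbound
    polyline; ``evaluated_mask`` excludes the terminal buffers.
    """

    distances: np.ndarray
    evaluated_mask: np.ndarray
    inbound_offset: int


@dataclass
class ReturnSegments:
    """Contiguous sub-tracks of a return, one per strategy run.

    Indices are into the excursion track; consecutive sub-tracks share a
    boundary fix so their path lengths add up to the evaluated span.
    """

    subtracks: list[tuple[StrategyLabel, int, int]]


def corridor_profile(exc: Excursion,
                     cfg: AnalysisConfig = DEFAULT_CONFIG) -> CorridorProfile:
    """Distance of every inbound fix to the outbound polyline."""
    tp = exc.turning_point_index
    if tp is None:
        raise ValueError("turning point not located")
    if tp < 1:
        raise DegenerateDataError("outbound track has fewer than 2 fixes")
    x, y = exc.track.x, exc.track.y
    dist = points_to_polyline_distances(x[tp:], y[tp:],
                                        x[: tp + 1], y[: tp + 1])
    inbound_path = exc.cum[tp:] - exc.cum[tp]
    total = inbound_path[-1]
    mask = ((inbound_path >= cfg.terminal_buffer_m)
            & (inbound_path <= total - cfg.terminal_buffer_m))
    return CorridorProfile(dist, mask, tp)


def _merge_short_runs(runs, min_len):
    """Iteratively flip the shortest run below ``min_len`` into its
    neighbours.  ``runs`` are (label, start, end, path_length) tuples in
    evaluated-fix order; merging concatenates adjacent same-label runs."""
    runs = list(runs)
    while len(runs) > 1:
        lengths = [r[3] for r in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_len:
            break
        label, s, e, ln = runs[shortest]
        flipped = (not label, s, e, ln)
        runs[shortest] = flipped
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                prev = merged.pop()
                merged.append((prev[0], prev[1], r[2],
                               prev[3] + r[3]))
            else:
                merged.append(r)
        runs = merged
    return runs


def classify_return(profile: CorridorProfile, exc: Excursion,
                    cfg: AnalysisConfig = DEFAULT_CONFIG
                    ) -> tuple[StrategyLabel, ReturnSegments]:
    """Label a return and, if combined, split it into sub-tracks."""
    mask = profile.evaluated_mask
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise DegenerateDataError("no evaluated inbound fixes "
                                  "(inbound shorter than the buffers)")
    inside = profile.distances[idx] <= cfg.corridor_m  # True = in corridor
    cum = exc.cum[profile.inbound_offset:]
    # contiguous runs of equal corridor state over the evaluated fixes
    change = np.nonzero(np.diff(inside.astype(int)))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(idx) - 1]))
    runs = []
    for s, e in zip(starts, ends):
        a, b = idx[s], idx[e]
        # extend run span to the midpoint boundaries with its neighbours
        lo = cum[a] if s == 0 else 0.5 * (cum[idx[s - 1]] + cum[a])
        hi = cum[b] if e == len(idx) - 1 else 0.5 * (cum[b] + cum[idx[e + 1]])
        runs.append((bool(inside[s]), int(a), int(b), float(hi - lo)))
    runs = _merge_short_runs(runs, cfg.min_run_m)

    off = profile.inbound_offset
    if len(runs) == 1:
        label = StrategyLabel.TRACKING if runs[0][0] else StrategyLabel.SCOUTING
        segs = ReturnSegments([(label, off + runs[0][1], off + runs[0][2])])
        return label, segs
    subtracks = []
    for i, (state, a, b, _) in enumerate(runs):
        sub = StrategyLabel.TRACKING if state else StrategyLabel.SCOUTING
        # share boundary fixes so path lengths tile the evaluated span
        start = runs[i - 1][2] if i > 0 else a
        subtracks.append((sub, off + start, off + b))
    return StrategyLabel.COMBINED, ReturnSegments(subtracks)


def classify_excursion(exc: Excursion, cfg: AnalysisConfig = DEFAULT_CONFIG
                       ) -> tuple[StrategyLabel, ReturnSegments]:
    """Corridor profile + classification in one call."""
    return classify_return(corridor_profile(exc, cfg), exc, cfg)
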