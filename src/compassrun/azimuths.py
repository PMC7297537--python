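"""Azimuths A, B and C (the compass run), sectors and axes.

Azimuth A is the magnetic direction of the dog's initial outbound
segment (excursion start fix to the fix nearest 5 s later).  Azimuth B
is the magnetic direction from the turning point to the owner.  Azimuth
C is the magnetic direction of the *compass run*: the initial inbound
segment from the turning point up to the first sustained deflection of
more than 20 degrees in track direction.

Azimuths are classified into +-45 degree cardinal sectors — north
(316-45), east (46-135), south (136-225), west (226-315) — after
rounding to whole degrees, and into the north-south vs east-west axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .geometry import circular_difference, magnetic_bearing, true_bearing
from .segmentation import Excursion

logger = logging.getLogger(__name__)


class CardinalSector(str, Enum):
    N = "N"
    E = "E"
    S = "S"
    W = "W"


class AxisClass(str, Enum):
    NS = "NS"
    EW = "EW"


class MissingFixError(ValueError):
    """No GPS fix near the required time offset."""


@dataclass
class CompassRun:
    """Result of compass-run extraction from a given start fix."""

    azimuth_deg: float       # magnetic chord bearing start -> run end
    length_m: float          # run length measured along the track
    end_index: int           # index (into the excursion track) of run end
    terminated: bool         # False if no deflection before the track ended


@dataclass
class AzimuthSet:
    azimuth_a: float
    azimuth_b: float
    azimuth_c: float
    compass_run_length: float
    compass_run_end_index: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sector_of(azimuth_deg: float) -> CardinalSector:
    """Cardinal sector of an azimuth, by whole-degree closed ranges."""
    a = _round_half_up(float(azimuth_deg) % 360.0) % 360
    if a >= 316 or a <= 45:
        return CardinalSector.N
    if a <= 135:
        return CardinalSector.E
    if a <= 225:
        return CardinalSector.S
    return CardinalSector.W


def axis_of(azimuth_deg: float) -> AxisClass:
    """North-south vs east-west axis of an azimuth."""
    return (AxisClass.NS
            if sector_of(azimuth_deg) in (CardinalSector.N, CardinalSector.S)
            else AxisClass.EW)


def azimuth_a(exc: Excursion, declination_deg: float,
              cfg: AnalysisConfig = DEFAULT_CONFIG) -> float:
    """Magnetic bearing of the initial outbound segment.

    From the excursion-start fix to the fix nearest ``azimuth_a_offset_s``
    (5 s) later; the fix must fall within half the nominal interval of
    the target time.
    """
    t = exc.track.time - exc.track.time[0]
    target = cfg.azimuth_a_offset_s
    k = int(np.argmin(np.abs(t - target)))
    dt_nominal = float(np.median(np.diff(exc.track.time)))
    if k == 0 or abs(t[k] - target) > 0.5 * dt_nominal + 1e-9:
        raise MissingFixError(
            f"no fix within half an interval of {target} s after start")
    bearing = true_bearing(exc.track.x[0], exc.track.y[0],
                           exc.track.x[k], exc.track.y[k])
    return magnetic_bearing(bearing, declination_deg)


def azimuth_b(exc: Excursion, declination_deg: float) -> float:
    """Magnetic bearing from the turning point to the owner."""
    i = exc.turning_point_index
    if i is None:
        raise ValueError("turning point not located")
    bearing = true_bearing(exc.track.x[i], exc.track.y[i],
                           exc.owner_pos[0], exc.owner_pos[1])
    return magnetic_bearing(bearing, declination_deg)


def extract_compass_run(exc: Excursion, declination_deg: float,
                        cfg: AnalysisConfig = DEFAULT_CONFIG,
                        start_index: int | None = None,
                        end_index: int | None = None) -> CompassRun:
    """Walk the inbound track until the first sustained >20 deg deflection.

    From the start fix (the turning point by default), each candidate fix
    k >= start+2 is tested: the run ends at the first k where the step
    heading k -> k+1 deviates from the chord bearing start -> k by more
    than the deflection threshold *and* the deviation persists at the
    next fix (ruling out one-point jiggles around obstacles).  The run
    azimuth is the magnetic chord bearing start -> k; its length is
    measured along the track.  If no sustained deflection occurs the run
    spans the whole inbound track (logged, not an error).

    Candidates closer than ``min_heading_chord_m`` (straight-line) to the
    run start are skipped: below a few times the GPS error the track has
    no resolvable direction, and fixes recorded while the dog stands at
    the turning point would otherwise terminate the run with a purely
    noise-generated "deflection".
    """
    s = exc.turning_point_index if start_index is None else start_index
    e = (exc.n_points - 1) if end_index is None else end_index
    if s is None:
        raise ValueError("turning point not located")
    if e - s < 2:
        raise ValueError("need at least 3 fixes after the run start")
    x, y = exc.track.x, exc.track.y

    def chord(k):
        if x[k] == x[s] and y[k] == y[s]:
            return np.nan
        return true_bearing(x[s], y[s], x[k], y[k])

    def heading(k):
        if x[k + 1] == x[k] and y[k + 1] == y[k]:
            return np.nan
        return true_bearing(x[k], y[k], x[k + 1], y[k + 1])

    def deflected(k, run_heading) -> bool:
        """Step k -> k+1 deviates >threshold from the run heading."""
        h = heading(k)
        if np.isnan(h):
            return False
        return abs(circular_difference(h, run_heading)) > cfg.deflection_deg

    end, terminated = e, False
    for k in range(s + 2, e):
        if np.hypot(x[k] - x[s], y[k] - y[s]) < cfg.min_heading_chord_m:
            continue
        run_heading = chord(k)
        if np.isnan(run_heading) or not deflected(k, run_heading):
            continue
        # "no immediate return": the next fix(es) must still deviate from
        # the run heading established up to the deflection point
        persist = range(k + 1, min(k + 1 + cfg.persistence_points, e))
        if all(deflected(m, run_heading) for m in persist):
            end, terminated = k, True
            break
    if not terminated:
        logger.info("trial %s: no sustained deflection; compass run spans "
                    "the whole inbound track", exc.trial_id)
    c = chord(end)
    if np.isnan(c):
        raise ValueError("compass run has zero chord; azimuth undefined")
    if cfg.run_length_as_chord:
        length = float(np.hypot(x[end] - x[s], y[end] - y[s]))
    else:
        length = float(exc.cum[end] - exc.cum[s])
    return CompassRun(magnetic_bearing(c, declination_deg), length,
                      end, terminated)


def azimuth_set(exc: Excursion, declination_deg: float,
                cfg: AnalysisConfig = DEFAULT_CONFIG) -> AzimuthSet:
    """All three azimuths of an excursion (single-strategy returns)."""
    run = extract_compass_run(exc, declination_deg, cfg)
    return AzimuthSet(azimuth_a(exc, declination_deg, cfg),
                      azimuth_b(exc, declination_deg),
                      run.azimuth_deg, run.length_m, run.end_index)
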