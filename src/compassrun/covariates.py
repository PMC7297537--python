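"""Sun-azimuth reference frame and wind-suitability covariates.

The sun analysis asks whether compass runs track the sun rather than
the magnetic field: a monthly/hourly table of solar azimuths (15th day
of each month, daylight hours, at a fixed reference location) provides
the reference frame, and each run azimuth is re-expressed relative to
the sun position at the nearest whole hour.

The wind analysis asks whether scouting returns could be explained by
olfactory piloting: the wind is *suitable* when it blows from the owner
toward the dog at the turning point, i.e. when the direction the wind
comes from lies within +-22.5 degrees of azimuth B.  Wind directions
use the meteorological "from" convention.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import logging
import math

import numpy as np
import pandas as pd

from .config import SunConfig
from .geometry import circular_difference

logger = logging.getLogger(__name__)


def _solar_declination_rad(frac_year_rad: float) -> float:
    """Fourier-series solar declination (radians), good to ~0.3 deg."""
    g = frac_year_rad
    return (0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
            - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
            - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g))


def sun_azimuth(month: int, hour: float, lat: float,
                lon: float = 0.0) -> float | None:
    """Solar azimuth (degrees true, clockwise from north) or None at night.

    Computed for the 15th day of ``month`` at local *solar* hour
    ``hour`` (solar noon = 12), latitude ``lat``.  Longitude does not
    enter once time is expressed as local solar time; the parameter is
    kept so call sites can carry the reference location around.
    """
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    doy = _dt.date(2015, month, 15).timetuple().tm_yday
    g = 2.0 * math.pi * (doy - 1 + (hour - 12.0) / 24.0) / 365.0
    decl = _solar_declination_rad(g)
    phi = math.radians(lat)
    h = math.radians(15.0 * (hour - 12.0))        # hour angle
    sin_alt = (math.sin(phi) * math.sin(decl)
               + math.cos(phi) * math.cos(decl) * math.cos(h))
    if sin_alt <= 0.0:
        return None                               # sun below horizon
    alt = math.asin(sin_alt)
    sin_az = -math.cos(decl) * math.sin(h) / math.cos(alt)
    cos_az = ((math.sin(decl) - sin_alt * math.sin(phi))
              / (math.cos(alt) * math.cos(phi)))
    return math.degrees(math.atan2(sin_az, cos_az)) % 360.0


def build_sun_table(cfg: SunConfig | None = None) -> dict[tuple[int, int], float]:
    """Monthly/hourly solar-azimuth table, daylight hours only.

    Keys are (month, whole hour of local solar time); values degrees
    true.
    """
    cfg = cfg or SunConfig()
    table: dict[tuple[int, int], float] = {}
    for month in range(1, 13):
        for hour in range(24):
            az = sun_azimuth(month, float(hour), cfg.ref_lat, cfg.ref_lon)
            if az is not None:
                table[(month, hour)] = az
    return table


def sun_table_frame(table: dict[tuple[int, int], float]) -> pd.DataFrame:
    """The sun table as a tidy DataFrame (month, hour, azimuth_deg)."""
    rows = [{"month": m, "hour": h, "sun_azimuth_deg": az}
            for (m, h), az in sorted(table.items())]
    return pd.DataFrame(rows)


def relative_to_sun(azimuth_c_mag: float, declination_deg: float,
                    month: int, hour: float,
                    table: dict[tuple[int, int], float]) -> float | None:
    """Compass-run azimuth re-expressed relative to the sun position.

    The magnetic run azimuth is converted to true (adding the trial's
    declination) and the solar azimuth at the nearest whole hour is
    subtracted.  Night-time trials (no table entry) return None and are
    logged as excluded.
    """
    key = (month, int(round(hour)) % 24)
    if key not in table:
        logger.info("no daylight sun azimuth for month=%d hour=%d; "
                    "excursion excluded from the sun analysis", *key)
        return None
    true_az = (azimuth_c_mag + declination_deg) % 360.0
    return (true_az - table[key]) % 360.0


def wind_bin_center(wind_from_deg: float) -> int:
    """Nearest of the eight 45-degree bin centres (0, 45, ..., 315)."""
    return int(round((wind_from_deg % 360.0) / 45.0) % 8) * 45


def wind_suitable(azimuth_b_deg: float, wind_from_deg: float | None,
                  half_width_deg: float = 22.5) -> bool | None:
    """Is the wind suitable for olfactory piloting toward the owner?

    Air moving from the owner to the dog arrives *from* the owner's
    bearing as seen from the dog, i.e. from azimuth B.  Returns None
    (not assessable) when no wind was detected.
    """
    if wind_from_deg is None:
        return None
    return bool(abs(circular_difference(wind_from_deg, azimuth_b_deg))
                <= half_width_deg)


def month_name(month: int) -> str:
    return calendar.month_abbr[month]
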