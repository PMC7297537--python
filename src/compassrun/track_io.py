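"""Reading and writing GPS tracks (GPX 1.1) and trial metadata tables.

A *trial* pairs one dog track with one owner track plus field metadata
(dog identity, site, wind, date-time, magnetic declination).  Tracks are
stored with times in seconds since the first fix; the absolute UTC time
of the first fix is kept so that the sun analysis can recover local time.

Metadata lives in a UTF-8 CSV with one row per trial; an empty wind cell
means "no wind detected" (which is not the same as wind from 0 degrees).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GPX_NS = "http://www.topografix.com/GPX/1/1"

#: CSV columns expected by :func:`read_trial_table`
TRIAL_COLUMNS = [
    "trial_id", "dog_id", "sex", "breed", "shoulder_height_cm", "site_id",
    "familiarity", "wind_from_deg", "wind_speed_ms", "datetime_local",
    "utc_offset_hours", "declination_deg", "dog_gpx", "owner_gpx",
]


class GpxFormatError(ValueError):
    """The file is not a usable GPX 1.1 track (e.g. missing timestamps)."""


class TrackValidationError(ValueError):
    """Track content violates an invariant (e.g. non-monotone times)."""


@dataclass
class Track:
    """A timestamped GPS track.

    time: seconds since the first point (strictly increasing, >= 2 points);
    lat/lon: WGS84 degrees; nominal_interval: programmed fix interval (s);
    start_time: UTC datetime of the first fix, if known.
    """

    time: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    nominal_interval: float = 5.0
    start_time: _dt.datetime | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        validate_track(self)

    def __len__(self) -> int:
        return len(self.time)


def validate_track(track: Track) -> None:
    t, lat, lon = track.time, track.lat, track.lon
    if len(t) < 2:
        raise TrackValidationError("track needs at least 2 points")
    if not (len(t) == len(lat) == len(lon)):
        raise TrackValidationError("time/lat/lon arrays must have equal length")
    if not np.all(np.isfinite(t)):
        raise TrackValidationError("non-finite timestamps")
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TrackValidationError(
            f"times not strictly increasing at point index {int(bad[0]) + 1}"
        )
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise TrackValidationError("latitude/longitude out of range")
    gaps = np.nonzero(np.diff(t) > 3.0 * track.nominal_interval)[0]
    for g in gaps:
        logger.warning(
            "gap of %.1f s (> 3x nominal interval) after point %d",
            t[g + 1] - t[g], int(g),
        )


@dataclass
class TrialRecord:
    """One homing trial: a dog track, the owner's track, and metadata."""

    trial_id: str
    dog_id: str
    sex: str
    breed: str
    shoulder_height_cm: float
    site_id: str
    familiarity: str                 # "familiar" | "unfamiliar"
    wind_from_deg: float | None      # magnetic, direction wind blows FROM
    wind_speed_ms: float | None
    datetime_local: _dt.datetime | None
    utc_offset_hours: float
    declination_deg: float
    dog_track: Track = field(repr=False, default=None)
    owner_track: Track = field(repr=False, default=None)

    def __post_init__(self):
        if self.wind_from_deg is not None and not (
            0.0 <= self.wind_from_deg < 360.0
        ):
            raise ValueError(
                f"trial {self.trial_id}: wind_from_deg {self.wind_from_deg} "
                "outside [0, 360)"
            )
        if not np.isfinite(self.declination_deg):
            raise ValueError(f"trial {self.trial_id}: non-finite declination")


def _parse_gpx_time(text: str) -> _dt.datetime:
    text = text.strip()
    if text.endswith("Z"):
        text = text[:-1] + "+00:00"
    t = _dt.datetime.fromisoformat(text)
    if t.tzinfo is None:
        t = t.replace(tzinfo=_dt.timezone.utc)
    return t.astimezone(_dt.timezone.utc)


def read_gpx(path) -> Track:
    """Read a GPX 1.1 file into a :class:`Track`.

    All track segments are concatenated in time order; times become
    seconds since the first fix.  Fractional-second timestamps are kept.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise GpxFormatError(f"{path}: not parseable XML: {exc}") from exc
    ns = {"g": GPX_NS}
    pts = root.findall(".//g:trk/g:trkseg/g:trkpt", ns)
    if not pts:
        # tolerate un-namespaced GPX from simple writers
        pts = root.findall(".//trk/trkseg/trkpt")
        ns = None
    if not pts:
        raise GpxFormatError(f"{path}: no track points found")
    times, lats, lons = [], [], []
    for pt in pts:
        el = pt.find("g:time", ns) if ns else pt.find("time")
        if el is None or not el.text:
            raise GpxFormatError(f"{path}: track point without timestamp")
        times.append(_parse_gpx_time(el.text))
        lats.append(float(pt.get("lat")))
        lons.append(float(pt.get("lon")))
    order = np.argsort([t.timestamp() for t in times], kind="stable")
    times = [times[i] for i in order]
    lats = np.asarray(lats)[order]
    lons = np.asarray(lons)[order]
    t0 = times[0]
    rel = np.array([(t - t0).total_seconds() for t in times])
    if len(rel) >= 3:
        nominal = 2.5 if np.median(np.diff(rel)) < 3.75 else 5.0
    else:
        nominal = 5.0
    return Track(rel, lats, lons, nominal_interval=nominal, start_time=t0)


def write_gpx(track: Track, path, name: str = "track") -> None:
    """Write a :class:`Track` as GPX 1.1 (coordinates to 1e-7 degrees)."""
    t0 = track.start_time or _dt.datetime(2015, 6, 15, 10, 0,
                                          tzinfo=_dt.timezone.utc)
    root = ET.Element("gpx", version="1.1", creator="compassrun",
                      xmlns=GPX_NS)
    trk = ET.SubElement(root, "trk")
    ET.SubElement(trk, "name").text = name
    seg = ET.SubElement(trk, "trkseg")
    for dt_s, lat, lon in zip(track.time, track.lat, track.lon):
        pt = ET.SubElement(seg, "trkpt",
                           lat=f"{lat:.7f}", lon=f"{lon:.7f}")
        stamp = t0 + _dt.timedelta(seconds=float(dt_s))
        ET.SubElement(pt, "time").text = (
            stamp.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"
        )
    ET.ElementTree(root).write(path, encoding="unicode",
                               xml_declaration=True)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    return float(s)


def read_trial_table(path) -> list[TrialRecord]:
    """Read a trial metadata CSV and load every referenced GPX track.

    GPX paths are resolved relative to the CSV's directory.  Unreadable
    files are collected and reported together in a single error.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    base = path.parent
    records, failures = [], []
    for _, row in table.iterrows():
        try:
            dog_track = read_gpx(base / row["dog_gpx"])
            owner_track = read_gpx(base / row["owner_gpx"])
            when = row["datetime_local"].strip()
            records.append(TrialRecord(
                trial_id=row["trial_id"],
                dog_id=row["dog_id"],
                sex=row["sex"],
                breed=row["breed"],
                shoulder_height_cm=float(row["shoulder_height_cm"]),
                site_id=row["site_id"],
                familiarity=row["familiarity"],
                wind_from_deg=_opt_float(row["wind_from_deg"]),
                wind_speed_ms=_opt_float(row["wind_speed_ms"]),
                datetime_local=_dt.datetime.fromisoformat(when) if when else None,
                utc_offset_hours=float(row["utc_offset_hours"] or 0.0),
                declination_deg=float(row["declination_deg"] or 0.0),
                dog_track=dog_track,
                owner_track=owner_track,
            ))
        except (OSError, ValueError, GpxFormatError) as exc:
            failures.append(f"trial {row.get('trial_id', '?')}: {exc}")
    if failures:
        raise ValueError(
            "failed to load {} trial(s):\n  {}".format(
                len(failures), "\n  ".join(failures))
        )
    return records
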