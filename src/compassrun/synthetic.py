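"""Synthetic homing trials with ground truth.

Each trial emulates the field protocol: the owner walks a slow
meandering path with the dog nearby; the dog breaks away on a
correlated random walk (a game pursuit); when the separation first
reaches 100 m the owner freezes (the excursion start / goal); the dog
continues outbound, pauses at the turning point, performs a short
*compass run* whose axial direction is drawn from a doubled-angle von
Mises distribution, and returns by one of three strategies:

* tracking  — retraces the outbound track with smooth lateral error,
* scouting  — takes a novel route via a laterally offset waypoint,
  kept at least 60 m from the outbound track over its middle portion,
* combined  — retraces part-way, then switches to scouting.

Isotropic Gaussian GPS noise is added per coordinate (default
4.2/sqrt(2) m, so the 2-D RMS position error matches the +-4.2 m
receiver accuracy), and tracks are emitted as GPX plus metadata and
truth tables, consumed unchanged by the analysis pipeline.
"""

from __future__ import annotations

import datetime as _dt
import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (LocalFrame, circular_difference,
                       cumulative_path, points_to_polyline_distances,
                       true_bearing)
from .track_io import Track, TrialRecord, write_gpx

__all__ = ["SimConfig", "SimTruth", "GenerationError",
           "simulate_trial", "simulate_dataset", "write_dataset"]


class GenerationError(RuntimeError):
    """No feasible trial geometry found within the attempt budget."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the field study where it states a value (sampling
    rate, GPS accuracy, strategy frequencies, 18.1 m mean compass run)
    and plausible movement parameters where it does not.
    """

    n_trials: int = 50
    n_dogs: int = 10
    sampling_interval: float = 5.0        # s (2.5 or 5.0)
    gps_noise_sigma: float = 4.2 / math.sqrt(2)   # m per coordinate
    outbound_speed: float = 2.0           # m/s
    inbound_speed: float = 2.5            # m/s
    p_tracking: float = 0.60
    p_scouting: float = 0.32
    p_combined: float = 0.08
    axis_mu: float = 0.0                  # magnetic N-S axis
    kappa_axial: float = 1.5              # von Mises kappa on doubled angles
    run_length_mean: float = 18.1         # m
    run_length_sd: float = 6.0            # m
    turning_pause: float = 60.0           # s of stationarity at the turn
    scouting_heading_noise_sd: float = 12.0   # deg per step
    outbound_heading_sd: float = 15.0     # deg per step (wrapped normal)
    tracking_lateral_sd: float = 8.0      # m, AR(1) lateral retrace error
    declination: float = 0.0              # deg east
    p_no_wind: float = 0.22
    site_lat: float = 49.8
    site_lon: float = 15.5
    seed: int = 0

    def __post_init__(self):
        total = self.p_tracking + self.p_scouting + self.p_combined
        if abs(total - 1.0) > 1e-9:
            raise ValueError("strategy probabilities must sum to 1")
        if self.kappa_axial < 0:
            raise ValueError("kappa_axial must be >= 0")
        if min(self.outbound_speed, self.inbound_speed) <= 0:
            raise ValueError("speeds must be positive")


@dataclass
class SimTruth:
    """Ground truth for one simulated trial (clean geometry, planar
    coordinates in the dataset's local frame)."""

    trial_id: str
    dog_id: str
    strategy: str
    open_index: int            # sample index where separation first >= 100 m
    open_time: float
    owner_x: float
    owner_y: float
    turning_index: int         # first stationary sample at the turning point
    turning_time: float
    run_azimuth_mag: float     # drawn compass-run direction, deg magnetic
    run_length_m: float        # realised clean run length
    switch_time: float | None  # combined returns: tracking->scouting switch
    ref_lat: float
    ref_lon: float


# movement constants of the emulated protocol (not analysis thresholds)
_OWNER_SPEED = 1.0             # m/s while walking
_PRE_WALK_S = (40.0, 80.0)     # owner+dog walk before the pursuit starts
_OUT_PATH_M = (280.0, 450.0)   # outbound path beyond the excursion start
_OUT_PATH_COMBINED_M = (470.0, 650.0)
_MIN_BEELINE = {"tracking": 150.0, "scouting": 220.0, "combined": 320.0}
_VIA_OFFSET_M = (70.0, 120.0)  # lateral via-point offset for scouting
_SCOUT_CLEAR_MID_M = 60.0      # min distance to outbound, middle portion
_SCOUT_CLEAR_M = 35.0          # min distance elsewhere (outside skip zones)
_DWELL_S = 60.0                # wandering near the owner after arrival


def _crw(rng, start, heading0, n, speed, dt, sigma_deg):
    """Correlated random walk: wrapped-normal heading increments."""
    inc = rng.normal(0.0, math.radians(sigma_deg), n)
    h = math.radians(heading0) + np.cumsum(inc)
    steps = speed * dt
    x = start[0] + np.cumsum(steps * np.sin(h))
    y = start[1] + np.cumsum(steps * np.cos(h))
    return np.column_stack([x, y]), math.degrees(h[-1]) % 360.0


def _walk_to(rng, start, waypoints, speed, dt, noise_sd, max_steps=3000):
    """Step toward successive waypoints with heading noise; the final
    waypoint is approached exactly (last step lands on it)."""
    pos = np.asarray(start, float).copy()
    out = []
    step = speed * dt
    for wi, wp in enumerate(waypoints):
        tol = 15.0 if wi < len(waypoints) - 1 else 0.0
        while True:
            d = math.hypot(wp[0] - pos[0], wp[1] - pos[1])
            if d <= max(tol, step):
                if tol == 0.0:
                    pos = np.asarray(wp, float).copy()
                    out.append(pos.copy())
                break
            bearing = math.atan2(wp[0] - pos[0], wp[1] - pos[1])
            bearing += rng.normal(0.0, math.radians(noise_sd))
            pos = pos + step * np.array([math.sin(bearing),
                                         math.cos(bearing)])
            out.append(pos.copy())
            if len(out) > max_steps:
                raise GenerationError("inbound walk did not converge")
    return np.array(out) if out else np.empty((0, 2))


def _resample_polyline(points, spacing):
    """Points every ``spacing`` metres along a polyline (excludes the
    start point, includes the end)."""
    cum = cumulative_path(points[:, 0], points[:, 1])
    targets = np.arange(spacing, cum[-1], spacing)
    x = np.interp(targets, cum, points[:, 0])
    y = np.interp(targets, cum, points[:, 1])
    res = np.column_stack([x, y])
    return np.vstack([res, points[-1]])


def _lateral_ar1(rng, n, sd, rho=0.8, clip=22.0):
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * math.sqrt(1 - rho * rho), n - 1)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov[i - 1]
    return np.clip(out, -clip, clip)


def _offset_laterally(path, offsets, taper_tail_m=60.0):
    """Displace a path perpendicular to its local direction; offsets are
    tapered to zero over the final stretch so the path still converges."""
    d = np.gradient(path, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    norm[norm == 0] = 1.0
    perp = np.column_stack([-d[:, 1] / norm, d[:, 0] / norm])
    cum = cumulative_path(path[:, 0], path[:, 1])
    to_go = cum[-1] - cum
    ramp = np.clip(to_go / taper_tail_m, 0.0, 1.0)
    return path + perp * (offsets * ramp)[:, None]


def _draw_run(rng, cfg: SimConfig):
    """Axial compass-run direction (deg true) and length (m)."""
    doubled = rng.vonmises(math.radians(2.0 * cfg.axis_mu), cfg.kappa_axial)
    axis = (math.degrees(doubled) / 2.0) % 180.0
    direction = (axis + (180.0 if rng.random() < 0.5 else 0.0)) % 360.0
    length = max(5.0, rng.normal(cfg.run_length_mean, cfg.run_length_sd))
    return direction, length


def _scout_clearance_ok(sub_path, outbound_poly):
    """Clearance checks for a scouting (sub-)path against the outbound
    track: >= 60 m over the middle 25-75 %, >= 35 m everywhere outside
    an 80 m head and 55 m tail (those stretches are shorter than the
    classifier's run-merging length and cannot flip the label)."""
    cum = cumulative_path(sub_path[:, 0], sub_path[:, 1])
    total = cum[-1]
    if total <= 0:
        return False
    dist = points_to_polyline_distances(sub_path[:, 0], sub_path[:, 1],
                                        outbound_poly[:, 0],
                                        outbound_poly[:, 1])
    mid = (cum >= 0.25 * total) & (cum <= 0.75 * total)
    if mid.any() and dist[mid].min() < _SCOUT_CLEAR_MID_M:
        return False
    body = (cum >= 80.0) & (total - cum >= 55.0)
    return not (body.any() and dist[body].min() < _SCOUT_CLEAR_M)


def _scout_leg(rng, cfg, start, goal, run_dir, run_len, outbound_poly):
    """Compass run + novel route to the goal.

    The via-point offset is built from the outbound track's actual
    lateral extent relative to the chord (run end -> goal), so the novel
    route clears the outbound track by construction; a final clearance
    check guards the rare residual failures.
    Returns (points, realised_run_len)."""
    dt, v = cfg.sampling_interval, cfg.inbound_speed
    k_steps = max(1, round(run_len / (v * dt)))
    run_vec = np.array([math.sin(math.radians(run_dir)),
                        math.cos(math.radians(run_dir))])
    run_pts = start + run_vec * (v * dt) * np.arange(1, k_steps + 1)[:, None]
    q = run_pts[-1]
    realised = k_steps * v * dt
    mid = 0.5 * (q + goal)
    u = goal - q
    nrm = math.hypot(u[0], u[1])
    if nrm < 1.0:
        raise GenerationError("goal too close to the compass-run end")
    u_hat = u / nrm
    perp = np.array([-u_hat[1], u_hat[0]])
    # lateral extent of the outbound track on each side of the chord
    w = outbound_poly - q
    along = w @ u_hat
    lat = w @ perp
    span = (along > -60.0) & (along < nrm + 60.0)
    ext_pos = float(lat[span].max(initial=0.0))
    ext_neg = float(-lat[span].min(initial=0.0))
    sides = [1.0, -1.0] if ext_pos <= ext_neg else [-1.0, 1.0]
    for attempt in range(30):
        for side in sides:
            ext = ext_pos if side > 0 else ext_neg
            d = ext + rng.uniform(*_VIA_OFFSET_M) + 20.0 * attempt
            via = mid + side * d * perp
            # the course change ending the run must be unambiguous w.r.t.
            # the >20 deg criterion under heading/GPS noise
            turn = abs(circular_difference(
                true_bearing(q[0], q[1], via[0], via[1]), run_dir))
            if turn < 45.0:
                continue
            # the course change ending the run is a deliberate manoeuvre:
            # its first two steps head exactly for the via point
            via_hat = (via - q) / math.hypot(*(via - q))
            clean = q + via_hat * (v * dt) * np.array([[1.0], [2.0]])
            try:
                walk = _walk_to(rng, clean[-1], [via, goal], v, dt,
                                cfg.scouting_heading_noise_sd)
            except GenerationError:
                continue
            pts = np.vstack([run_pts, clean, walk])
            if _scout_clearance_ok(np.vstack([[start], pts]), outbound_poly):
                return pts, realised
    raise GenerationError("no clear scouting route found")


def _simulate_clean(rng, cfg: SimConfig, strategy: str,
                    run_dir: float, run_len: float):
    """One attempt at the clean (noise-free) trial geometry.

    Returns (dog_xy, owner_xy, truth_fields) or None if infeasible.
    """
    dt = cfg.sampling_interval

    # --- owner + dog walk together, then the dog breaks away
    n_pre = max(2, round(rng.uniform(*_PRE_WALK_S) / dt))
    owner_pre, owner_heading = _crw(rng, (0.0, 0.0), rng.uniform(0, 360),
                                    n_pre, _OWNER_SPEED, dt, 10.0)
    dog_pre = owner_pre + rng.normal(0.0, 2.0, owner_pre.shape)

    out_range = (_OUT_PATH_COMBINED_M if strategy == "combined"
                 else _OUT_PATH_M)
    out_path_target = rng.uniform(*out_range)
    # enough steps to build 100 m of separation and then the outbound path
    n_out = int((out_path_target + 400.0) / (cfg.outbound_speed * dt)) + 10
    dog_out, _ = _crw(rng, dog_pre[-1], rng.uniform(0, 360), n_out,
                      cfg.outbound_speed, dt, cfg.outbound_heading_sd)
    owner_out, _ = _crw(rng, owner_pre[-1], owner_heading, n_out,
                        _OWNER_SPEED, dt, 10.0)
    sep = np.hypot(*(dog_out - owner_out).T)
    over = np.nonzero(sep >= 100.0)[0]
    if over.size == 0:
        return None
    i_free = int(over[0])
    owner_out[i_free:] = owner_out[i_free]          # owner freezes
    goal = owner_out[i_free].copy()
    owner_walk = owner_out

    cum = cumulative_path(dog_out[:, 0], dog_out[:, 1])
    past = np.nonzero(cum - cum[i_free] >= out_path_target)[0]
    if past.size == 0:
        return None
    i_turn = int(past[0])
    dog_out = dog_out[: i_turn + 1]
    turn_pt = dog_out[-1]
    if math.hypot(*(turn_pt - goal)) < _MIN_BEELINE[strategy]:
        return None
    # the outbound must not graze the goal after opening
    mid_d = np.hypot(*(dog_out[i_free + 1:] - goal).T)
    if mid_d.size and mid_d.min() < 20.0:
        return None

    n_pause = max(1, round(cfg.turning_pause / dt))
    pause = np.tile(turn_pt, (n_pause, 1))

    outbound_poly = dog_out[i_free:]                # excursion outbound
    v, dtv = cfg.inbound_speed, cfg.sampling_interval
    realised_run = float("nan")
    switch_steps = None

    if strategy == "scouting":
        inbound, realised_run = _scout_leg(rng, cfg, turn_pt, goal,
                                           run_dir, run_len, outbound_poly)
    else:
        centreline = np.vstack([outbound_poly[::-1], goal])
        resampled = _resample_polyline(centreline, v * dtv)
        if strategy == "tracking":
            offs = _lateral_ar1(rng, len(resampled), cfg.tracking_lateral_sd)
            inbound = _offset_laterally(resampled, offs)
            # the chord start->goal direction is the truth "run" direction
            realised_run = float("nan")
        else:                                       # combined
            rcum = cumulative_path(resampled[:, 0], resampled[:, 1])
            frac = rng.uniform(0.35, 0.55)
            k_switch = int(np.searchsorted(rcum, frac * rcum[-1]))
            k_switch = min(max(k_switch, 2), len(resampled) - 2)
            track_part = resampled[: k_switch + 1]
            offs = _lateral_ar1(rng, len(track_part),
                                cfg.tracking_lateral_sd)
            track_part = _offset_laterally(track_part, offs,
                                           taper_tail_m=1e-9)
            switch_pt = track_part[-1]
            if math.hypot(*(switch_pt - goal)) < 180.0:
                return None
            scout_part, realised_run = _scout_leg(
                rng, cfg, switch_pt, goal, run_dir, run_len, outbound_poly)
            inbound = np.vstack([track_part, scout_part])
            switch_steps = len(track_part)

    n_dwell = max(2, round(_DWELL_S / dt))
    dwell = goal + rng.normal(0.0, 1.5, (n_dwell, 2))

    dog = np.vstack([dog_pre, dog_out, pause, inbound, dwell])
    n_total = len(dog)
    owner = np.vstack([owner_pre, owner_walk[: i_turn + 1],
                       np.tile(goal, (n_total - n_pre - i_turn - 1, 1))])

    open_idx = n_pre + i_free
    turn_idx = n_pre + i_turn                      # first stationary sample
    truth = {
        "open_index": open_idx,
        "owner_x": float(goal[0]), "owner_y": float(goal[1]),
        "turning_index": turn_idx,
        "run_length_m": realised_run,
        "switch_index": (None if switch_steps is None
                         else turn_idx + n_pause + switch_steps),
    }
    return dog, owner, truth


def simulate_trial(cfg: SimConfig, trial_seed, trial_id: str = "trial",
                   dog_id: str = "dog") -> tuple[TrialRecord, SimTruth]:
    """Generate one trial; deterministic in (cfg, trial_seed).

    The strategy label and the compass-run draw are fixed once per
    trial; geometric feasibility retries only redraw nuisance parts, so
    rejection cannot bias the axial distribution.
    """
    rng = np.random.default_rng(trial_seed)
    strategy = ["tracking", "scouting", "combined"][int(
        rng.choice(3, p=[cfg.p_tracking, cfg.p_scouting, cfg.p_combined]))]
    run_dir_true, run_len = _draw_run(rng, cfg)

    result = None
    for _ in range(100):
        try:
            result = _simulate_clean(rng, cfg, strategy, run_dir_true,
                                     run_len)
        except GenerationError:
            result = None
        if result is not None:
            break
    if result is None:
        raise GenerationError(f"{trial_id}: no feasible geometry in "
                              "100 attempts")
    dog, owner, truth = result

    dt = cfg.sampling_interval
    times = np.arange(len(dog)) * dt
    if cfg.gps_noise_sigma > 0:
        dog = dog + rng.normal(0.0, cfg.gps_noise_sigma, dog.shape)
        owner = owner + rng.normal(0.0, cfg.gps_noise_sigma, owner.shape)

    # site offset keeps trials distinct but within the local frame
    off = rng.uniform(-1500.0, 1500.0, 2)
    frame = LocalFrame(cfg.site_lat, cfg.site_lon)
    dog_lat, dog_lon = frame.unproject(dog[:, 0] + off[0], dog[:, 1] + off[1])
    ow_lat, ow_lon = frame.unproject(owner[:, 0] + off[0],
                                     owner[:, 1] + off[1])

    month = int(rng.integers(1, 13))
    hour = int(rng.integers(8, 16))
    start_local = _dt.datetime(2016, month, int(rng.integers(1, 29)),
                               hour, int(rng.integers(0, 60)))
    start_utc = (start_local - _dt.timedelta(hours=1)).replace(
        tzinfo=_dt.timezone.utc)
    wind = (None if rng.random() < cfg.p_no_wind
            else float(rng.uniform(0.0, 360.0)))
    owner_times = times[: len(owner)]

    record = TrialRecord(
        trial_id=trial_id,
        dog_id=dog_id,
        sex="F" if rng.random() < 0.63 else "M",
        breed=_BREEDS[zlib.crc32(dog_id.encode()) % len(_BREEDS)],
        shoulder_height_cm=float(20 + (zlib.crc32(dog_id.encode()) % 7) * 5),
        site_id=f"site{int(rng.integers(1, 63)):02d}",
        familiarity="familiar" if rng.random() < 0.5 else "unfamiliar",
        wind_from_deg=wind,
        wind_speed_ms=None if wind is None else float(rng.uniform(0.5, 8.0)),
        datetime_local=start_local,
        utc_offset_hours=1.0,
        declination_deg=cfg.declination,
        dog_track=Track(times, dog_lat, dog_lon, nominal_interval=dt,
                        start_time=start_utc),
        owner_track=Track(owner_times, ow_lat, ow_lon, nominal_interval=dt,
                          start_time=start_utc),
    )
    switch = truth["switch_index"]
    sim_truth = SimTruth(
        trial_id=trial_id, dog_id=dog_id, strategy=strategy,
        open_index=truth["open_index"],
        open_time=truth["open_index"] * dt,
        owner_x=truth["owner_x"] + off[0],
        owner_y=truth["owner_y"] + off[1],
        turning_index=truth["turning_index"],
        turning_time=truth["turning_index"] * dt,
        run_azimuth_mag=(run_dir_true - cfg.declination) % 360.0,
        run_length_m=truth["run_length_m"],
        switch_time=None if switch is None else switch * dt,
        ref_lat=cfg.site_lat, ref_lon=cfg.site_lon,
    )
    return record, sim_truth


_BREEDS = ["dachshund", "fox terrier", "jagdterrier", "beagle",
           "basset hound", "miniature schnauzer"]


def simulate_dataset(cfg: SimConfig
                     ) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Simulate ``cfg.n_trials`` trials, round-robin over the dogs.

    Per-trial seeds are spawned from ``numpy.random.SeedSequence
    (cfg.seed)``, so datasets are reproducible and trials independent.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trials)
    records, truths = [], []
    for i, child in enumerate(children):
        dog_id = f"dog{i % cfg.n_dogs + 1:02d}"
        rec, truth = simulate_trial(cfg, child, trial_id=f"trial{i + 1:04d}",
                                    dog_id=dog_id)
        records.append(rec)
        truths.append(truth.__dict__)
    return records, pd.DataFrame(truths)


def write_dataset(records: list[TrialRecord], truth: pd.DataFrame,
                  outdir) -> Path:
    """Write GPX tracks, the trial metadata CSV, and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        dog_file = f"{rec.trial_id}_dog.gpx"
        owner_file = f"{rec.trial_id}_owner.gpx"
        write_gpx(rec.dog_track, outdir / dog_file, name=f"{rec.trial_id} dog")
        write_gpx(rec.owner_track, outdir / owner_file,
                  name=f"{rec.trial_id} owner")
        rows.append({
            "trial_id": rec.trial_id, "dog_id": rec.dog_id, "sex": rec.sex,
            "breed": rec.breed,
            "shoulder_height_cm": rec.shoulder_height_cm,
            "site_id": rec.site_id, "familiarity": rec.familiarity,
            "wind_from_deg": ("" if rec.wind_from_deg is None
                              else f"{rec.wind_from_deg:.1f}"),
            "wind_speed_ms": ("" if rec.wind_speed_ms is None
                              else f"{rec.wind_speed_ms:.1f}"),
            "datetime_local": rec.datetime_local.isoformat(),
            "utc_offset_hours": rec.utc_offset_hours,
            "declination_deg": rec.declination_deg,
            "dog_gpx": dog_file, "owner_gpx": owner_file,
        })
    pd.DataFrame(rows).to_csv(outdir / "trials.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)
    return outdir
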