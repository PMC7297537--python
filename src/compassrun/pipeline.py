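"""End-to-end analysis pipeline: trials in, tables and summaries out.

For every trial the pipeline projects both tracks into a local planar
frame, detects excursions, locates the turning trajectory and turning
point, measures azimuths A/B/C, classifies the return strategy (with
sub-track splitting for combined returns), and computes speed and
homing-efficiency metrics.  Results are collected into two tidy tables
— one row per excursion, one row per (excursion, strategy sub-track) —
plus dataset-level circular statistics.  Identical inputs and
configuration yield identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import azimuths as az
from . import metrics
from .circstats import CircularSample, rayleigh_test
from .config import DEFAULT_CONFIG, AnalysisConfig, SunConfig
from .covariates import build_sun_table, relative_to_sun, sun_table_frame, \
    wind_suitable
from .geometry import LocalFrame, PlanarTrack
from .segmentation import analyze_excursion, detect_excursions
from .strategy import StrategyLabel, classify_excursion
from .track_io import TrialRecord, read_trial_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    excursions: pd.DataFrame
    subtracks: pd.DataFrame
    summary: dict
    n_trials: int
    config: AnalysisConfig = field(default=DEFAULT_CONFIG)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.excursions.to_csv(outdir / "excursions.csv", index=False)
        self.subtracks.to_csv(outdir / "subtracks.csv", index=False)
        circ_rows = []
        for name, res in self.summary.get("rayleigh", {}).items():
            circ_rows.append({
                "sample": name, "n": res.n, "mu": res.mu, "r": res.r,
                "z": res.z, "p": res.p, "axial": res.axial})
        pd.DataFrame(circ_rows).to_csv(outdir / "circular_stats.csv",
                                       index=False)
        (outdir / "summary.txt").write_text(format_summary(self))
        return outdir


def make_frame(records: list[TrialRecord]) -> LocalFrame:
    """Local frame centred on the mean first-fix position."""
    lat = float(np.mean([r.dog_track.lat[0] for r in records]))
    lon = float(np.mean([r.dog_track.lon[0] for r in records]))
    return LocalFrame(lat, lon)


def analyze_trial(record: TrialRecord, frame: LocalFrame,
                  cfg: AnalysisConfig = DEFAULT_CONFIG) -> list[dict]:
    """Analyse one trial; returns one result dict per kept excursion.

    Each dict has an "excursion" row, a list of "subtrack" rows, and
    the underlying Excursion object.
    """
    dx, dy = frame.project(record.dog_track.lat, record.dog_track.lon)
    ox, oy = frame.project(record.owner_track.lat, record.owner_track.lon)
    dog = PlanarTrack(record.dog_track.time, dx, dy)
    owner = PlanarTrack(record.owner_track.time, ox, oy)
    decl = record.declination_deg
    results = []
    for k, exc in enumerate(detect_excursions(
            dog, owner, cfg, trial_id=record.trial_id,
            dog_id=record.dog_id)):
        analyze_excursion(exc, cfg)
        label, segments = classify_excursion(exc, cfg)
        try:
            azimuth_a = az.azimuth_a(exc, decl, cfg)
        except az.MissingFixError as exc_err:
            logger.warning("trial %s: %s", record.trial_id, exc_err)
            azimuth_a = np.nan
        azimuth_b = az.azimuth_b(exc, decl)
        eff = metrics.homing_efficiency(exc)
        exc_id = f"{record.trial_id}#{k + 1}"
        when = record.datetime_local
        row = {
            "excursion_id": exc_id,
            "trial_id": record.trial_id,
            "dog_id": record.dog_id,
            "sex": record.sex,
            "familiarity": record.familiarity,
            "start_index": exc.start_index,
            "end_index": exc.end_index,
            "start_time_s": float(exc.track.time[0]),
            "total_length_m": exc.total_length,
            "turning_segment": exc.turning_segment,
            "turning_index": exc.start_index + exc.turning_point_index,
            "turning_time_s": float(
                exc.track.time[exc.turning_point_index]),
            "azimuth_a": azimuth_a,
            "azimuth_b": azimuth_b,
            "strategy": label.value,
            "n_subtracks": len(segments.subtracks),
            "inbound_speed_kmh": metrics.inbound_speed_kmh(exc),
            "inbound_length_m": eff.inbound_length_m,
            "beeline_m": eff.beeline_m,
            "efficiency_pct": eff.index_pct,
            "wind_from_deg": record.wind_from_deg,
            "wind_suitable": wind_suitable(azimuth_b, record.wind_from_deg,
                                           cfg.wind_half_width_deg),
            "month": when.month if when else None,
            "hour": when.hour if when else None,
            "declination_deg": decl,
        }
        subs = []
        if label is StrategyLabel.COMBINED:
            pieces = [(sub, s, e) for sub, s, e in segments.subtracks]
        else:
            pieces = [(label, exc.turning_point_index, exc.n_points - 1)]
        for si, (sub_label, s, e) in enumerate(pieces):
            start = exc.turning_point_index if si == 0 else s
            try:
                run = az.extract_compass_run(exc, decl, cfg,
                                             start_index=start,
                                             end_index=exc.n_points - 1
                                             if si == len(pieces) - 1 else e)
            except ValueError as err:
                logger.warning("trial %s subtrack %d: %s",
                               record.trial_id, si, err)
                continue
            subs.append({
                "excursion_id": exc_id,
                "trial_id": record.trial_id,
                "dog_id": record.dog_id,
                "sub_index": si,
                "sub_strategy": sub_label.value,
                "start_index": start,
                "end_index": e,
                "azimuth_c": run.azimuth_deg,
                "run_length_m": run.length_m,
                "run_terminated": run.terminated,
                "sector": az.sector_of(run.azimuth_deg).value,
                "axis": az.axis_of(run.azimuth_deg).value,
            })
        results.append({"excursion": row, "subtracks": subs,
                        "object": exc})
    return results


def run_pipeline(records: list[TrialRecord],
                 cfg: AnalysisConfig = DEFAULT_CONFIG) -> PipelineResult:
    """Analyse a full dataset of trials."""
    if not records:
        raise ValueError("no trials to analyse")
    frame = make_frame(records)
    exc_rows, sub_rows = [], []
    for record in records:
        for res in analyze_trial(record, frame, cfg):
            exc_rows.append(res["excursion"])
            sub_rows.extend(res["subtracks"])
    excursions = pd.DataFrame(exc_rows)
    sub_cols = ["excursion_id", "trial_id", "dog_id", "sub_index",
                "sub_strategy", "start_index", "end_index", "azimuth_c",
                "run_length_m", "run_terminated", "sector", "axis"]
    subtracks = (pd.DataFrame(sub_rows) if sub_rows
                 else pd.DataFrame(columns=sub_cols))
    if excursions.empty:
        raise ValueError("no excursions detected in any trial")
    summary = metrics.summarize_dataset(excursions, subtracks, len(records))
    return PipelineResult(excursions, subtracks, summary, len(records), cfg)


def run_from_dir(data_dir, cfg: AnalysisConfig = DEFAULT_CONFIG
                 ) -> PipelineResult:
    """Load a dataset directory (trials.csv + GPX files) and analyse it."""
    return run_pipeline(read_trial_table(Path(data_dir) / "trials.csv"), cfg)


def sun_relative_azimuths(result: PipelineResult,
                          sun_cfg: SunConfig | None = None) -> pd.DataFrame:
    """Scouting compass runs re-expressed relative to the sun position.

    Joins each scouting sub-track with the trial's month/hour and the
    monthly/hourly sun table; night-time or unterminated rows drop out.
    """
    table = build_sun_table(sun_cfg)
    scout = result.subtracks[result.subtracks["sub_strategy"]
                             == StrategyLabel.SCOUTING.value]
    meta = result.excursions.set_index("excursion_id")
    rows = []
    for _, r in scout.iterrows():
        m = meta.loc[r["excursion_id"]]
        if m["month"] is None or m["hour"] is None:
            continue
        rel = relative_to_sun(r["azimuth_c"], m["declination_deg"],
                              int(m["month"]), float(m["hour"]), table)
        if rel is not None:
            rows.append({"excursion_id": r["excursion_id"],
                         "dog_id": r["dog_id"],
                         "azimuth_c_rel_sun": rel})
    return pd.DataFrame(rows)


def format_summary(result: PipelineResult) -> str:
    """Human-readable dataset report."""
    s = result.summary["strategy"]
    lines = ["Homing-excursion analysis summary",
             "=" * 34,
             f"trials analysed: {result.n_trials}",
             f"classified return events: {s.n_events}", ""]
    for label in StrategyLabel:
        c = s.counts.get(label, 0)
        lines.append(
            f"  {label.value:9s} {c:4d}  "
            f"({s.share_of_events.get(label, 0.0):5.1f} % of events, "
            f"{s.share_of_trials.get(label, 0.0):5.1f} % of trials)")
    mrl = result.summary.get("mean_run_length_scouting_m", float("nan"))
    lines += ["", f"mean scouting compass-run length: {mrl:.1f} m", ""]
    for name, res in result.summary.get("rayleigh", {}).items():
        kind = "axial" if res.axial else "angular"
        mu = (f"{res.mu:.0f}/{(res.mu + 180) % 360:.0f}"
              if res.axial else f"{res.mu:.0f}")
        lines.append(f"Rayleigh ({kind}) {name}: n={res.n}, mu={mu} deg, "
                     f"r={res.r:.3f}, Z={res.z:.2f}, p={res.p:.3g}")
    eff = result.summary.get("efficiency_by_axis", {})
    if eff:
        lines.append("")
        for axis_name, rec in eff.items():
            lo, hi = rec.get("ci95", (float("nan"), float("nan")))
            lines.append(
                "mean homing efficiency, {} compass runs (scouting): "
                "{:.1f} % (95 % CI {:.1f}-{:.1f}, n={})".format(
                    axis_name, rec["mean"], lo, hi, rec["n"]))
    return "\n".join(lines) + "\n"
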