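"""Speeds, homing-efficiency index, odds ratios, dataset summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import DegenerateDataError, Excursion
from .strategy import StrategyLabel

logger = logging.getLogger(__name__)


@dataclass
class EfficiencyRecord:
    """Homing efficiency of one return.

    index = 100 * inbound path length / beeline (turning point to the
    excursion start/owner); 100 % is a perfectly straight return.
    """

    inbound_length_m: float
    beeline_m: float
    index_pct: float


@dataclass
class ContingencyTable:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class StrategySummary:
    """Counts per strategy with both percentage bases.

    ``share_of_events`` divides by classified return events (combined
    returns count once); ``share_of_trials`` divides by the number of
    trials, the other denominator used in field reporting.
    """

    counts: dict[StrategyLabel, int]
    n_events: int
    n_trials: int
    share_of_events: dict[StrategyLabel, float]
    share_of_trials: dict[StrategyLabel, float]


def inbound_speed_kmh(exc: Excursion) -> float:
    """Mean inbound speed: inbound path length over duration, in km/h."""
    dur = exc.inbound_duration()
    if dur <= 0:
        raise DegenerateDataError("inbound duration is zero")
    return 3.6 * exc.inbound_length() / dur


def homing_efficiency(exc: Excursion) -> EfficiencyRecord:
    """Homing-efficiency index of an excursion (>= 100 % up to the
    return radius; the inbound track ends within 10 m of the owner)."""
    beeline = exc.beeline()
    if beeline <= 0:
        raise DegenerateDataError("owner coincides with the turning point")
    inbound = exc.inbound_length()
    return EfficiencyRecord(inbound, beeline, 100.0 * inbound / beeline)


def odds_ratio(table: ContingencyTable) -> float:
    """(a*d)/(b*c); a 0.5 continuity correction is applied to every cell
    when any off-diagonal count is zero (logged)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == b == c == d == 0:
        raise ValueError("all-zero contingency table")
    if b * c == 0:
        logger.info("zero cell in contingency table; applying 0.5 "
                    "continuity correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def strategy_shares(counts: dict[StrategyLabel, int],
                    n_trials: int) -> StrategySummary:
    """Percentage bookkeeping over events and over trials."""
    n_events = sum(counts.values())
    if n_events == 0:
        raise ValueError("no classified returns")
    return StrategySummary(
        counts=dict(counts),
        n_events=n_events,
        n_trials=n_trials,
        share_of_events={k: 100.0 * v / n_events for k, v in counts.items()},
        share_of_trials={k: 100.0 * v / n_trials for k, v in counts.items()}
        if n_trials else {},
    )


def summarize_dataset(excursion_table: pd.DataFrame,
                      subtrack_table: pd.DataFrame,
                      n_trials: int) -> dict:
    """Dataset-level summary from the pipeline's per-excursion and
    per-subtrack tables.

    Returns strategy counts/shares, mean compass-run length, axis counts
    per strategy, and mean homing efficiency by compass-run axis for
    scouting returns (NS vs EW).  Row order of the inputs is
    irrelevant.
    """
    from .circstats import CircularSample, rayleigh_test  # cycle-free import

    counts = {label: int((excursion_table["strategy"] == label.value).sum())
              for label in StrategyLabel}
    summary: dict = {"strategy": strategy_shares(counts, n_trials)}

    scout = subtrack_table[subtrack_table["sub_strategy"]
                           == StrategyLabel.SCOUTING.value]
    summary["mean_run_length_scouting_m"] = (
        float(scout["run_length_m"].mean()) if len(scout) else np.nan)
    summary["axis_counts"] = {
        label.value: subtrack_table[subtrack_table["sub_strategy"]
                                    == label.value]["axis"]
        .value_counts().to_dict()
        for label in (StrategyLabel.TRACKING, StrategyLabel.SCOUTING)
    }

    circ = {}
    for label in (StrategyLabel.TRACKING, StrategyLabel.SCOUTING):
        sub = subtrack_table[subtrack_table["sub_strategy"] == label.value]
        if len(sub) >= 2:
            circ[f"azimuth_c_{label.value}"] = rayleigh_test(
                CircularSample(sub["azimuth_c"].to_numpy(), axial=True))
    for col in ("azimuth_a", "azimuth_b"):
        vals = excursion_table[col].dropna().to_numpy()
        if len(vals) >= 2:
            circ[col] = rayleigh_test(CircularSample(vals, axial=False))
    summary["rayleigh"] = circ

    eff = {}
    rng = np.random.default_rng(0)    # fixed: summaries are deterministic
    for axis in ("NS", "EW"):
        sel = scout[scout["axis"] == axis]
        merged = excursion_table.set_index("excursion_id")
        ids = sel["excursion_id"].unique()
        vals = merged.loc[merged.index.intersection(ids),
                          "efficiency_pct"].to_numpy()
        rec = {"n": int(len(vals)),
               "mean": float(np.mean(vals)) if len(vals) else np.nan,
               "ci95": (np.nan, np.nan)}
        if len(vals) >= 2:
            boots = vals[rng.integers(0, len(vals),
                                      (2000, len(vals)))].mean(axis=1)
            rec["ci95"] = tuple(np.quantile(boots, [0.025, 0.975]))
        eff[axis] = rec
    summary["efficiency_by_axis"] = eff
    return summary
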