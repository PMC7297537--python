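"""Analysis thresholds, collected in one place.

Defaults are the field protocol's values: the 100 m excursion-opening
alarm, the 10 m return radius, the 200 m minimum excursion length, the
ten-decile speed profile, the >20 degree compass-run deflection, the
+-30 m tracking corridor, +-45 degree cardinal sectors and +-22.5 degree
wind bins.  Quantities the protocol leaves open (pause threshold,
corridor terminal buffer, minimum strategy run) have documented defaults
and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AnalysisConfig:
    # excursion detection
    open_distance_m: float = 100.0     # dog-owner separation that opens an excursion
    close_distance_m: float = 10.0     # return radius around the excursion start
    min_excursion_length_m: float = 200.0

    # turning-trajectory detection
    n_segments: int = 10               # equidistant path-length deciles
    edge_segments: tuple[int, ...] = (1, 10)   # "too close to start/goal"
    long_pause_gap_s: float = 120.0    # single inter-fix gap marking a long pause

    # azimuths
    azimuth_a_offset_s: float = 5.0    # fix used for the initial outbound segment
    deflection_deg: float = 20.0       # compass-run terminating deflection
    persistence_points: int = 1        # extra points the deflection must persist
    min_heading_chord_m: float = 15.0  # chord below which track direction is
    #   unresolved: ~3.5x the 4.2 m chord noise of consumer GPS fixes, so a
    #   "deflection" cannot be manufactured by position jitter alone
    run_length_as_chord: bool = False  # report run length along the path (default)

    # return-strategy classification
    corridor_m: float = 30.0           # tracking corridor half-width
    terminal_buffer_m: float = 50.0    # inbound path masked at each end
    min_run_m: float = 100.0           # minimum sub-strategy run (path length)

    # circular classification
    sector_half_width_deg: float = 45.0   # cardinal sectors N/E/S/W
    wind_half_width_deg: float = 22.5     # olfactory-suitability wind bin

    def __post_init__(self):
        for name in ("open_distance_m", "close_distance_m",
                     "min_excursion_length_m", "deflection_deg",
                     "corridor_m", "sector_half_width_deg",
                     "wind_half_width_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONFIG = AnalysisConfig()


@dataclass
class SunConfig:
    """Reference location for the monthly/hourly sun-azimuth table.

    Default is a central point of the study country (Czech Republic).
    """

    ref_lat: float = 49.8
    ref_lon: float = 15.5
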