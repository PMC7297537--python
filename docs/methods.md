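# Methods

`compassrun` analyses homing excursions of free-roaming dogs tracked with
GPS collars while their owner waits at a fixed, hidden position.  This
note documents the models and procedures the package implements, the
parameters that matter, what the synthetic trial generator does and does
not emulate, and the numerical choices made where the protocol leaves
the design open.

## The excursion model

A trial records two synchronous tracks: the dog (collar at 2.5 or 5.0 s
fix intervals) and the owner (handheld receiver).  Both are projected
into a local planar frame by an equirectangular projection around a
reference point (`x = R Δλ cos φ₀`, `y = R Δφ`, R = 6 371 000 m).  Trial
extents are a few kilometres, so projection distortion is far below the
GPS position error (±4.2 m 2-D RMS) and the mapping is exactly
invertible; geodesic corrections to bearings at these extents are ≪ 1°
and are not applied.

An **excursion** opens at the first dog fix whose straight-line
separation from the (time-interpolated) owner position reaches 100 m —
the handheld device alarms at this distance, the owner stops and the
owner's position at that instant is frozen as the *excursion start*
(the goal).  The excursion closes at the first later dog fix within
10 m of the goal.  Excursions with total path length under 200 m, and
excursions the dog never closed, are discarded (the latter logged).
One trial may contain several excursions.

**Turning trajectory and turning point.**  The excursion is divided
into ten equal path-length deciles; per-decile mean speed is the decile
path length over its duration, with boundary times linearly interpolated
within fixes.  The slowest decile is the turning trajectory unless it is
*improbable* — in the first/last decile, or containing a single
inter-fix gap over 120 s (a long stop at one point, e.g. drinking) — in
which case the second slowest is used; if that is improbable too, the
remaining deciles are scanned from slowest upward for the first whose
maximal straight-line distance from the goal exceeds the excursion's
median fix distance.  Within the chosen decile the consecutive-fix pair
with the lowest speed (ties to the earliest) marks the turning point.
The edge-decile and 120 s conventions are this package's
operationalisation of a protocol step that originally included a video
check; both are configurable.

## Azimuths and the compass run

All azimuths are magnetic: `magnetic = (true − declination) mod 360`,
with the east-positive declination supplied per trial (no geomagnetic
model is consulted; the synthetic generator uses 0° by default).

* **Azimuth A** — bearing from the excursion-start dog fix to the fix
  nearest 5 s later (the 2nd fix at 2.5 s sampling, the 1st at 5.0 s).
* **Azimuth B** — bearing from the turning point to the goal.
* **Azimuth C (compass run)** — chord bearing from the turning point to
  the end of the initial inbound segment.  Walking forward from the
  turning point, candidate fix k (k ≥ turning+2) terminates the run if
  the step heading k→k+1 deviates from the chord (turning→k) by more
  than 20° *and* the next step still deviates by more than 20° from
  that same chord.  Comparing subsequent steps against the chord frozen
  at the deflection point implements "no immediate return to the
  preceding track heading": the chord itself rotates once the dog turns,
  and re-deriving it at k+1 systematically misses moderate course
  changes.  One persistence fix is the default (configurable).

Two numerical guards matter at consumer-GPS noise levels:

* Candidates closer than `min_heading_chord_m` (default 15 m ≈ 3.5× the
  4.2 m chord noise between two fixes) to the run start are skipped.
  While the dog stands at the turning point the fixes are pure position
  jitter; without the guard, a noise-generated "deflection" terminates
  the run within the stationary pause and azimuth C becomes noise.  The
  default scales with receiver accuracy (3.5 × 2-D RMS) and should be
  lowered for better receivers.  A consequence is that runs much
  shorter than this scale have no resolvable direction — a physical
  limit of the data, not of the algorithm.
* Run length is reported along the track by default; the observed path
  through the stationary pause accumulates noise jitter, so a chord
  option (`run_length_as_chord`) is provided and is the faithful length
  measure under noise.

Azimuths are rounded half-up to whole degrees only for sector
classification and display; internal arithmetic is full precision.
Sectors are the printed integer ranges N 316–45, E 46–135, S 136–225,
W 226–315 (0 ≡ 360 → N), and the axis classes NS = {N, S},
EW = {E, W}.

## Return strategies

For every inbound fix the minimum distance to the outbound polyline is
computed exactly (perpendicular foot clamped to each segment).  Fixes in
the first and last 50 m of inbound path are excluded — the endpoints
coincide with the outbound track by construction.  Evaluated fixes are
labelled in/out of a 30 m corridor (≤ 30 m is in); contiguous runs
shorter than 100 m of path are merged into their neighbours so that GPS
noise and brief obstacle detours cannot flip a label.  All-in →
**tracking**, all-out → **scouting**, otherwise **combined**, split into
contiguous sub-tracks that share boundary fixes (so sub-track path
lengths tile the evaluated span).  Azimuth C is measured separately at
the start of each sub-strategy track.  The 50 m buffer and 100 m
minimum run are package conventions (configurable); the corridor
half-width 30 m is the protocol's.

## Circular statistics

Azimuths A and B are angular; azimuth C is axial (meaningful modulo
180°) and is doubled before analysis, with the mean reported as an axis
µ/µ+180.  The mean vector is (C̄, S̄) with r = √(C̄²+S̄²).  The Rayleigh
test uses Z = n r² with the series-corrected p

    p = e^(−Z) [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)]

clamped to [0, 1]; its empirical size at n = 25–30 is 4.9–5.1 %.  The
two-sample Watson U² uses the tie-weighted combined-EDF form; p-values
are reported as critical-value bounds derived from the asymptotic series
P(U² > u) = 2 Σ (−1)^(k−1) e^(−2k²π²u) (which reproduces the standard
table, e.g. 0.187 at α = 0.05), plus an exact label-permutation p on
request (the in-package oracle for the table route).  Confidence arcs
for mean directions are bootstrap percentile arcs (default 10 000
resamples, seeded) — robust for axial data and directly testable for
coverage.  Two analysis levels are supported: excursion-level (each
bearing independent) and dog-level (a mean per dog, then a grand mean;
dogs with r = 0 have no defined mean and are excluded with a log entry).

## Covariates

**Sun.**  A reference table of solar azimuths is built for the 15th day
of each month at whole hours of local solar time, daylight only, at a
configurable reference location (default 49.8° N 15.5° E, central to
the study sites).  Solar position uses the Fourier-series solar
declination (accurate to ~0.3°) and the standard hour-angle formula;
the result matches an independent Meeus-based ephemeris within 1°.
Each scouting run azimuth is converted to true bearing (adding the
trial's declination) and re-expressed relative to the sun azimuth at
the nearest hour; night-time trials drop out with a log entry.

**Wind.**  Wind directions use the meteorological *from* convention.
Wind is *suitable* for olfactory piloting when it blows from the owner
toward the dog, i.e. when the circular difference between the wind-from
direction and azimuth B is ≤ 22.5° (one of eight 45° bins).  Trials
with no detected wind are not assessable and are excluded, not coded as
0°.

**Metrics.**  Inbound speed is inbound path length over duration
(km/h).  The homing-efficiency index is 100 × inbound path length /
beeline (turning point → goal); it is ≥ 100 % up to the 10 m return
radius.  Odds ratios are (ad)/(bc) with a 0.5 continuity correction of
all cells when an off-diagonal cell is zero (logged).  Strategy shares
are reported against two denominators side by side — classified return
events, and trials — because field reports mix both bases.

## The synthetic trial generator

The generator emulates the protocol's structure with ground truth, so
every stage is testable without field data: a pre-excursion walk with
the dog near the owner; a correlated-random-walk pursuit (wrapped-normal
heading increments, σ = 15°/step, 2 m/s) that freezes the owner at
100 m separation; an outbound continuation of 280–450 m (470–650 m for
combined returns); a fully stationary turning pause (default 60 s); a
compass run whose axial direction is von Mises on doubled angles around
the N-S axis (κ default 1.5), sign uniform, length Normal(18.1 m, 6 m)
truncated at 5 m; and an inbound return at 2.5 m/s by the drawn
strategy.  Tracking retraces the outbound with a smooth AR(1) lateral
error (σ = 8 m, ρ = 0.8, clipped at 22 m); scouting runs the compass
run, then turns by at least 45° toward a via point offset laterally
beyond the outbound track's actual extent, enforcing ≥ 60 m clearance
over the middle portion; combined retraces 35–55 % of the way back and
then scouts.  The first two fixes of the terminating course change are
noise-free: the manoeuvre is a deliberate turn, and it must be
unambiguous relative to the 20° criterion for the protocol to have
identified it in the field.  Isotropic Gaussian noise (σ = 4.2/√2 m per
coordinate, i.e. 4.2 m 2-D RMS) is added to every fix of both tracks.

Strategy label and compass-run draw are fixed once per trial;
geometric-feasibility retries redraw only nuisance parts (via offsets,
walk noise), so rejection cannot bias the axial distribution.
Per-trial seeds are spawned from `numpy.random.SeedSequence(seed)`.

What the generator does **not** emulate: temporally correlated GPS
error (real collar error drifts smoothly; the i.i.d. noise used here is
the harsher case for heading-based rules), forest-path networks,
game-driven outbound shapes, wind-driven scent fields, multi-switch
combined returns, and dog-specific movement styles.  Tests passing on
these data therefore demonstrate the analysis chain's correctness and
noise robustness under stated conditions, not biological realism.

## Problem sizes and test design

Dataset-scale checks use 250 scouting trials for axial-alignment
recovery, 1000 datasets of 25 trials for the null (κ = 0) rejection-rate
calibration, 200 mixed trials for strategy-label recovery, 500
noise-free trials for turning-point recovery, and 200 two-sample
problems for Watson table-vs-permutation agreement; these sizes give
binomial standard errors comfortably inside the asserted bands while
keeping the whole suite around five minutes on one CPU.  Compass-run
*length* recovery is assessed with the chord measure, 2.5 s sampling,
3 m 2-D RMS noise (gate scaled to 10.5 m accordingly) and run-length
spread σ = 3 m, so that essentially all simulated runs are above the
direction-resolvability scale; with the default 4.2 m noise and
path-length measure the recovered length is dominated by stationary
jitter at the pause, as discussed above.

## Known limitations

* Runs shorter than ~3.5× the GPS chord noise have no resolvable
  direction; their azimuth C reflects the subsequent route instead.
* The "improbable decile" thresholds (edge deciles, 120 s gap) are
  conventions replacing the study's video review.
* Whether "separated by more than 30 m" must hold at every inbound
  point is not stated in the protocol; the all-runs-after-merging rule
  used here is one documented interpretation.
* Mixed-effects model fits (speed/efficiency GLMMs) are out of scope;
  group means and bootstrap arcs are reported instead.
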