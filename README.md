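# compassrun

Analysis pipeline for **homing excursions of GPS-tracked, free-roaming
dogs**: trajectory segmentation, turning-point detection, extraction of
the magnetic **compass run** at the start of the return, classification
of returns as *tracking* (retracing the outbound route) or *scouting*
(novel route), and axial circular statistics testing whether scouting
returns begin with a short run aligned along the north–south magnetic
axis.

It is written for movement ecologists and animal-navigation researchers
working with paired dog/owner GPS tracks (GPX 1.1, 2.5 or 5 s fixes),
and ships a synthetic trial generator with ground truth so the whole
chain is testable without field data.

## The analysis in brief

An **excursion** is the dog's track from the moment its separation from
the owner first reaches 100 m (the owner then stays put — the
*excursion start*, the goal) until the dog returns within 10 m of that
point; excursions shorter than 200 m are excluded.  The excursion is cut
into ten equal path-length deciles; the slowest decile (with documented
fallbacks) is the *turning trajectory*, and its slowest consecutive-fix
pair the *turning point*.  Three magnetic azimuths are measured:

* **A** — initial outbound segment (start fix → fix 5 s later),
* **B** — turning point → owner,
* **C** — the compass run: chord from the turning point to the first
  sustained deflection of more than 20° in track direction.

Returns are *tracking* if every evaluated inbound fix lies within a
±30 m corridor of the outbound track, *scouting* if separated by more
than 30 m, and *combined* otherwise (split into sub-tracks, azimuth C
measured per sub-track).  Azimuth C is **axial** (meaningful modulo
180°): analyses double the angles, so the mean is an axis µ/µ+180 with
resultant length r, tested by the Rayleigh statistic Z = n r² with the
series-corrected p-value; distributions are compared with the
two-sample Watson U² (critical-value bounds plus a seeded permutation
p).  A homing-efficiency index, 100 × inbound path length / beeline, and
sun-position and wind-suitability covariates complete the picture.  See
`docs/methods.md` for the full account.

## Worked example

```sh
compassrun all --n-trials 250 --seed 7 --out demo
```

simulates 250 trials at the study conditions (GPS noise ±4.2 m 2-D RMS,
strategy mix 60/32/8 %, compass-run axis N–S with von Mises
concentration κ = 1.5, mean run length 18.1 m), writes the dataset
(GPX + metadata + truth CSV) to `demo/data/`, analyses it, and prints:

```
classified return events: 248

  tracking   159  ( 64.1 % of events,  63.6 % of trials)
  scouting    71  ( 28.6 % of events,  28.4 % of trials)
  combined    18  (  7.3 % of events,   7.2 % of trials)

mean scouting compass-run length: 65.4 m

Rayleigh (axial) azimuth_c_tracking: n=177, mu=82/262 deg, r=0.045, Z=0.35, p=0.704
Rayleigh (axial) azimuth_c_scouting: n=89, mu=167/347 deg, r=0.187, Z=3.10, p=0.0446
Rayleigh (angular) azimuth_a: n=248, mu=40 deg, r=0.076, Z=1.42, p=0.241
Rayleigh (angular) azimuth_b: n=248, mu=208 deg, r=0.069, Z=1.17, p=0.309

mean homing efficiency, NS compass runs (scouting): 177.2 % (95 % CI 160.2-197.6, n=57)
mean homing efficiency, EW compass runs (scouting): 159.9 % (95 % CI 150.1-171.3, n=32)
```

Read: outbound directions (A) and owner bearings (B) are random;
compass-run directions (C) are random in tracking returns but axially
clustered near the N–S axis (167°/347°) in scouting returns, where the
axial Rayleigh rejects uniformity; run lengths measured along the noisy
track overstate the generating 18.1 m because the stationary turning
pause accumulates GPS jitter (use the chord option for a faithful
length).  Per-excursion and per-sub-track tables land in
`demo/analysis/*.csv`.

Library use mirrors the CLI:

```python
from compassrun import SimConfig, simulate_dataset, run_pipeline

records, truth = simulate_dataset(SimConfig(n_trials=100, seed=1))
result = run_pipeline(records)
print(result.summary["rayleigh"]["azimuth_c_scouting"])
```

`compassrun analyze <dir> --out <dir>` runs the same pipeline on any
directory with a `trials.csv` and GPX files (see
`compassrun.track_io.TRIAL_COLUMNS` for the metadata schema);
`compassrun suntable` exports the monthly/hourly solar-azimuth table.

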