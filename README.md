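# fishrhythm

Rest-activity rhythm analysis for fish locomotor recordings.

Comparative chronobiology in fishes — for example across Lake Malawi
cichlid species and life stages — asks when an animal moves and when it
rests over the light:dark cycle. The raw material is either a positional
track from a video tracker (one `(t, x, y)` sample per frame) or a
manually scored ethogram of active-swimming state events. `fishrhythm`
turns both into the standard quantities of that analysis:

* **rest bouts** — maximal runs of swimming speed below a stage-specific
  threshold (12 mm/s for juveniles, 4 cm/s for adults) lasting at least
  60 s; deliberately a sleep-like proxy, not a sleep claim;
* **hourly zeitgeber profiles** — locomotion (mm/h), active time and rest
  time per ZT hour, with no smoothing; ZT0 is lights-on (default
  photoperiod 14 h light : 10 h dark, recordings starting at ZT1);
* **the diurnality index** (activity change ratio)
  `A_R = (D − N) / (D + N)`, where `D` and `N` are mean hourly activity in
  the light and dark phase: +1 fully diurnal, −1 fully nocturnal;
* **the crepuscularity index** `C_R = C / NC − 1`, where `C` is mean
  activity in the hour after each light transition (dawn, dusk) and `NC`
  the mean over the remaining hours: 0 = no change, 1 = a 100% increase;
* **species-level statistics** — one-way ANOVA, mixed two-way
  (time-of-day × species) repeated-measures ANOVA with Šidák-corrected
  post hoc contrasts, paired day/night t tests, and cross-stage OLS
  correlation of species means.

Because such studies rarely publish raw recordings, the package includes
a **synthetic trajectory simulator**: a two-state (active/rest)
semi-Markov process with phase-dependent speeds and hazards, an optional
crepuscular speed boost after light transitions, and closed-form ground
truth (`expected D`, `N`, `A_R`, per-phase rest fractions) so every stage
of the analysis can be validated against known truth.

## A worked example

```python
import fishrhythm as fr

schedule = fr.LightSchedule()                      # 14:10 LD, start at ZT1
params = fr.species_preset("diurnal", stage="juvenile", seed=1, fps=5.0)

(traj,), truth = fr.simulate_trajectory(params, schedule)
speed = fr.compute_speed(traj)
bouts = fr.detect_rest_bouts(speed, fr.threshold_for_stage("juvenile"))
profile = fr.bin_hourly(traj, bouts, schedule, speed=speed)
ix = fr.rhythm_indices(profile, schedule)
```

This prints (via `examples/01_simulate_and_profile.py`):

```
expected D =     91800 mm/h   measured D =     91014 mm/h
expected N =     33943 mm/h   measured N =     35007 mm/h
expected A_R = +0.460      measured A_R = +0.444
crepuscularity C_R = -0.106
```

The expected values are the closed-form stationary expectations of the
simulation parameters; the measured values come from running the full
analysis on one simulated subject-day, so they scatter around the truth
(here by ~0.02 on `A_R`). An `A_R` of +0.44 is a clearly diurnal animal;
`C_R` near 0 means no particular dawn/dusk burst.

More narrative scripts live in `examples/` (rest-bout accounting, the
ethogram pathway, the statistical battery, profile plots). A thin CLI
wraps the same pipeline for config-driven runs:

```
fishrhythm all --config run.yaml --seed 1 --out results_dir
```

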