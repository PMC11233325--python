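# Methods

## The analysis model

A recording is a uniform frame grid of positions for one subject. Sample
`i` represents the frame interval `((i−1)/fps, i/fps]`, so `n` samples
span `(n−1)/fps` seconds. All internal times are seconds from recording
start; the canonical length unit is mm (the adult 4 cm/s cutoff is stored
as 40 mm/s). Zeitgeber conversion happens in exactly one place, the
`LightSchedule`, which maps time to ZT hour (`ZT0` = lights-on) on a
periodic 24 h cycle; the defaults are the standard recording condition:
14 h light : 10 h dark, recording start at ZT1, 15 frames/s.

**Speed.** `speed[i]` is the Euclidean displacement between consecutive
valid samples divided by the frame interval, assigned to the later
sample. Speed across a tracking gap is undefined and excluded from both
activity and rest accounting — exclusion is conservative and exactly
testable, whereas interpolation invents data. No smoothing is applied by
default; an optional boxcar is available but off, since the thresholds
were defined empirically on raw tracker output.

**Rest bouts.** A frame is inactive when its speed is *strictly* below
the stage threshold (juvenile 12 mm/s, adult 40 mm/s). A maximal run of
inactive frames lasting **≥ 60 s (inclusive)** is a rest bout. The
inclusive reading matches "1 min or longer"; at 15 fps the alternative
differs by one frame. Runs interrupted by gaps are split; gap frames
belong to no bout. The four frame classes — active, in-bout rest,
sub-minimum inactivity, gap — partition every recording exactly (integer
frame counts, converted to seconds by one shared `dt`).

**Hourly binning.** Each frame interval is assigned to the ZT hour
containing its *midpoint*; midpoints never coincide with bin edges, so
assignment is unambiguous, every day's bins sum exactly to that day's
path length, and the frame ending exactly on a day boundary cannot leak
into a nonexistent 25th bin (assignment by the interval's endpoint would
do both). Rest bouts are split pro rata across the bins they overlap.
Multi-day recordings are averaged per ZT bin across days; recordings
must span whole 24 h days — for partial days "mean of hourly bins" and
"phase total / phase length" diverge, so partial days are rejected
rather than guessed.

**Indices.** `D` and `N` are means of the light- and dark-phase hourly
bins (14 and 10 bins by default, resolved from the schedule, never
hard-coded). `A_R = (D − N)/(D + N)`; `C_R = C/NC − 1` with `C` the mean
of the bins starting at lights-on and at lights-off (`window_h = 1` by
default, configurable to 2; `NC` excludes only the crepuscular bins).
Zero denominators make an index *undefined*, reported as missing and
excluded from group statistics with a logged count — a motionless fish
has no diurnality, not zero diurnality.

**Ethogram pathway.** Manually scored active-swimming intervals are
normalized (sorted, merged where touching), complemented within the
recording span, and complement gaps ≥ 60 s become rest bouts. An
ethogram carries no displacement information, so its activity profile is
time-in-active-state per hour; trajectory profiles carry the same
activity-time channel alongside mm locomotion, and that shared channel
is the basis on which the two pathways are compared. On seed-matched
synthetic data the two pathways agree exactly, because both observe the
same underlying state sequence.

**Group recordings.** When individual identities cannot be maintained,
the per-bin arithmetic mean across the group's subjects is analyzed as
one profile (subject count retained for statistics).

## The simulator

Each subject is an independent two-state semi-Markov process. In phase
`p ∈ {light, dark}` the active→rest hazard is `rest_rate_p` and the
rest→active hazard `wake_rate_p` (both 1/s); dwell times are exponential
with the hazard at state entry, and dwells in progress are redrawn
(state retained) at light transitions — the simplest memoryless
construction, with transition behavior exercised separately by the
crepuscular multiplier, which scales active speed during the first hour
after each transition. The initial state is drawn from the starting
phase's stationary occupancy `rest_rate/(rest_rate + wake_rate)`.

Active frames displace by `mean_active_speed_p / fps`; rest frames by a
fixed jitter of 25% of the stage threshold, so simulated rest is
unambiguously sub-threshold and simulated swimming unambiguously
supra-threshold (the simulator refuses active speeds at or below the
threshold). Headings are isotropic and uniform per frame; when a step
would leave the rectangular arena the heading is redrawn until the step
stays inside. Rejection, rather than reflective folding, is used
deliberately: folding shortens the measured chord between consecutive
positions and can push an active frame's apparent speed below the
threshold near walls, which would break the exact correspondence between
the state sequence and the thresholded speed series that the dual-pathway
checks rely on. Step feasibility from the worst-case position (the arena
center) requires `step ≤ diag/2`; parameters are validated against
`0.35 · diag` to keep the rejection loop short. Path length is unaffected
by the boundary rule since step magnitudes are preserved.

Closed-form ground truth per phase: rest fraction
`rf = rest_rate/(rest_rate + wake_rate)` and expected hourly distance
`3600 · [(1 − rf) · v_active + rf · v_jitter]`, with the crepuscular
hour's boost averaged over the phase's hours. The jitter term is part of
the truth because rest-state drift is real path length that the analysis
measures; omitting it would bias `A_R` recovery by more than the
Monte-Carlo error at realistic sample sizes. `params_with_expected_ar`
inverts this formula for the dark-phase speed to build scenarios with an
exact target `A_R`; the closed form was confirmed by brute-force
averaging of 200 simulated subject-days before the recovery tests were
frozen.

The ethogram generator emits the same state sequence (an isolated random
stream per subject) as the trajectory generator, snapped to the frame
grid, so seed-matched calls are exactly consistent.

**What the simulator does not emulate.** No social interaction (group
recordings are independent subjects sharing an arena), no heading
persistence or wall-following (the analysis uses only speed), no tracker
noise or identity swaps, no gradual twilight. Passing tests therefore
validate the analysis machinery and its statistical calibration, not the
biology of any particular species; the four phenotype presets (diurnal,
nocturnal, arrhythmic, crepuscular) are qualitative archetypes, since no
per-species quantitative activity parameters are published.

## Statistics

One-way ANOVA (scipy), paired t (scipy), OLS species-mean regression
(scipy), and the mixed two-way repeated-measures ANOVA via pingouin's
split-plot implementation (subjects nested in species; sphericity is
trivial with a two-level within factor). Šidák correction
`1 − (1 − p)^m` uses the number of species-level contrasts in the family.
All tests are two-sided at α = 0.05. Tests validate each against
independent hand-coded sums-of-squares/closed-form oracles. A paired
day/night comparison with identical vectors returns t = 0, p = 1; a
non-zero constant difference has no within-pair variance and raises
rather than reporting an infinite statistic.

## Numerical choices and problem sizes

* Duration comparisons on float time grids use an absolute slack of
  1e-9 s; the 60 s rule is otherwise exact in frames.
* Exhaustive detector validation runs every boolean sequence of length
  ≤ 20 through the public detector (batched with mask-gap separators,
  whose run-splitting semantics are unit-tested independently) against a
  pure-Python run-length oracle, with a few-second minimum duration so
  short sequences can contain bouts at all; the 60 s rule at 15 Hz is
  covered by 1000 random sticky-state sequences with dropped frames.
* Monte-Carlo calibration suites (type-I error of the paired test over
  2000 null runs, interaction power over 200 runs at n = 12/species,
  `A_R` recovery over 50/200 subjects) simulate at 1–2 frames/s in the
  adult geometry: hourly distances and occupancies are frame-rate
  invariant for this process, and these sizes keep the suites tractable
  on a single CPU. Analysis defaults remain 15 fps.
* Pipeline outputs are written atomically (temp file + rename) with the
  config echoed alongside; identical configs give byte-identical tables.

## Known limitations

* The detector's strict `<` threshold and inclusive `≥ 60 s` rule are
  declared conventions; real tracker exports may have been thresholded
  with different edge semantics inside the tracking software.
* Gaps are excluded, not imputed; heavily dropped recordings will
  under-count both activity and rest relative to wall-clock time.
* The mixed ANOVA assumes complete day/night pairs (incomplete subjects
  are dropped with a logged count) and species as a fixed factor.
* `D`/`N` are bin means, so the package refuses partial recording days
  instead of silently reweighting them.
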