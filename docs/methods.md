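# Methods

This note documents the models and numerical choices behind `sensortoy`:
what the game engines and the synthetic cohort generator compute, which
parameters matter and why they default as they do, and what the synthetic
results can and cannot say about real children.

## Cube surface model

The toy's surface is modelled as 54 cells, face-major (face *f* owns
indices 9f…9f+8, row-major viewed from outside), with faces ordered by
outward normal (+z, +x, −z, −x, +y, −y).  The commercial toy's physical
index layout is not public; any consistent layout yields identical
statistics because every downstream quantity depends only on adjacency and
cell directions, so one layout was fixed and documented to keep logs
comparable across runs.  Cell directions are the normalised positions of
the 3 × 3 grid centres on a unit cube — only the direction enters the
cosine-similarity feature.  Headings are in-face unit steps; rolling over
an edge maps (cell, heading) → (neighbour cell, −old-normal), which makes
"forward" globally well defined: the forward map is a bijection on the 216
(cell, heading) states and every straight walk closes after 12 steps
(4 faces × 3 cells).  `up_face` ties (exact 45° poses) resolve to the
lowest face id so behaviour is deterministic.

## Game engines

**Roadrunner.**  The dot advances one step every *d* seconds
(d = 0.8/0.6/0.4 for LoD 0/1/2).  Moves happen at t = k·d after the
segment start, k ≥ 1; a move falling exactly on a segment boundary belongs
to the next segment, which fixes the event counts (37/49/74 moves per 30 s
segment).  At a face's centre cell the next direction is drawn uniformly
from {left, right, forward}; the original game is described only as
"random", and the uniform reading is the maximum-entropy choice.  The dot
starts at the top face's centre heading +x (any fixed start works;
determinism preferred).  The player cannot influence the dot, so the event
log depends only on schedule and seed.

**Maze.**  Two fixed closed-loop tracks: level 0 is the equatorial ring of
middle-row cells (every edge crossing at an edge's middle); level 1
detours over the top face so two crossings happen at off-middle edge
cells.  The published track layouts are schematic, so the loops here are
documented constructions with the stated crossing properties — the
statistics depend only on on/off-track timing, not on which exact cells
form the track.  The dot moves at most one cell per 0.3 s control step.
At every level boundary the dot respawns at the track start (the track
changes with the level); if a level ended off-track, the respawn closes
the episode with an `off_path_exit` at the boundary so enter/exit events
strictly alternate over the whole session.  Warm-up replays the easiest
level for 60 s in both games and is excluded from all features.

## Synthetic cohort generator

The generator emulates the study population: n = 95 children aged
6.5–9.0 y, labelled 1 when the fine-motor percentile is ≤ 16.  Latent
skill s ∈ [0, 1] is drawn from a two-component mixture — low-skill
N(0.18, 0.05²) with probability = prevalence, typical N(0.62, 0.12²)
otherwise, clipped to [0, 1] — and maps to the percentile as
⌊100·s^1.5⌉.  The MABC-2 norm tables are not public; only the ≤ 16
threshold matters downstream, and with these components the label-1
fraction tracks the prevalence to within ~2 pp.  Two further per-child
traits decouple the label from the signals, as in real cohorts:

* `control_skill` = s + N(0, 0.12), clipped — the games and the pegboard
  test measure correlated but distinct constructs;
* `activity` ~ U(0.5, 1.5) — how vigorously the child swings the cube when
  steering deliberately, independent of skill.

`control_skill` drives the handling model (each parameter monotone in
1 − skill): tracking gain 1.5 + 4.5 s (1/s), reaction latency
0.08 + 0.35 (1 − s) s, angular wobble 0.05 + 0.9 (1 − s) rad/s,
translational jitter 0.3 + 1.7 (1 − s) m/s², maze error rate
0.04 + 0.16 (1 − s) per step.

**Motion synthesis.**  The child's state is the world-up direction in the
body frame, u(t).  The target direction is the current dot cell
(roadrunner) or the current cell plus a 0.25 s tilt pulse toward the
intended next cell (maze).  u relaxes toward the delayed target through a
critically damped second-order lag (two cascaded poles at the gain): arm
movements are C¹-smooth, so the commanded angular velocity is continuous
and the motion's spectral content stays below ~1 Hz, well under the 4 Hz
analysis filter — a deliberate design constraint, since skill must be
observable in the filtered features and the filtered signals must track
the simulator's internal state.  Wobble is first-order low-passed Gaussian
orientation noise with a 2 Hz corner (amplitude wobble_sd / 2π·2 Hz), so
part of it survives the 4 Hz filter.  The gyroscope reports the angular
velocity consistent with u̇ = −ω × u plus low-passed spin about u and
white measurement noise (0.02 rad/s); the accelerometer reports the
gravity vector in the body frame, −9.81 · u m/s², plus jitter.  Feature
extraction estimates up as the negated normalised low-passed acceleration
— the same convention, drift-free, and computable from recorded channels
alone.  Outputs are clipped to the hardware ranges (±8 G, ±2000 dps) and
sampled at 110 Hz.

In the maze, steering requires large deliberate swings whose magnitude is
the `activity` trait: the effective wobble and jitter become
0.3 × (skill part) + activity-driven terms (0.4 rad/s and 1.5 m/s² per
activity unit).  The precision game's inertial channel therefore mostly
encodes style rather than skill, while its game channel (time on track)
carries a weak-to-moderate skill signal through the error rate.  This is
the study condition the generator is built to emulate — the speed game is
the more diagnostic one — and the label-recovery tests assert exactly that
ordering.

## Feature pipeline

Zero-phase (forward–backward) 4th-order Butterworth at 4 Hz per axis, then
magnitudes, then central-difference derivatives (one-sided at the ends) —
filtering before combining is the conventional movement-science order, and
the zero-phase two-pass realisation squares the amplitude response, which
the filter tests check against the analytic transfer function.  Gravity is
deliberately not removed from the acceleration magnitude: orientation
changes then remain visible in *a*.  Aggregation pools both occurrences of
a level before taking mean and SD (population SD), reading "mean over
time" as pooling rather than mean-of-means.  Gender is encoded girl = 0,
boy = 1; age in real-valued years.

## Evaluation and statistics

Fold plan: one fold per label-1 child; label-0 children are permuted by
seed and assigned cyclically, so with n₁ > n₀ the first n₁ − n₀ of them
serve in exactly two test sets (49/46 → 49 folds, 3 reused).  When a drawn
cohort has surplus negatives the plan still builds one fold per positive
and the leftover negatives only train — the generalisation is needed
because a prevalence-0.5 cohort draws either majority.  Standardisation
(KNN, LR, SVM) is fitted on the training fold only; the decision tree uses
raw features.  Hyperparameters are conventional defaults (k = 5, C = 1,
Gini, RBF) exposed in `classifier_specs`.  On two-sample test sets F1 is
defined as 0 when precision + recall = 0.

Wilcoxon signed-rank, two-sided, α = .05: zero differences are discarded
(classic treatment; Pratt selectable), an all-zero comparison is p = 1.
With ≤ 25 nonzero differences the exact null is computed by dynamic
programming over doubled (possibly tied, half-integer) ranks — fold-wise
accuracy differences are heavily tied, and the standard library exact path
cannot handle ties; beyond that, the normal approximation with tie and
continuity corrections (the two paths agree to < 0.02 at the study's fold
count).  No multiple-testing correction is applied, matching the per-test
α reading of the original analysis; readers should treat borderline p's
accordingly.

## Problem sizes and determinism

Default study size is the deployed one: 95 children, two sessions each
(240 s roadrunner, 300 s maze at 110 Hz).  A full study — simulation, 22
feature tables, both grids, four comparison tables — runs in ~15 s on one
CPU; the acceptance script and the statistical test suites use 5-seed
sweeps, 20 label shuffles and 500-replicate nulls, chosen to keep Monte
Carlo error well below the asserted margins.  All randomness flows from
explicit integer seeds through hierarchical `SeedSequence` spawning;
identical inputs give byte-identical outputs.

## What passing tests show — and what they do not

The synthetic generator produces label-bearing structure in both sensor
and game channels with realistic overlap, so the pipeline's recovery of
the label (and the speed-over-precision ordering) demonstrates that the
machinery — geometry, engines, features, CV design, tests — is correct and
leak-free.  It does not validate the toy as a clinical instrument: effect
sizes here are configuration, not measurements; real children differ in
ways the control model does not capture (fatigue, strategy changes,
age-dependent motor maturation beyond a scalar skill); and the real
study's accuracies were computed on data that are available only on
request, so no numeric agreement with them is claimed anywhere in this
package.  Known further limitations: the maze tilt-to-motion law and the
original cosine-similarity provenance (engine state vs sensor estimate)
are undocumented in the source material and fixed here by documented
choice; MABC-2 subtests are not modelled; features are time-domain only.
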