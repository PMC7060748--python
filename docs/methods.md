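# Methods

This note documents the models, parameter defaults and numerical choices
behind `nursetag`, and what the synthetic-data tests do and do not show
about real tag data.

## Data model and conventions

A tag record holds uniform-rate channels in the whale body frame:
x surge (+forward), y sway (+left), z heave (+up). The accelerometer
reports specific force in m/s², so a level resting tag reads
(0, 0, −9.81). Depth is metres positive down; a −0.5 m sensor offset is
tolerated. Time is seconds since deployment start; the wall-clock tag-on
time is carried once in the file header so no timezone arithmetic enters
the analysis. Event intervals are closed-open `[start_s, end_s)`; the
analysis assumes event annotations are already expressed on the sensor
time base (the mapping from video timestamps to sensor samples is
deployment-specific plumbing outside this package's scope).

## Kinematic processing

* **Decimation.** All channels are anti-alias filtered and subsampled to
  10 Hz (`scipy.signal.resample_poly`, linear-phase FIR). The humpback
  fluking band (~0.1–0.4 Hz) is far inside the passband; a 0.2 Hz unit
  sine survives with <1% amplitude error.
* **Whale-frame correction.** A fixed rotation is estimated from a calm
  calibration window (animal level and unaccelerated, typically logging
  at the surface): the minimal rotation mapping the window-mean specific
  force onto (0, 0, −g). Windows whose mean magnitude differs from g by
  more than 20% are rejected — a pitched descent, for instance, fails
  this check by construction. Gravity alone cannot constrain the roll
  about the longitudinal axis; the minimal rotation is the standard
  resolution of that ambiguity.
* **Static/dynamic split.** Static acceleration is a centred running mean
  per axis; dynamic = acc − static, an exact additive decomposition. The
  default window is 5 s, at least twice a ~4 s humpback stroke period,
  and configurable. A running mean is not a brick-wall filter: a 0.25 Hz
  stroke leaks into the static estimate with a sinc(fW) factor, leaving
  the dynamic component ~18% larger than the raw sine at 0.25 Hz and ~6%
  smaller at 0.425 Hz. Segment-level tolerances (15%) account for this;
  it affects nursing and baseline segments alike and does not reverse any
  contrast direction at the studied effect sizes.
* **ODBA** is the L1 norm of the dynamic acceleration,
  |dₓ| + |d_y| + |d_z|, in m/s².
* **Orientation.** pitch = asin(surge/‖static‖) (nose-up positive),
  roll = atan2(sway, −heave). Samples whose static magnitude strays more
  than 50% from g are flagged undefined rather than silently reported.
  Heading is not computed: it needs a per-deployment magnetometer
  calibration that is not part of this pipeline; circular statistics are
  exercised on pitch and roll.
* **Fluke strokes.** The stroke series (dorsoventral dynamic acceleration
  by default; pitch is supported as an alternative, since field practice
  varies) is band-passed (2nd-order Butterworth, 0.1–0.6 Hz, zero-phase)
  and strokes are counted one per full oscillation with a Schmitt
  trigger: a positive-going zero crossing is recorded when the signal
  rises above +0.05 m/s², re-armed only after an excursion below
  −0.05 m/s². This is robust to the amplitude modulation seen during
  nursing and invariant to constant offsets. The trigger starts armed, so
  an oscillation beginning at a rising zero is counted. A stroke belongs
  to a segment iff its zero-crossing time lies inside the segment, which
  makes segment counts exact up to ±1 edge stroke.

## Dive phases

A dive is a maximal interval with depth above a surface threshold
(default 1 m) reaching a minimum depth (default 5 m); the original field
procedure segmented dives visually, so these numeric thresholds are an
operationalization, documented and configurable. Boundaries are
interpolated threshold crossings.

Each dive splits into: **descending**, from the surface to the *first*
attainment of maximum depth (ties broken by first attainment, making
descending shortest); **ascending**, the earliest suffix that (a) begins
where depth has started to decrease below the dive maximum and (b) never
rises more than 10 m (less than an adult body length) above its running
minimum — the strictest reading of "at any point along that ascent" —
terminating at the surface; **horizontal**, whatever lies between,
possibly empty (V-dives). Pitch is deliberately not used: a nursing
calf's pitch is confounded by the act of nursing itself.

Condition (b) alone is monotone in the candidate start index (removing
the front element can only raise running minima), so the implementation
binary-searches the earliest index satisfying it and then scans forward
for the first decrease; tests verify exact agreement with a brute-force
sample-by-sample application of the rule. A depth tolerance (default
0.05 m, the typical pressure-sensor resolution) keeps flat bottoms from
being claimed by either boundary on filtered data; with heavy depth noise
the boundary placement degrades gracefully but remains rule-consistent.

## Matched sampling design

Nursing segments enter at their true durations. Baselines are 30 s
windows — the mean nursing duration (23 s) plus one standard deviation
(7 s) — drawn per deployment and per dive phase in which that individual
nursed: 15 per phase for calves, 9 for mothers. A draw is a uniform
random start time over the deployment followed by a forward scan to the
first window that lies entirely inside one contiguous interval of the
requested phase (windows may not straddle phase boundaries or surface
time — the strictest reading) and overlaps no nursing, probable-nursing
or poor-video interval and no previously selected window. Probable
nursing (inconclusive on video) and poor video are excluded from
sampling because they are excluded from analysis. Mother nursing
segments are the timestamps of the calf's events copied onto the
mother's record.

Feasibility is checked exactly before and during sampling: the maximum
number of disjoint windows in a union of free intervals is
Σ floor(length/window); infeasible requests raise an error naming the
achievable maximum rather than looping. A rejection cap of 10⁵ draws
guards against livelock on pathologically fragmented phases. All
randomness flows through one seeded NumPy generator, and the seed is
recorded in the run metadata. The forward scan puts a small atom of
probability on each free-interval start; away from those atoms the start
distribution is exactly uniform (verified against a Kolmogorov–Smirnov
test and an independent reimplementation).

## Statistical comparison

For each response (mean ODBA, FSR) a linear mixed model
`response ~ nursing + phase + nursing:phase` with a random intercept per
individual is fitted by REML (statsmodels `MixedLM`; the default
optimizer occasionally hits a singular profiled Hessian on small
unbalanced designs, so Powell and Nelder–Mead are fallbacks). Phase uses
sum-to-zero coding, so the `nursing` coefficient is the phase-averaged
(marginal, Type-III-style) nursing effect; whether the original analysis
used marginal or sequential tests is not documented, and marginal is the
choice here. Significance uses a Wald F with 1 numerator df and
denominator df = n − rank(X) − (g − 1), charging both the fixed effects
and the between-individual contrasts; for 116 calf segments over four
individuals with a full 2×3 design this gives F(1, 107). No Satterthwaite
correction is applied — a documented approximation favouring
implementability; simulation shows the resulting test holds its nominal
size (type-I error within [0.03, 0.07] at α = 0.05 over 1000 null
replicates of the study-shaped design). Mothers are modelled only when
segment counts permit; otherwise output is descriptive. No
multiple-testing correction is applied across the two responses,
matching the original analysis.

Budgets use exact closed-open interval arithmetic: non-nursing proximity
is |proximity ∖ nursing|, and nursing + non-nursing proximity +
remainder = good-video time identically. Nursing-to-foraging gaps are
distances between closed intervals (0 when overlapping); nursing events
in deployments without foraging annotations are flagged undetermined.
Report rounding follows the printed conventions: durations to whole
seconds (half-to-even), percentages to two decimals, speeds to one
decimal. Where the published per-event durations and per-deployment
totals disagree by ±1 s, summaries recompute from the per-event inputs
and do not force agreement.

## Synthetic deployments

The generator emulates exactly the structure the analysis assumes:
piecewise-linear dive cycles (optionally with a re-descent excursion on
the ascent to exercise the 10 m rule); heave-axis sinusoidal stroking at
a baseline gait of 0.25 Hz (a ~4 s stroke period, mid-range for
humpbacks) with amplitude 0.25 m/s², putting baseline segment mean ODBA
near 0.2 m/s², inside the 0.12–0.28 m/s² range observed for travelling
mother–calf pairs; optional deterministic glide bouts; Gaussian sensor
noise (0.02 m/s² per axis); a gravity component consistent with the
pitch implied by depth slope at the mean swimming speed (1.4 m/s); and a
stroke-phase-locked 10% speed ripple (arbitrary but documented). Depth
is generated at the accelerometer rate, subsampled to 10 Hz and
interpolated back, mimicking the pressure sensor's bandwidth while
keeping channels equal length.

Nursing events scale gait frequency and amplitude multiplicatively,
phase-continuously at the window start: calves ×1.7 (FSR) and ×1.5
(ODBA), mothers ×0.3 for both — the ratios observed in the field tables;
a zero multiplier silences stroking entirely, reproducing the mothers'
0.0000 strokes/s events. Unit multipliers are an exact identity. All
outputs are bit-identical for equal configurations including the seed.

What the simulator does **not** emulate: hydrodynamic coupling, tag
slippage, heading dynamics, irregular dive shapes, depth-dependent or
behaviour-dependent speed, non-Gaussian sensor noise, and any day/night
structure (the reference deployments contain none). Passing tests
therefore demonstrate that the pipeline recovers the statistical
structure it assumes from data *of that structure* at realistic
magnitudes — not that the field effect sizes themselves are reproduced,
which would require the original (undeposited) raw tag records. For the
same reason the published headline F statistics and the 4.1–64.4 m
nursing depth range are not reproduction targets.

## Problem sizes

Tests and the acceptance script run the reference-structure simulation
at a 40 Hz (tests: 20 Hz) accelerometer rate rather than the field 400 Hz,
and ten 465 s dive cycles per deployment (~77 min). Both rates are far
above the 0.6 Hz top of the stroke band, so the decimated 10 Hz analysis
stream is statistically identical; the choice simply keeps simulated
deployments compact. The Monte-Carlo suites use 100 replicates
(directional recovery, power) and 1000 replicates (type-I calibration).
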