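# Methods

## Coordinate convention and data model

All positions are SI (metres, seconds) in a right-handed frame: `w`
increases along the walking direction, `y` is up, `x` lateral. A
camera-facing capture system whose depth axis decreases as the subject
approaches is mapped to `w` by negation at ingest, which makes every metric
sign stable regardless of hardware placement. Six marker roles are tracked —
handle and tip per crutch, one marker per foot — grouped into four entities
(two crutches, two feet). Occlusion is represented by absence: a frame simply
lacks the occluded role, and absence survives file round trips. Metrics are
reported in the clinical units of the application (degrees, centimetres).

## Movement segmentation

Entity speed is the magnitude of the centered finite difference of the
reference marker's position (foot marker; crutch tip — the placement-relevant
end; the handle enters only the angle), after a moving-average smoothing of
0.2 s. Occlusion gaps up to 0.2 s are linearly interpolated before
differentiation; longer gaps split the series and can never be bridged by a
bout.

Bouts are detected with velocity hysteresis: onset when speed exceeds
`v_on` = 0.10 m/s, offset at the start of the first stretch below
`v_off` = 0.05 m/s lasting at least `min_quiet` = 0.20 s; bouts shorter than
`min_bout` = 0.15 s are discarded. The defaults separate walking-speed
marker movement (peak ≈ 1.9 × step/duration ≈ 0.6–1.5 m/s for typical steps)
from jitter (σ = 1–2 mm at 30 Hz stays an order of magnitude below `v_on`
after smoothing). No capture system dictates these values; all are exposed
in the segmentation config.

Two numerical refinements matter for metric fidelity:

- **Sub-frame endpoint interpolation.** Threshold crossings are linearly
  interpolated between samples. At 30 Hz the frame grid alone contributes up
  to ±33 ms of onset error; synchronicity is a ratio of interval overlaps,
  and at small crutch–foot lags that quantization alone would exceed the
  0.05 recovery tolerance.
- **Plateau-referenced displacement.** Net walk-axis displacement is read at
  the calmest sample within one smoothing window outside each bout endpoint,
  not at the threshold crossings. The marker is static on the flanking
  plateaus, so this removes the bias from the slow movement tails that
  thresholds cut off; displacement recovers configured step length to well
  under 1% even at 2 mm noise.

Bout *duration* still carries the threshold bias: the slow tails of a
bell-shaped speed profile lie below any finite threshold, while the moving
average widens the apparent movement. Net effect with defaults is ≈ +0.03 s
on a 0.6 s bout, so derived step speed is systematically ≈ 5% low. Step
length is unbiased; analyses that need unbiased speed should use step length
divided by the known cycle timing rather than bout duration.

## Pattern matching

A gait pattern is a cyclic sequence of states, each a set of entities that
must all complete one bout — in any order or overlap — before the state
completes. The matcher is greedy and online (no global alignment): it reacts
at the moment of the offending onset, which is the correct model for a live
feedback system and keeps matching deterministic.

Error semantics, where the design was open:

- `wrong_entity` — onset of an entity the expected state does not require.
  A lone crutch move during the single-foot state is penalized this way;
  whether a live system should forgive such balance corrections is
  interpretive, and this package flags them.
- `wrong_order` — a required entity of the current state moving again
  before the state completes (a within-cycle sequencing violation).
- `incomplete_state` — trailing partial state at the end of data.
- After any error the matcher expects the current state from scratch,
  modelling a trainer that asks the user to repeat the movement. Errors are
  data (returned and logged at WARN with timestamp and entity), never
  exceptions.
- **Boundary tolerance**: a non-required entity whose bout begins within
  0.1 s of the current state's completion, and which the next state
  requires, is attributed to the next state rather than flagged — real
  transitions are not knife-edged.

An exercise is `success` iff at least the required number of complete cycles
(default 3) were matched with zero error events; sessions with a sustained
(> 1 s) full-entity marker gap are `excluded` (`tracking_loss`) before any
analysis, and excluded subjects never enter group statistics.

## Metrics

Crutch angle is measured at the crutch's placement (end of its bout);
crutch position at state completion, pairing each crutch with the state's
moving foot; both average the marker positions over a 0.15 s settle window
after the measurement time — the markers are static there, so the window
only suppresses jitter (a single 2 mm-noise frame would otherwise exceed the
0.2 cm position tolerance). The foot-center offset (15 cm) and an additive
cane-mount angle correction (default 0°, since no calibrated value is
available) sit in the metric config. Synchronicity is the intersection of
all required bouts over their union; it is 1 iff all intervals coincide and
is undefined (NaN) for single-entity states. Per-subject summaries are
means and sample SDs (n−1) over all valid cycles with pairwise NaN
exclusion.

## Synthetic sessions

The generator scripts each bout as a minimum-jerk displacement profile
(s(τ) = 10τ³ − 15τ⁴ + 6τ⁵), the standard kinematic model for point-to-point
limb movements; its bell-shaped speed curve exercises the hysteresis
thresholds realistically. Defaults: step length 0.40 m, bout duration 0.6 s,
stance 0.8 s, crutch-onset lag 0.2 s, 4 cycles, 30 Hz, subject height
1.75 m, crutch modelled as a 1.0 m rigid rod (scaled by height) at constant
tilt, tip landing at the configured angle and foot-center offset. Feet lift
5 cm and crutch tips 3 cm during swing. Noise is i.i.d. Gaussian per
coordinate per frame. Identical (params, errors, seed, dropout) give
bit-identical output.

Planned errors are injected in a pre-window before the affected cycle:
`wrong_entity` as an out-and-back bout (net displacement 0) of the named
entity; `wrong_order` as a duplicated injured-foot bout. In both cases the
cycle is then performed correctly, mirroring the repeat-after-alert
protocol, so a planned single error produces exactly one detected event and
a complete session otherwise. Tracking dropout deletes all of a crutch's
roles from a configurable time onward, reproducing the mid-session loss of
crutch tracking that renders real sessions non-analyzable.

Cohorts draw per-subject parameters from configurable normals (truncated to
physical bounds with resampling, max 100 attempts, e.g. durations > 0.1 s),
with an optional per-subject dropout probability.

What the generator does *not* emulate: full-body kinematics, balance
corrections, weight-bearing, non-Gaussian tracking artifacts (ghost markers,
identity swaps), or within-session parameter drift (fatigue). Passing
recovery tests therefore demonstrates the pipeline's correctness on clean
kinematics of the modelled gait, not robustness to every real-world capture
pathology.

## Statistics

All test statistics are computed from first principles; scipy supplies only
the F, χ² and t distribution functions.

- **Two-group MANOVA.** H and E are the between- and within-group SSCP
  matrices; with two groups E⁻¹H has exactly one nonzero eigenvalue λ, so
  Pillai = λ/(1+λ), Wilks = 1/(1+λ), Hotelling trace = Roy = λ, and the F
  transform F = λ(N−p−1)/p on (p, N−p−1) df is exact, identical for all four
  statistics. The implementation is restricted to this two-group case; the
  general g-group approximations are out of scope. λ also equals
  Hotelling's T²/(N−2), which the tests exploit as an independent oracle.
  A singular E raises an error naming the zero-variance variable(s).
- **Levene** centers on group means by default (the common default of
  clinical statistics packages); a median-centered (Brown–Forsythe) variant
  is available via `center="median"`. **Box's M** uses the standard
  log-determinant form with the χ² approximation.
- **Pooling** of group summaries is exact: n-weighted mean, and SD from the
  total (within + between) sum of squares over N−1 — i.e. the SD of the
  concatenated data. Note that two equal-SD groups pool to slightly *less*
  than their common SD (√(2(n−1)/(2n−1)) of it), which is the behaviour
  consistent with published combined columns.
- **SUS**: odd items contribute (r−1), even items (5−r), total × 2.5;
  scores live exactly on {0, 2.5, …, 100}; the conventional above-average
  threshold is a score strictly greater than 68. Questionnaire percentages
  round half away from zero. p-values are formatted journal-style
  (3 decimals, "<.001" floor).

Simulation checks in the test suite: type-I error of the MANOVA is
calibrated to 0.05 ± 0.01 over 10,000 null replicates at n = 12/13, p = 2,
and power at the published group means/SDs exceeds 95% over 500 replicates.
Those replicates draw per-subject metric summaries directly from the group
distributions — the MANOVA consumes subject-level means, so this isolates
the statistical property; a full trajectory-level cohort comparison is
additionally tested end to end at smaller n.

## Problem sizes

Default test problem sizes: 4-cycle sessions (~13.5 s at 30 Hz, ≈ 400
frames), 100 sessions for parameter recovery, 500 replicates for
power/calibration at the metric level, 10,000 for type-I calibration, 6–12
subjects per cohort for end-to-end comparisons. These are the package's
standard verification sizes; all are parameters.

## Known limitations

- Step speed from bout duration is biased ≈ 5% low (threshold tails; see
  above). Step length, angle, position and synchronicity are unbiased.
- The matcher penalizes any non-required movement; there is no notion of a
  harmless adjustment move.
- One marker per foot: foot orientation and true foot center are not
  observable; the 15 cm offset is a population constant, not per-subject.
- MANOVA is two-group only; Levene/Box M assume independent subjects.
- The generator's crutch tilt is constant through the swing, so the angle
  metric is exactly recoverable; real crutch swing varies tilt and the angle
  is well-defined only at placement.
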