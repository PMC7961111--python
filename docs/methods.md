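# Methods

This note documents the models and procedures implemented in `tentlaf`,
the choices made where the design was genuinely open, and what the
simulator-based tests do and do not establish about real data.

## Event model

Time is float seconds from trial start; annotations made at video rate
(30 Hz) convert as `frame / 30`, which decouples all analysis from the
recording frame rate. Subtask intervals are half-open `[t_start, t_end)`
so abutting intervals tile time without double counting; any time not
covered by an interval is *approach* (transitioning between subtasks).
Both conventions are supported for approach: explicit `approach` intervals
in the input, or inference from gaps — the lookup `ongoing_subtask_at`
treats them identically.

Object labels are categories, not instances: all four tent corners are
"tent corner". This matches the annotation vocabulary and implies
category-level LAF closure (any tent-corner touch closes a tent-corner
LAF). Fixations with no object label are off-object ("elsewhere") and
matter only as interrupters: they break fixation runs and satisfy the
LAF separation rule.

## LAF extraction rules

1. **Merging.** Maximal runs of consecutive fixations on one target merge
   into a segment (summed dwell as duration). A run is broken only by a
   fixation on a different target or off-object; a plain temporal gap
   between two same-target fixations does not break it.
2. **Instruction rule.** Multi-fixation runs on the instructions are
   reading, not look-ahead, and are discarded.
3. **Guiding exclusion.** A segment is the guiding look — and never a
   LAF — if it contains a touch of its category, or if such a touch
   follows it with no intervening fixation of any kind. The "any touch"
   scope (rather than only the matched touch) is deliberate: when a
   category is touched repeatedly, the guiding look of touch *k* would
   otherwise qualify as a look-ahead to touch *k+1*, which no annotator
   would code.
4. **Matching.** A surviving segment becomes a LAF iff a touch of its
   category occurs after the segment ends; it is matched to the most
   immediate such touch (one LAF, one touch; several LAFs may share a
   touch and then form a repeat group).

Two latency conventions exist because the defining endpoints differ in
reasonable usage: segment end → guiding-look start (default), and segment
end → touch. Both are always computed and written; the `latency` field
follows the configured convention. When no guiding run can be located the
guide-based latency falls back to the touch and is flagged. The ongoing
subtask is evaluated at the segment start by default (midpoint by flag);
step distance counts non-approach intervals from the interval containing
the LAF start (next-to-start if in approach) to the interval containing
the touch, floored at zero.

The on-/off-task relevance map (subtask → set of relevant object
categories) is a reconstruction from the task's structure, fully
overridable via YAML. It is the one component with no authoritative
source; all on-task fractions inherit its assumptions.

## Subtask-sequence model

The 37-step assembly outline compresses to 12 subtask labels; consecutive
steps of one grouped act merge into a single occurrence while repeated
acts (four corners, four guylines, two poles) are retained, so the
idealized sequence has 23 occurrences and self-transitions at the
repeated subtasks. Transition matrices are first-order with
self-transitions counted; approach is not a state — approach periods are
deleted so flanking subtasks become adjacent.

The idealized reference matrix replaces structural zeros with a floor of
1e-6 and then renormalizes each row (renormalization is optional; it keeps
rows exactly stochastic and changes scores by at most ~1e-5 log units per
transition). Path scores use natural logs; only relative comparisons are
meaningful. Cohort-average matrices average each row over the
participants who actually visited (and left) that state, so averaged rows
remain conditional probabilities.

Bottleneck regressions ask, per subtask, whether time on that subtask
predicts the *rest* of the trial (trial duration minus that subtask's
contribution), with a fixed multiple-comparison alpha of 0.004 (0.05/12).
Simple OLS reports F(1, n−2); a constant predictor yields a flagged
undefined result, a constant response a zero slope with R² = 0.

## Statistics

- Latency distributions: 10 s bins in time mode; 1-step bins centered on
  integers in step mode; cumulative shares are right-edge CDF values.
- The two-sample t-test defaults to the pooled-variance Student form
  (df = n1 + n2 − 2), with Welch–Satterthwaite df behind a flag.
- The composite experience score codes categorical items first
  (low/medium/high → 0/0.5/1; owns-tent yes/no → 1/0), divides each item
  by the *observed* cohort maximum (a declared scale maximum can be
  supplied instead), and averages the five normalized items equally.
- Calibration error is the per-point Euclidean gaze–target distance in
  degrees, summarized as the per-participant median per phase; a
  participant is excluded when the mean of the pre- and post-trial
  medians exceeds 5°.

## Simulator

The generator emulates the *structure* of tent-assembly behavior, not its
biomechanics: state sequences from the (floored idealized) transition
matrix with a uniform-noise mixture (default 0.05); per-subtask lognormal
durations (stand-ins sized so a typical trial lasts on the order of ten
minutes, with instruction reading and pole assembly the most variable);
approach gaps (probability 0.7, lognormal mean 4 s); touches of each
subtask's relevant objects at 0.7 s spacing from the interval start, each
spanned by a 0.5 s guiding fixation.

LAFs are injected by a Poisson process at 2.7 events/min (the budget
covers repeats, so the hazard is the rate of *all* LAFs). Each injection
is flanked by off-object filler fixations so it can never merge into a
guiding run, and fresh injections always take an unused (object, touch)
pair so repeat groups arise only from the explicit repeat mechanism.
Injected dwells are lognormal with mean 0.583 s and SD 0.206 s; with
probability 0.3 an injection is a two-fixation run (exercising the
merger), except on the instructions where the single-fixation rule binds.

Two design points matter for parameter recovery:

- The on-/off-task flag (default probability 0.47) is drawn once per
  injection, and a position is accepted only if *both* flags could be
  honored there, so position acceptance is independent of the flag and
  the realized on-task fraction among applicable LAFs is exactly
  Bernoulli in the configured probability.
- The repeat probability (default 0.45) governs the revisit-attempt
  chain. A repeat must fit between the previous LAF and the touch's
  guiding look, so when the touch is imminent the chain is cut short and
  the realized revisit fraction falls below the configured value. The
  recovery test therefore uses a regime with distant touches and low
  crowding, where blocking is rare.

Latencies are not drawn directly: they emerge from step-ahead choice
(geometric over future touchable objects, default p = 0.35) and subtask
durations, mirroring how the task itself produces the heavy right tail.
A direct two-component lognormal latency mixture (a short action-driven
component, weight 0.35, median 4 s; a long planning-driven component,
median ~65 s) is provided for distribution-recovery tests; its defaults
place ≈35% of mass below 10 s and ≈75% below 100 s, matching the
cumulative shares used in the accounting checks.

Cohorts derive per-participant sub-seeds from `SeedSequence([seed, index])`,
so runs are reproducible end to end and any participant can be re-run
alone. Default cohort size is 18 (the size of a typical included cohort
for eye-movement analysis in this task).

**What passing tests show — and don't.** Exact extractor inversion on
simulator output shows the extraction rules are implemented correctly and
self-consistently; it says nothing about annotation noise, gaze-to-object
mapping error, or idiosyncratic behavior in real recordings, none of
which the simulator emulates (touches at interval starts are a
simplification; there is no gaze geometry, no incidental fixations on
future targets, and no instruction-reading content). Monte-Carlo recovery
shows estimator consistency under the generative model only.

## Numerical choices

- Row-stochasticity tolerance 1e-9; oracle agreement asserted at 1e-10.
- Zero-probability transitions score −∞ with a flag rather than raising
  (impossible against a floored matrix).
- Sequence sampling stops at the terminal state (vent cover) or at a cap
  of 80 occurrences; injection placement retries up to 80 positions and
  drops the injection (counted in the manifest) if none fits.
- Event CSVs write times with shortest round-trip float text and are read
  back with round-trip parsing, so write→read is exact.

## Known limitations

- The relevance map is a reconstruction; on-task fractions change under
  other defensible mappings (hence the YAML override).
- The extractor assumes already-annotated events; fixation detection and
  gaze-to-object assignment are upstream concerns.
- First-order Markov structure ignores longer-range sequential
  dependencies that real assembly strategies exhibit.
- Realized revisit fractions undershoot the configured repeat probability
  under crowding, as described above.
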