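# tentlaf

Look-ahead fixation (LAF) analysis for extended sequential visuomotor
behavior, built around the natural task of assembling a camping tent.

During long multi-step tasks, people do not only fixate the object they are
currently manipulating: they also *look ahead* to objects they will need
later. `tentlaf` turns annotated event streams — subtask intervals,
object-labeled fixations, and touch events — into a full quantitative
description of that behavior. It is aimed at eye-tracking and visuomotor
researchers who have (or want to simulate) event-level annotations of
sequential natural behavior.

## What it computes

**LAF extraction.** A LAF is a maximal run of consecutive fixations on an
object category that the participant touches later, separated from the
*guiding look* (the fixation that accompanies the hand's arrival) by at
least one fixation elsewhere. Runs that guide a touch are excluded, as are
multi-fixation runs on the instructions (reading). Each LAF is matched to
its most immediate future touch of the same category and annotated with:

- latency `Δt = t_guide − t_LAF-end` (or to the touch itself, by flag),
- step distance: number of non-approach subtask intervals between LAF and
  touch,
- on-/off-task status: whether the target is relevant to the ongoing
  subtask (approach and instruction periods are not applicable),
- repeat group: LAFs revisiting the same target before one touch.

**Subtask-sequence scoring.** Each participant's chronological subtask
occurrences (over 12 labels compressed from a 37-step outline) are treated
as states of a first-order Markov chain. The per-participant transition
matrix `P` is the row-normalized count matrix (self-transitions included);
cohort matrices are row-wise means over participants who visited each
state. Sequences are scored against an idealized reference matrix — the
count matrix of the canonical assembly sequence with a probability floor
`ε = 1e-6` replacing structural zeros — by the path log-probability

```
L(s) = Σ_k ln P(s_k → s_{k+1})
```

**Statistics.** Latency histograms and cumulative distributions (10 s or
1-step bins), LAF rates per minute, ongoing-task × target cross-tabs,
on-task fractions, repeat-structure summaries, simple OLS
(β, R², F(1, n−2), p) and pooled/Welch two-sample t-tests, composite
experience scores from a five-item questionnaire, and gaze-calibration
error with a 5° inclusion rule.

**Simulator.** A generative model of the task emits event logs with known
ground truth: a subtask sequence sampled from the reference matrix,
lognormal subtask durations with approach gaps, touches with guiding
fixations, and LAFs injected by a Poisson process (default 2.7/min) with
controlled on-task probability, geometric step-ahead distribution, and
repeat probability. The extractor provably recovers the injected truth
exactly, which anchors every downstream test.

## Worked example

```
tentlaf simulate --seed 5 --participants 3 --out out/sim
tentlaf extract  --events out/sim/events.csv --out out/ext
tentlaf analyze  --events out/sim/events.csv --lafs out/ext/lafs.csv --out out/ana
```

prints (deterministically, for this seed):

```
tentlaf 0.1.0 analysis report

participants: 3; total LAFs: 75
mean path log-probability vs idealized reference: -23.393
bottleneck subtasks (alpha=0.004): ['support bag']
LAF rate per minute: M=2.62 SD=0.62 range=(1.99, 3.22)
mean on-task fraction: 0.400
on- vs off-task latency: t(73)=-1.81, p=0.0744 (on M=21.5s, off M=44.6s)
repeat structure: 45 groups, 27 isolated, 48 LAFs in repeat sequences (40% of targets revisited)
```

Reading this: the three simulated participants produced 75 LAFs at about
2.6 per minute (the simulator's default hazard is 2.7/min). Their subtask
paths score −23.4 natural-log units against the idealized assembly
sequence (more negative = more unusual ordering). 40% of applicable LAFs
targeted an object relevant to the ongoing subtask; on-task LAFs had
shorter latencies than off-task ones (21.5 s vs 44.6 s here, not
significant at this tiny n). 40% of LAF targets were revisited at least
once before being touched. Per-table CSV outputs (transition matrices,
latency distributions, cross-tabs, regressions) land in `out/ana/`.

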