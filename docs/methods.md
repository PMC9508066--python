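# Methods

## Scope

`pmtrack` implements the complete analysis chain for a dynamic-start
mouse-tracking paradigm probing prospective-memory (PM) aftereffects and
ongoing-task costs, plus a synthetic generator for the same paradigm. The
analysis chain is the deliverable; the generator exists so that every stage
can be validated against known ground truth without participant data.

## The paradigm encoded in `ExperimentConfig`

A 1280×1024 px screen; trials start at the bottom midline (x = 640, 10 px
above the bottom edge) and the response stage begins once the cursor has
travelled 160 px upward. Each of 12 cycles contains an active phase
(40 standard / 4 PM / 4 oddball trials) and a finished phase, which in the
PM-task-repetition condition has 40 standard / 4 PM_REPEATED / 4 oddball /
4 new-PM trials and in the ongoing-task-only condition 40 standard /
4 PM_REPEATED / 8 oddball trials (two cues × 4, equating deviant-stimulus
counts). Conditions alternate across cycles and half the participants start
with each. Blocks open with two standard trials and every cue-bearing trial
is followed by at least two standards. Stages time out at 1,500 ms; the
cursor is sampled at 100 Hz.

Raw trajectories are stored in screen convention (origin top-left, y
downward) exactly as pixel hardware logs them; the upward-positive transform
`y_u = screen_h − y` is applied only during normalization. Trials are keyed
by `(participant_id, cycle, trial_index)` with `trial_index` running
continuously through a cycle (active block first), which keeps the key
unique without a phase column in the trajectory table; the within-block
position is `trial_index` minus the block offset.

Response boxes are modelled as circular containment regions (radius 110 px)
around nominal centroids of the two parity boxes (upper-left corner) and
the PM box (upper-right corner). The exact box geometry of the original
hardware is unknown; only containment ("the cursor entered the box") and the
approach direction matter for any computed quantity.

## Preprocessing

Two analysis pools are defined on finished phases:

* **aftereffects** — PM_REPEATED vs. oddball trials;
* **costs** — standard trials, minus the single standard immediately
  following any cue-bearing trial (post-deviant slowing would otherwise
  contaminate the baseline). New-PM trials count as cue-bearing here.

Both pools then drop wrong-box responses, commission errors and timeouts,
and finally apply a single-pass ±3 SD RT rule per participant × trial type ×
condition (sample SD, computed on the cell before removal; cells with < 2
trials are skipped). The pass is single and non-iterative — the field
default — and runs after the error exclusions, matching the stated order of
the original pipeline. Timeout trials carry no completed response and are
excluded everywhere; exclusion reports carry per-participant counts and
fractions.

Trajectories are resampled by linear interpolation at 100 equally spaced
time points spanning the response stage (endpoint-preserving and idempotent
on already-normalized input), then recentered (`x_c = x − 640`) and flipped
(`y_u`). No smoothing or arc-length resampling is applied.

## Kinematic measures

* **AUC** (px²): signed area between the path and the straight chord from
  its first to its last point, by the shoelace formula on the closed
  polygon. Rightward (PM-side) deviation of an upward movement is positive;
  the measure is translation-invariant and antisymmetric under x-reflection.
  Degenerate paths (first = last point) return 0 with a warning. z-scores
  are computed per participant over the union of the compared cells, with
  the population-SD convention (ddof = 0; switchable), pinned in tests.
* **Angle** (∈ [−1, 1]): per step, `atan2(Δx_c, Δy_u)` in degrees, clamped
  to ±90° and divided by 90. Response-stage movement is upward-dominated,
  so |θ| > 90° is rare and fixed scaling keeps units comparable across
  participants; a per-participant max-|θ| rescaling variant is available
  (`angle_standardization="participant_max"`) since per-participant
  standardization admits both readings. Zero-length steps inherit the
  previous angle. The standardization is orientation-specific (built for
  upward movement); speed, not angle, is the measure that commutes exactly
  with time reversal.
* **Speed** (px per normalized step): `√(Δx_c² + Δy_u²)`. Note that after
  time normalization the sum of step speeds equals the path length, so
  overall movement duration does not affect mean speed — only its
  distribution over normalized time and the path geometry do.

A 100-point path yields 99 step values; step k sits between positions k and
k+1, so segment bounds are reported on the 1..99 difference grid (printed
step indices of a 1..100 grid map onto it with at most one step of
ambiguity, which is below the 10-step reporting threshold).

## Time-continuous statistics

The two-stage random-effects scheme standard in this literature: per
participant and per time step, OLS of the dependent across trials on
effect-coded (−1/+1) predictors plus intercept (trial type, finished-phase
condition, and their product, depending on the analysis scope); then per
step a two-sided one-sample t-test of the betas across participants
(df = n − 1). With balanced cells, effect coding makes each beta the
half-difference of cell means — the closed form the test suite pins to
1e-10. No multiple-comparison correction is applied beyond the reporting
rule: only maximal runs of ≥ `min_run` = 10 consecutive steps with p < α =
.05 are reported, signed by the group-mean beta; a sign flip inside a run
splits it, since a mixed-sign run is uninterpretable as one effect. Steps
with zero between-participant variance get p = 0/1 by the sign of the mean,
with a warning.

## Discrete statistics

The 2×2 within-subject ANOVA uses the standard SS decomposition with each
effect tested against its own participant-interaction error term,
df = (1, n − 1), and partial η² = SS_eff/(SS_eff + SS_err), which for 1-df
effects equals F/(F + df_err) — one formula serves every reported effect
size. Paired t-tests report d = mean(diff)/SD(diff) = t/√n with a 95% CI by
noncentral-t inversion (the bracket for the noncentrality root expands
adaptively because low-df noncentral t has heavy tails). Commission rates
are percentages of PM-box entries among all finished-phase PM_REPEATED
(resp. oddball) trials, timeouts included in the denominator; the two
oddball cues of the ongoing-task-only condition are pooled. The minimal
detectable effect size solves the noncentral-t power function of the
two-tailed paired t-test by bisection; a 10,000-rep Monte-Carlo simulation
cross-checks it in the acceptance suite. The exploratory deflection/slowing
correlation reduces each participant's mean PM_REPEATED angle and speed
series to the maximum angle over steps 34–66 ("second third") and the
minimum speed over steps 67–99 ("last third") — the verbal window
definitions fixed to the difference-step grid — and correlates the pairs
across participants (df = n − 2).

## The synthetic generator

`build_design` constructs per-participant schedules by shuffling
`[cue, standard, standard]` units with leftover single standards after two
leading standards — every admissible count set satisfies the sequencing
constraints by construction, and infeasible counts (standards < 2 + 2 ×
cues) raise. Digits are uniform on 2–9; cue symbols are drawn per cycle
from a per-participant shuffled pool, with the PM_REPEATED cue equal to the
active phase's PM cue.

`simulate_trajectory` generates the response stage of one trial:

* The baseline reach is a **minimum-jerk** position profile — the standard
  smooth-reach null — aimed past the box centroid (overshoot 220 px): the
  participant targets the box *area* and the stage ends at box **entry**,
  so the boundary is crossed at substantial speed rather than at the end of
  the deceleration. Without this, the late-window speed minimum collapses
  onto the terminal deceleration/noise floor and carries no information
  about injected slowing. The drawn RT is the entry time.
* A **deflection** toward the PM box is a raised-cosine *velocity* bump
  (px per normalized step) over a window of observed movement time
  (default 0.30–0.60), so that angle — which differentiates position —
  inherits a bump of matching latency; an optional compensatory bump of
  opposite sign (`return_amp`, default off) emulates
  centered-then-corrected movement, used for the costs condition's standard
  trials. The baseline absorbs the net displacement so the movement still
  ends inside the chosen box.
* **Slowing** multiplies movement progress by `1 − slow_amp · bump` over a
  late window (default 0.65–0.95) with entry time held fixed, so the speed
  dip is accompanied by a shallow compensatory speed-up elsewhere — a
  necessary property of any fixed-endpoint, fixed-duration movement, and
  consistent with mid-trial speed-ups preceding late slowing in this
  paradigm.
* Isotropic Gaussian **noise** (default 4 px) per sample, target jitter
  (12 px SD), log-normal RTs (σ = 0.22) truncated at the stage timeout
  (slower draws become response-stage timeouts, ~1% of trials, which carry
  no trajectory), and with probability `p_commission` full **capture** into
  the PM box (the commission-error definition: the trial ends as soon as
  the cursor enters the PM box).

Cell parameters of the `paper_like_effects` preset encode the reported
phenomenology: cell mean RTs 1010/932 (PM-task-repetition PM_REPEATED /
oddball), 762/734 (ongoing-task-only), 684/657 (standards), 676/828/915
(active standard/PM/oddball) ms; commission probabilities 2.6/1.05/0.4/0.05%
across the four deviant cells; deflection amplitudes 2.6/2.2 px/step for
PM_REPEATED vs. 0.6 for oddball (oddballs get a small orienting deflection
of their own so contrasts, not absolute deflection, carry the effect);
slowing 0.30/0.25 vs. 0.08; and for PM-task-repetition standards an early
central-channel bias with late return plus early slowing (the costs
signature). Between-participant heterogeneity is a shared log-normal
multiplier (σ = 0.4) on all deflection/slowing amplitudes — the shared
factor is what links a participant's deflection to their subsequent slowing
and produces the negative peak/trough correlation — plus a log-normal RT
multiplier (σ = 0.12).

### What the generator does *not* emulate

Real trajectories contain corrective submovements, pauses, curvature
idiosyncrasies and x-flips; RT distributions have heavier right tails; and
effect sizes vary between participants beyond a single shared amplitude
factor. In particular, because the injected RT cost is a fixed shift,
simulated discrete effect sizes (e.g. the costs d) run larger than typical
empirical values at the same mean difference. Passing tests therefore show
that the pipeline *recovers what was injected* under realistic noise — not
that real data would yield the same segment boundaries or effect sizes,
which are properties of the behavioral data themselves.

## Problem sizes and numerical choices

Recovery checks run 100 replicates at the full design size (n = 42
participants) but instantiate trajectories only for the trials the
aftereffects analysis consumes (finished-phase PM_REPEATED/oddball of the
ongoing-task-only condition); the design itself is always built in full, so
sequencing and counterbalancing are identical to a complete run. The
false-positive control runs the identical harness with all trajectory
effects zeroed. Oracle equivalences use 100 random balanced designs (OLS,
1e-10), 10,000 random p-series (segment scan vs. brute force), and 100
random tables (ANOVA vs. an independent implementation). Interpolation is
linear in time; OLS uses `numpy.linalg.lstsq` with an explicit rank check;
t/F tail probabilities come from scipy; the minimum-jerk inverse uses a
513-point lookup with linear interpolation; all randomness flows from a
single `numpy` SeedSequence, spawned per stage so stages can be re-run
independently.

## Known limitations

* The angle standardization's fixed-scaling default is one of two readings
  of per-participant standardization; both are implemented, and segment
  boundaries can shift by a few steps between them in data with wide angle
  ranges.
* The 3-SD outlier rule's cells are scoped to finished-phase analyses;
  whether means/SDs should cross phases is undefined for this design and
  irrelevant to the analyses implemented.
* Segment bounds are reported on the 99-step difference grid; comparisons
  with bounds printed on a 100-step position grid carry one step of
  indexing ambiguity.
* The commission-rate denominator includes timeout trials; excluding them
  changes rates by well under the between-participant SD at realistic
  timeout rates.
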