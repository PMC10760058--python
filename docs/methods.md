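# Methods

## Task and conventions

The toolkit models the desk-scale visuomotor-rotation reaching task: on
each trial a participant shoots a cursor from a start circle through one of
4 cardinal targets (0°, 90°, 180°, 270°); on perturbed trials the cursor is
rotated relative to the hand. Throughout the package, counter-clockwise
cursor rotations are positive and adaptive hand responses that oppose a CCW
rotation are reported as positive movement angles, so learning curves rise
toward the rotation magnitude. Trials are grouped into epochs (cycles) of 4
— each target once per epoch, in randomized order — and the epoch is the
unit of all averaging. "Epoch" and "cycle" are used interchangeably.

A schedule is fully determined by (paradigm, parameters, master seed). The
master seed is split with `numpy.random.SeedSequence.spawn` into independent
streams for target-order randomization and trial-wise rotation sampling, so
changing one leaves the other untouched. Breaks (30 s rests) are flags on
the preceding trial, never phantom trials, keeping indices aligned with
protocol statements like "after trial 160". The practice block (80 null + 8
no-feedback trials) is produced by the same builder with a practice flag so
it inherits the structural invariant checks.

Paradigm block structures (epochs): savings and interference run
baseline 10 / rotation 30 / washout 30 / re-rotation 30 (400 trials, rests
after trials 160 and 260; the second rotation matches or opposes the first,
respectively); spontaneous recovery runs 10 / 60 / counter-rotation 10 /
no-feedback 20 (400 trials, rest after 160); the standard aftereffect
design and its delayed-feedback, limited-preparation-time and high-variance
variants run 10 / 60 / no-feedback 20 (360 trials). The high-variance
variant samples each rotation-phase trial from N(30°, 12°). The
gradual-rotation builder ramps linearly per epoch (the ramp shape is not
prescribed anywhere; linear is the assumption, and `ramp_epochs=1`
degenerates to an abrupt schedule). Error-clamp trials carry the clamp
angle in `rotation_deg` with a dedicated feedback mode; they are included
for schedule completeness and the simulator treats their error as the clamp
angle irrespective of hand direction (the standard clamp convention), but
no experiment here validates them.

## Online task rules

Movement-time limits: a reach faster than 10 ms or slower than 275 ms
forfeits the point with a negative tone; movement times above 600 ms or
reaction times above 1000 ms add an on-screen warning. A hit requires the
terminal angular error to fall within the target's angular half-width; from
the stated display geometry (target 0.04% of screen size, radial
displacement 10× the target size) this is asin(1/20) ≈ 2.87°, which is the
default and is configurable. The practice gate requires strictly more than
65% successful trials (MT < 600 ms, RT < 1000 ms, |error| ≤ 30°); the 65%
boundary itself fails.

The preparation-time threshold staircase starts at 350 ms and, once its
10-trial success window is full, moves 5 ms down when ≥ 8 of the windowed
trials beat the threshold and 5 ms up otherwise, clamped to [280, 350] ms.
"Moving windows of 10 trials" is read as a sliding window evaluated every
trial after the first ten; a non-overlapping block mode (update every 10th
trial) is available behind `block_mode=True` since the wording admits both.
A "successful" reaction time during calibration is RT ≤ the current
threshold — the only threshold in scope. Calibration spans 84 trials (the
44-trial second practice half plus 40 baseline trials) and the state is
then frozen. Screen-delay adjustment (subtracting the 154 ms average
display latency, mapping the staircase bounds to true preparation times of
126–196 ms) is applied only in analysis, never in the online rule.

## Simulator

Each synthetic participant is a two-state learner. On feedback trials the
target error is e = r − (x_i + x_e); the implicit state updates as
x_i ← a_i·x_i + b_i·e and the explicit state as x_e ← a_e·x_e + b_e·e. On
no-feedback trials e = 0 and both states decay by retention. The error
entering the implicit update is the shared residual r − x_i − x_e: this is
the reading under which the implicit steady state obeys the competition
relation x_i = p_i(r − x_e) with p_i = b_i(1 − a_i + b_i)⁻¹ for any fixed
or co-converging explicit state, and the iterated dynamics are verified
against that closed form to < 1e-6 degrees over a parameter grid.

Only the implicit update and the competition steady state are prescribed by
the theory; the explicit dynamics are this package's modeling choice: a
second, faster state (lower retention, higher error sensitivity), the
standard fast process of two-state motor-learning models. Defaults are the
canonical slow/fast constants: a_i = 0.996, b_i = 0.02 (implicit gain
p_i ≈ 0.83), a_e = 0.92, b_e = 0.21. With these, the standard design yields
total adaptation ≈ 26.5°, implicit aftereffect ≈ 15° and explicit strategy
≈ 11° — the right orders of magnitude for a 30° rotation — and the
spontaneous-recovery design rebounds to a positive angle during the
no-feedback block. An earlier ad-hoc pair (a_i = 0.98, b_i = 0.05) unlearned
too fast during the brief counter-rotation to rebound positive, which is
why the canonical constants were adopted.

Expression and instructions: the movement angle is x_i + x_e plus Gaussian
motor noise (default s.d. 3.5°, typical endpoint scatter for cursor
reaches). An aim-straight instruction withholds the explicit component
(angle = x_i + noise) while preserving the state; keep-aiming expresses the
full angle with no feedback-driven update (no-feedback trials deliver no
error anyway). The 30 s instruction pause costs the implicit state one
extra retention step, capturing passage-of-time decay. Reaction time is
rt_base + slope·|expressed strategy| + noise (defaults 400 ms, 4 ms/deg,
60 ms s.d.), so strategy users show an elevated rotation-phase median RT
and the aim-straight block returns to baseline.

Condition modifiers scale the sensitivities: delayed endpoint feedback
multiplies b_i by 0.1 (≈ 90% aftereffect reduction — a configurable default,
not a claim); the high-variance perturbation multiplies b_i by 0.8 and b_e
by 0.5; limited preparation time disables the explicit system; the
non-responder phenotype disables strategy and sets b_i ≈ 0 (flat curves).
Savings and interference are produced by second-exposure scales: savings
doubles b_e from the second rotation onward (a primed explicit memory),
interference halves both sensitivities on the opposite rotation. An
"experienced" participant carries an explicit prior: a remembered re-aiming
magnitude engaged when the first perturbed feedback trial is noticed and
held thereafter, adding to the expressed aim and subtracting from the error
the adaptive states see. Modeling it as a mere initial value of the leaky
explicit state would wash out during baseline and do nothing; the held
prior reproduces the observed pattern — higher total adaptation with a
suppressed implicit aftereffect, points translated along the same
competition line.

Cohorts draw participant parameters i.i.d. from truncated-normal priors
around the defaults (s.d. 0.005 on a_i, 0.01 on b_i, 0.02 on a_e, 0.05 on
b_e, clipped to [0, 1]) with per-participant seeds spawned from the master
seed, so cohorts are bit-reproducible.

The simulator does forward simulation and closed forms only — no fitting of
the state-space model to data. Use-dependent or reinforcement residuals
(the few degrees of aftereffect that survive feedback delays in real data)
are not mechanistically modeled; the non-responder phenotype is a
parameter regime, not a mechanism.

## Measurement pipeline

Movement angle: the signed angle between hand and target (relative to the
start) at the first crossing of 95% of the radial displacement, linearly
interpolated between the bracketing samples; verified against exact plane
geometry to < 1e-6 degrees. Movement initiation (for RT) is the first
sample beyond 5% of the radial displacement (configurable; the protocol
defines RT only as target onset to initiation). Trials that never cross the
95% radius are invalid; invalid trials are excluded from epoch means but
retained in files with a validity flag (the exclusion rule is this
package's choice — no rule is prescribed).

Baseline subtraction removes the mean of the 3 epochs immediately preceding
rotation onset; for a second, opposite-signed exposure the series is
sign-reversed first so both exposures read as positive adaptation. The
savings/interference angular metric (Δangle) is the early change (mean of
rotation epochs 1–3 minus the preceding 3 epochs) on exposure 2 minus
exposure 1, computed on baseline-subtracted series. The rate metric fits
y(t) = A + (y_pre − A)·exp(−ρt) with the curve constrained through the
pre-onset epoch value y_pre at t = 0 and rotation epochs at t = 1, 2, …;
free parameters are ρ ∈ [0, 10] and A ∈ [−90, 90], least squares with
multiple starts over a geometric ρ grid. The "3-parameter" count includes
the constrained initial value. A flat series equal to y_pre leaves ρ
unidentifiable and returns ρ = 0 (slowest-rate tie-break). Δrate is
ρ₂ − ρ₁; both Δ metrics are antisymmetric under swapping exposures.

Decomposition: total adaptation is the mean of the last 5 rotation epochs;
the implicit measure is the mean of the first 5 (early), last 5 (late) or
all (full, used for small unresponsive subgroups) no-feedback epochs;
explicit strategy is total minus the designated implicit measure, exactly,
so the identity explicit + implicit = total holds by construction.
De-correlated variants for the ANCOVA use disjoint epochs — implicit from
no-feedback epochs {2, 4, 6}, explicit from total minus epochs {1, 3, 5} —
so motor noise is not shared between the measures (their correlation on
white noise is ≈ 0 by Monte-Carlo check). Spontaneous-recovery period means
cover cycles 1–10 (baseline), 79–80 (end of counter-rotation) and 81–100
(no-aiming). Preparation-time summaries use phase medians (robust to the
occasional extreme RT) and report the rotation-minus-baseline change;
screen-delay adjustment shifts the medians but not the change.

## Cohort statistics

The competition regression is ordinary least squares of implicit learning
on explicit strategy: under x_i = p_i(r − x_e) the slope is −p_i and the
intercept p_i·r, so |slope| estimates the implicit gain and intercept/r
should match it — reported as `p_i_hat` and `intercept_over_r` with 95%
CIs. (The regression orientation is the standard one; reversing it is a
one-line change for anyone who wants the other conditional.) Parameter
recovery is unbiased to < 2% at n = 200 over 500 replicate cohorts.

Responder sorting fits 1- and 2-component Gaussian mixtures
(scikit-learn, 10 restarts, fixed seed) to the 1-D adaptation feature —
the mean of the last 10 rotation epochs — and selects by AIC; with two
components the higher-mean one is "responsive". The mean ± s.d. display
sometimes shown for this feature is treated as descriptive; a 2-D feature
can be passed by stacking, but 1-D is the default.

The ANCOVA (implicit ~ explicit + group) uses Type-II sums of squares
(robust to predictor order in these balanced-ish designs) via statsmodels,
reporting F, p and partial η² for the group factor and the covariate; its
type-I error is verified to sit in [0.03, 0.07] at nominal 0.05 under a
null simulation. Group-test wrappers (one-sample/paired/unpaired t,
Wilcoxon rank-sum, Shapiro–Wilk, one-way ANOVA with post-hoc Tukey HSD,
repeated-measures ANOVA) delegate to scipy/statsmodels and return tidy
dicts (test, statistic, df, p, effect size, n). Post-hoc comparisons use
Tukey HSD only; no further multiplicity correction is added. Identical
paired vectors return t = 0, p = 1 rather than NaN.

## What the synthetic data does and does not show

The generator emulates: epoch-level learning curves with competition
between the systems, savings/interference/spontaneous-recovery signatures,
instruction-gated aftereffects, strategy-linked preparation-time shifts,
and responder/non-responder heterogeneity. It does not emulate: trial-level
kinematics beyond the linear RT model, use-dependent biases, attention or
fatigue drift, device differences (trackpad vs mouse), or outlier behavior
of real at-home participants. Passing tests therefore certify the pipeline
(measures, fits, tests) against a known ground truth, not the empirical
claims themselves — cohort-level human statistics depend on unreleased
participant data and are deliberately out of scope.

## Problem sizes and numerics

Simulated cohorts in the test suite use 10–15 participants of 360–400
trials, matched to the protocols' structure; steady-state equivalence
iterates the update to a 1e-14 fixed-point tolerance; the exponential-fit
grid covers ρ ∈ [0.05, 1], A ∈ [5, 30]; regression recovery uses 500
replicates at n = 200; the ANCOVA null calibration uses 1000 replicates at
n = 25 per group. Degenerate inputs are defined behavior: zero-variance
rotation draws return the mean exactly; all-invalid epochs propagate NaN;
zero-variance explicit vectors make the competition regression refuse to
fit; negative screen-delay-adjusted RTs are returned and flagged by
consumers rather than clipped.
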