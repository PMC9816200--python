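# Methods

## The decision problem

A double-target trial shows 10 elements: one easy target among N_E easy
elements and one difficult target among N_D = 10 − N_E difficult elements
(N_E = 1…9). Correct gap discriminations earn +2 cents, errors cost 2
cents, and the session clock (390 s) is decremented by each trial's
stimulus-onset-to-response duration, so the agent's effective objective is
cents per second. Search is serial and self-terminating: only the fovea can
tell targets from distractors (minimum element spacing 5° guarantees this),
so finding the target of an n-element set costs (n−1)/2 distractor
inspections in expectation under a uniformly random inspection order
without replacement.

## Ideal observer

For each condition and target option t ∈ {easy, difficult} with set size n:

    E[time](t)   = t_plan + (n − 1)/2 · t_insp + t_resp          (s)
    E[reward](t) = 100 · (p_t · r⁺ + (1 − p_t) · r⁻) = 2(2 p_t − 1)  (cents)
    g_t          = E[reward](t) / E[time](t)                      (cents/s)

where p_t is the option's discrimination accuracy. The target's own viewing
time is not a separate term: response time is measured from the offset of
the last gaze shift, so it already contains the terminal target dwell.
ΔG = g_easy − g_difficult is the sole model input per condition; the
optimal target is argmax with ties broken toward easy. The session-level
*theoretical maximum* gain aggregates over the equal mix of the nine
conditions as a ratio of sums, Σ E[reward] / Σ E[time], matching how
empirical gain is computed (accumulated points over session time) — the
mean of per-condition ratios would be a different and wrong estimand.

## Generative model

Two free parameters, both in the gain units (cents/s):

- σ_d, **decision noise**: ε ~ N(0, σ_d²) is added to ΔG once per trial.
- σ_f, **fixation noise**: the noisy gain difference is transformed by a
  cumulative Gaussian, b = Φ((ΔG + ε)/σ_f) ∈ [0, 1], the per-trial bias
  toward the easy set. At σ_f = 0 the transform degenerates to a step in
  the sign of its argument.

The bias acts on the *odds scale*: w = b/(1 − b) multiplies the remaining
easy-element count when the next fixated set is sampled. With e easy and d
difficult elements remaining (targets included, e, d ≥ 1 until
termination), the easy set is chosen with probability q = w·e/(w·e + d); a
chosen set's fixation lands on its target with probability 1/size,
otherwise one of its distractors is removed. The walk ends at the first
target; no path exceeds 9 fixations (8 distractors + 1 target). A bias is
naturally > 1 on this odds scale, which is why w rather than b is the
quantity entering the sampling rule; neutral bias is b = 0.5 ⇔ w = 1, under
which the 10 elements are exchangeable and each target is found first with
probability 0.5.

**Exact enumeration.** Because every fixation removes exactly one element
from the fixated set, the path to the state "i easy and j difficult
distractors removed" fixes all fixation counts; full-tree expectations
therefore reduce to a dynamic program over the (N_E × N_D) state grid.
Each state contributes two terminal branches (easy/difficult target hit).
The implementation is vectorized over an array of weights, and terminal
path probabilities sum to 1 to ≤ 1e−12.

Two fixation-proportion summaries are computed and deliberately kept
distinct:

- `p_fix_chosen = E[(fixations on found-target's set)/(total fixations)]`,
  the per-trial mean proportion (terminal target fixation included in both
  numerator and denominator) — the reporting quantity;
- `expected_fix_chosen / expected_fixations`, the ratio of expectations —
  the quantity pooled fixation *counts* estimate, used in the likelihood.
  Binding the likelihood to the matching estimand avoids a small but
  systematic bias (Jensen gap between E[X/Y] and E[X]/E[Y]).

**Noise marginal.** Predictions marginalize over ε with 61-node
Gauss–Hermite quadrature (fixed order, documented constant), making model
predictions deterministic; σ_d = 0 collapses to a single tree evaluation.
The ancestral sampler `simulate_trial` draws the same process one path at a
time and serves as an independent Monte-Carlo oracle in the tests (the two
routes agree within 3 standard errors at 10⁵ draws).

Expected trial gain uses the *found* target's reward and accuracy (not the
a-priori optimal one), combined with planning/inspection/response timing
and the tree-expected number of distractor fixations. The predicted
session gain aggregates the nine conditions as a ratio of sums, and is
bounded above by the theoretical maximum for every noise setting (verified
numerically over a parameter grid).

## Fitting

The likelihood treats, per condition, the number of easy-target choices as
Binomial(n_trials, p_choose_easy) and the pooled number of fixations on the
chosen set as Binomial(n_fix_total, expected_fix_chosen/expected_fixations).
Within-trial fixations are in truth dependent (sampling without
replacement), so the second factor is a *pseudo-likelihood*; parameter
recovery shows the resulting estimator is nonetheless essentially unbiased
at interior truths (median estimates within a few percent of (0.3, 0.6) at
200 trials/condition over 20 replicates). Probabilities are clipped to
[1e−9, 1 − 1e−9].

Optimization is a 25 × 25 log-spaced grid on [1e−4, 10]² — bracketing
plausible noise levels (≈0.3 and ≈0.6 cents/s) by more than an order of
magnitude each way — followed by Nelder–Mead refinement in log-parameter
space from the grid optimum; the procedure is deterministic. Standard
errors come from the finite-difference observed information at the optimum
and are reported as NaN when the Hessian is not positive definite (e.g., on
the boundary). A choice-only likelihood is available via `choice_only=True`.
Per-(σ_d, σ_f) predicted curves are cached, so recovery studies re-use the
grid across replicates.

## Synthetic sessions

The generator emulates the study conditions: nine double-target conditions
in shuffled miniblocks (18 conditions in single-target mode), a 390-s clock
decremented after each trial with the final trial allowed to overshoot,
±0.02-point rewards, and set-specific accuracies (defaults 0.79 easy, 0.70
difficult). Timing defaults are the single-target group means: planning
237 ms, inspection 486 ms, response 1052 ms.

Per-fixation dwells are truncated-normal (mean `t_insp`, SD `dwell_sd`,
support (0, 500 ms]) — the truncation enforces the per-element viewing
budget. The default `dwell_sd` is small (4 ms) so that the mean simulated
dwell equals the nominal inspection time despite the budget sitting only
14 ms above it; realistic within-trial dwell variability is unknown (only
between-participant means are constrained) and can be configured, at the
cost of a truncation-induced downward shift of the mean. Trial duration is
planning + distractor dwells + response; single-target fixation sequences
are a uniform random inspection order within the shown set.

Raw gaze streams are rendered at 1 kHz: stationary (optionally jittered)
samples inside each fixated element's AOI, 30-ms linear saccade segments
between them (an invented but documented constant), the terminal target
held until the response, and optional injected blinks and sub-5-ms
spurious shifts for exercising the filters. Ground-truth events and
metrics accompany every stream, and the gaze pipeline applied to a
noiseless stream reproduces them to ≤ 1 ms.

What the generator does *not* emulate: spatial biases (the generative
model is position-blind, so proximity effects present in real data are
absent), oculomotor kinematics, perceptual mechanics beyond the accuracy
parameters, and realistic dwell-time distributions. Passing tests
therefore validate the algebra and the pipeline, not fidelity to any
particular human dataset.

## Gaze analysis conventions

- AOI membership is strict at the 2.5° radius (a boundary point is
  background).
- Dwell = entering-shift offset → leaving-saccade offset, or →
  leaving-blink onset; a blink fully inside a visit (same AOI before and
  after) does not end the visit and its duration is subtracted.
- The corrective-shift filter applies to saccades only; a blink that stays
  within one AOI is part of the visit by the subtraction rule, so treating
  it as "corrective" would contradict that rule.
- Screen bounds for the off-screen filter default to ±23.15° × ±13.54°
  (90.70 × 51.00 cm at 106 cm viewing distance).
- The viewing-budget tracker accumulates visit dwells per element and
  flags the element masked at the moment the cumulative dwell reaches
  500 ms (unused budget carries over between visits).
- Inspection time excludes target visits in single-target mode and the
  terminal (response-exited) target visit in double-target mode; response
  time is undefined when the last shift landed on a distractor.
- The trial-start check excludes trials whose gaze deviates > 2° from the
  cross anywhere in [−20, 80] ms around stimulus onset; an uncovered
  window yields an undetermined (None) flag rather than a guess.

## Behavioral statistics

Scalar summaries follow the condition-then-participant averaging rule:
compute the variable per set-size condition first, then average the
resulting vector unweighted. The search-time regression fits condition
means of stimulus-onset-to-response time against distractor count (under
serial search its slope is t_insp/2 ≈ 243 ms per distractor for the default
profile). The choice regression is normalized: 0.5 is subtracted from the
easy-choice proportions and 4 from the easy-distractor count, so the
intercept is the imbalance at the 4-vs-4 condition. Gaze-shift proportion
metrics (chosen set, easy set, smaller set, closest element) are computed
for the first two shifts of each trial with equal-set conditions excluded
from the smaller-set metric; their analytic chance levels are 0.50, 0.50,
0.25 and 0.10. The closest-element reference is the fixation cross for the
first shift and the previously fixated element for the second.

## Problem sizes and numerical choices

The test and validation suites use: 10⁵ Monte-Carlo draws per setting for
the enumeration oracle (3 binomial SEs), 50 seeded sessions for the
search-time-slope ensemble, 200 trials per condition × 20 replicates for
parameter recovery, and ensembles of 100–500 displays for the geometry
invariants. Display placement uses uniform rejection sampling with a
10,000-proposal cap per display and whole-display restarts until both
screen-half balances hold (exact 5/5 for 10 elements; within one element
per axis for odd single-target counts); an infeasible-geometry error is
raised after 1,000 restarts. Whether the original task balanced both axes
simultaneously is unknown; simultaneous balancing is the stricter, and
adopted, reading.

## Known limitations

- The fixation pseudo-likelihood understates the information content of
  correlated within-trial fixations; standard errors for σ_f are
  approximate.
- With one session of data, σ_d is weakly identified (choices provide one
  Bernoulli draw per trial while fixations provide several), so its
  standard error is large at small n.
- Group-level (hierarchical) fitting across participants and model
  comparison beyond the reported NLL are out of scope.
- The velocity-threshold event detector is a fixture-grade tool; real
  recordings should supply tracker-detected saccade/blink events.
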