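# Methods

`pescale` models error-driven learning of reward expectations when rewards
are drawn from distributions with different spreads, and asks how scaling
of prediction errors to that spread ("adaptation") shapes learning
performance. Because no trial-level human dataset accompanies the task,
every analysis runs end-to-end on synthetic participants whose generating
parameters are known; the package is therefore simultaneously a model
library, a task simulator, and a recovery test-bench.

## Models

All models predict the stated reward expectation `P_t` (points, 0–100
scale) on each trial of a condition and update it from the reward
prediction error `delta_t = r_t − P_t`:

* **Rescorla–Wagner (RW).** `P_{t+1} = P_t + alpha * delta_t` with a
  constant learning rate `alpha ∈ [0, 1]`.
* **Pearce–Hall (PH).** The learning rate is dynamic:
  `alpha_{t+1} = eta * |delta_t| / 100 + (1 − eta) * alpha_t`. The decay
  weight `eta ∈ [0, 1]` mixes the previous rate with the unsigned error
  normalised to the 100-point scale; `eta = 0` is exactly RW. The `|.|/100`
  term is clamped at 1 defensively; on the 0–100 scale it never binds.
* **Variance-adaptive PH.** The prediction error is divided by
  `omega_t = (1 − nu) + nu * f(sigma_t)` before both the prediction and
  learning-rate updates, where `sigma_t` is the sample SD of rewards
  received on trials 1..t (inclusive of trial t) and `f` is the identity
  (linear variant) or the natural logarithm (log variant). `nu = 0`
  reduces to PH; `nu = 0, eta = 0` to RW; `nu = 1` fixed gives the
  fixed-scaling variants. On trials 1–2, before a sample SD exists,
  `sigma` is the learner's initial expected reward SD (`sigma_init`, one
  free parameter per SD level when fitted).

Numerical choices: the log uses `ln(max(sigma, 1))` so its term is never
negative, and `omega` is floored at 1e-3; both guards only matter in
degenerate regions (tiny early-trial SDs, `nu > 1`). The running SD uses
the n−1 denominator. Predictions are not clipped inside the model — the
dynamics stay linear; clipping and rounding to the 0–100 integer scale
happen only in the response-generation layer. The base of the logarithm is
configurable through the scaling variant; natural log is the default
because it keeps `omega` between 1 and the SD over the task's range, i.e.
scaling "relative to, but smaller than" the SD.

## Task generator

The main task crosses reward SD {5, 10, 15} with EV {35, 65}. Each
condition is a fixed multiset of 42 integer rewards found by a seeded
discrete search over symmetric offset pairs `EV ± d`: the symmetry makes
the mean exact and the skewness identically zero, while the search tunes
the sample SD (tolerance ±0.25 points) and kurtosis (targets 2.6 / 2.6 /
2.57, tolerance ±0.05). Values are confined to `EV ± 2.5 SD`, clamped to
[0, 100] ("no tails"); the exact printed ranges are not machine-readable,
so the 2.5-SD rule stands in for them. The multisets are fixed properties
of the task — every participant receives the same rewards; only their
order varies. Orders are re-drawn until no two consecutive rewards are
outliers, where an outlier deviates from the EV by more than 1.5 SD (the
source design states the constraint but not the cutoff; 1.5 SD excludes
only the distribution extremes while leaving many valid orders).

Sessions interleave two conditions that differ in both SD and EV in 12
alternating blocks of 5–8 trials (6 blocks and 42 trials per condition),
with block-length 6-tuples drawn uniformly from all compositions of 42
into parts of 5–8. Three sessions cover all six distributions once, under
one of the two printed pairing schemes; a practice design uses SD {7, 14}
× EV {30, 60} over two sessions (168 trials). Fitting and metrics treat
each condition's 42 trials as contiguous.

## Fitting and model comparison

Models are fitted per participant by minimising the summed squared
difference between stated and modelled predictions, with `P_1` initialised
to the participant's first prediction per condition. The default objective
mask is condition-local trials 2–42 (trial 1's residual is identically
zero under that initialisation and would only inflate the observation
count); the first-10-trials-excluded and empirical-initial-SD (trials
3–42, `sigma_{1,2}` = SD of the first two rewards) variants are supported.
Optimisation is L-BFGS-B within box bounds (`alpha1, eta, nu ∈ [0, 1]`,
`nu` optionally unconstrained; `sigma_init ∈ [0.5, 50]`) from 10
Latin-hypercube starts — the objective is multimodal in `(eta, nu)`.

Least-squares fits are scored with the Gaussian concentrated likelihood:
`AIC = n ln(SSE/n) + 2k`, `BIC = n ln(SSE/n) + k ln n`,
`loglik = −n/2 (ln(2π SSE/n) + 1)`, with `k` the count of free model
parameters (the error variance is not counted; configurable). Nested pairs
are compared with likelihood-ratio statistics `LR = n ln(SSE_r / SSE_f)`,
summed over participants along with their degrees of freedom, against the
chi-squared upper tail; a full model fitting worse than its restriction
(an optimiser artifact) clamps LR at 0 with a warning. The comparison
table also runs the per-SD-specific-`alpha1` PH model against the adaptive
models, mirroring the source comparison layout, although that pair is
related by restriction only informally.

## Normative simulations

Simulated sessions mirror the task at EV 0: 42 integer-rounded Gaussian
rewards, the first prediction at distance `|N(15, 2)|` from the EV
(participants start near mid-scale, ~15 points from either EV), and
performance error measured as mean `|P_t − EV|` over trials 2–42. Grids
sweep `alpha` 0–1 in steps of 0.01 and `eta` 0–1 in steps of 0.1 for SD
1–20, averaging 50 replicate reward sequences per cell; reward draws and
start points are shared across the parameter axes of each SD so cell
differences are parameter effects only, and likewise across `nu` values in
sweeps and session-curve comparisons. The adaptive learner in these
simulations receives the true running SD (`sigma_init` equals the
generating SD): they characterise the normative value of scaling, not SD
estimation.

## Synthetic cohorts

A cohort member is a task design (counterbalanced pairing schemes and
session orders), a parameter draw, and a response layer. Defaults:
`nu ~ truncated Normal(0.5133, 0.3495)` on [0, 1] — the distribution the
fitted human cohort was reported with; `eta ~ Beta(2, 6)` (mean 0.25,
mild decays); `alpha1 ~ Beta(3, 3)` (mean 0.5, broad); `sigma_init` truth
equals each condition's generating SD; first predictions `~ N(50, 5)`
(mid-scale starts); additive Gaussian response noise of SD 3 points on
stated predictions, then rounding and clipping to the 0–100 integer scale.
Rounding and noise can be disabled, making generated predictions exactly
equal to the model trace — the basis of the noise-free recovery checks. An
optional count of "exaggerated scalers" draws `nu` uniformly from (1, 2],
matching the reported 7-of-31 members who scaled beyond the log SD when
the bound was lifted. Control trials (20%) are flagged and paid by
prediction accuracy (7.50 within 1 SD of the EV, 5.00 within 2 SD, 2.50
otherwise, in pounds); main trials pay 10% of the drawn reward. Control
trials are generated identically to main trials since they were
unannounced at prediction time.

What the generator does *not* emulate: motor/reaction-time structure,
omitted trials, practice-to-main transfer, within-session drift in
strategy, and — importantly — any coupling between a member's adaptation
and their other learning parameters: `nu`, `eta`, `alpha1` are drawn
independently. Passing tests therefore show the pipeline recovers what the
generator put in; they cannot show that human adaptation behaves this way.

## Metrics and regressions

Learning efficiency per condition: overall performance error (mean
`|prediction − EV|`, trial 1 included by default, maskable), final
performance error and final prediction instability (mean error and sample
SD over trials 36–42). Per participant: performance dissimilarity — the
sample SD of overall error across the three SD levels after averaging the
two EV conditions within each level. The quadratic regressions follow the
reported analysis: outcome and linear predictors `(nu, eta, alpha1)`
z-scored (sample SD), quadratic terms formed as squares of the z-scores
and left unstandardized. That ordering is identifiable from the reported
tables themselves: it implies the fitted intercept equals
`−(b4 + b5 + b6)(n − 1)/n`, an identity those tables satisfy to the
printed precision, and it keeps each quadratic term nearly orthogonal to
its linear term so the quadratic coefficient isolates curvature.

## Known limitations

* The quadratic `nu^2` link between adaptation and *overall* performance
  error is weak in synthetic cohorts at n = 31: with `alpha1` and `eta`
  drawn independently of `nu`, the U's left arm is shallow (non-adapters
  still know `sigma` perfectly and learn otherwise normally, and response
  noise adds a ~2.4-point error floor) while high-`alpha1` members blunt
  the right arm, so curvature largely cancels across the cohort and the
  `nu × alpha1` interaction — absent from the quadratic design — inflates
  residuals. Matched-cohort comparisons (same seeds, different `nu`) do
  show the qualitative effect robustly. The strong human curvature implies
  coupling between adaptation and the other parameters that independent
  draws do not produce.
* With `nu` near or above 1 and small running SDs the `omega` floor can
  amplify rather than shrink errors; this is a property of the model
  family in that regime, kept deliberately, and it is why exaggerated
  scaling is costly in the sweeps.
* Reported human-cohort statistics (comparison-table chi-squared values,
  regression coefficients) depend on the undeposited human data and are
  out of reach by construction; the package reproduces the design-level
  quantities and the qualitative structure instead.

## Problem sizes

Default problem sizes follow the study design: 42 trials per condition,
6 conditions, 31-member cohorts, 50 replicate distributions per grid cell,
200 sessions for the learning-curve comparison. Recovery checks use a
10-member noise-free cohort and 6 members per generator in the confusion
matrix, which is ample for exact-recovery and rank-ordering checks.
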