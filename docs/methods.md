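# Methods

## The generative models

All four simulators describe a one-dimensional task: on trial *t* a
learner intends a movement (aim point, AP), executes an endpoint

- always-explore models (Therrien18, Dhawale19):
  `EP(t) = AP(t) + η(t) + m(t)`
- explore-after-failure models (Therrien16, Cashaback19):
  `EP(t) = AP(t) + (1 − R(t−1)) η(t) + m(t)`

and receives a binary reward R(t) from the task's criterion. Motor
noise m ~ N(0, σ²_m) is never available to the learner; exploration
η ~ N(0, σ²_η(t)) is (in most models) known in size and sign and drives
the aim-point update:

- Therrien16/18: `AP(t) = AP(t−1) + R(t−1) η(t−1)` (full update on
  success; the learning fraction is effectively 1, with α = 0 read as
  "no updating at all" for sweep purposes),
- Cashaback19: `AP(t) = AP(t−1) + α R(t−1) (EP(t−1) − AP(t−1))`
  (partial knowledge of the executed reach),
- Dhawale19: `AP(t) = AP(t−1) + α RPE(t−1) η(t−1)` with reward
  prediction error `RPE(t) = R(t) − R̄(t)` — an update after success and
  a correction after failure, since the RPE changes sign.

Reward history is tracked by an exponentially weighted moving average
`R̄(t) = R̄(t−1) + β (R(t−1) − R̄(t−1))` with `β = 1 − e^(−1/τ)`;
τ = 5 trials (β ≈ 0.18) by default. Exploration variance is regulated
by reward (history):

- Therrien16/Cashaback19: σ²_η = σ²_η\* after failure, 0 after success
  (the endpoint gate);
- Therrien18: σ²_η\* after failure, 0.12 σ²_η\* after success;
- Dhawale19: the continuous variability control function
  `σ²_η(t) = 2.18 σ²_η* (R̄(t)^0.7 − 1)²` — poor recent success means
  more exploration; a perfect reward history shuts it off.

The constants 2.18, 0.7 and 0.12 and the reference reward-history
values 0.20 (post-failure) and 0.68 (post-success) are treated as given
calibration constants of the variability control function; the package
does not refit them. Note that 0.12 is exactly the control function
evaluated at R̄ = 0.68 with unit input variance, which ties the
Therrien18 binary rule to the Dhawale19 continuous one.

All state (aim point, endpoint, reward, reward history, RPE, noise) is
initialized to zero before trial 1; in particular R̄(1) = 0, so the
Dhawale19 learner starts at its maximal exploration 2.18 σ²_η\*.
Trial indexing is 1-based throughout.

### Task parameters

- `target_sigma_units` (default 4): target amplitude as a multiple of
  σ_m, resolved to movement units per learner. The
  `fixed_low_target` criterion overrides the multiplier with 2.
- Reward criteria: `fixed` rewards endpoints inside
  [target − 1, target + 1] (half-width configurable, bounds inclusive,
  in raw movement units by a literal reading of the zone definition);
  `adaptive_mean` / `adaptive_median` additionally reward endpoints at
  least as close to the target as the mean/median of the last
  `history_window` endpoints (default 10 per the operational grid
  definition; the alternative reading of 5 changes every headline
  quantity by less than 0.02 SR, so the choice is immaterial);
  `random` rewards each trial with probability `random_p` = 0.5
  independent of performance. On trials with no history the adaptive
  criteria fall back to the fixed-zone rule; the adaptive comparison is
  one-sided as printed in the grid definition (it assumes approach from
  the baseline side).

### Common random numbers

`draw_noise_vectors(n_trials, n_sims, seed)` yields two standard-normal
vectors per simulation index, deterministic in (seed, index) and
independent of the consuming model; each model scales them by its own
σ_η(t) and σ_m. Between-model comparisons within a simulation set are
therefore paired. The random criterion uses a separate substream so
that reward randomness never perturbs the shared draws.

## The estimators

Both estimators measure variability as the **median of squared
trial-to-trial changes** — robust to the mean shift that learning
produces — and infer exploration as the excess variability following
non-successful trials.

**TTC** (lag-1): changes `Δ(t) = EP(t) − EP(t−1)` are split by R(t−1);
`σ̂²_η = (π/4) a (Δ̃²₋ − Δ̃²₊)`. The π/4 factor converts a
two-draw-based change statistic to a variance; `a` corrects for
exploration that survives success: a = 1 (Therrien16, Cashaback19),
a = 1.14 = 1/(1 − 0.12) (Therrien18), and for Dhawale19
`a = 1 / (mean₋ R̄^1.4 − mean₊ R̄^1.4 − 2 mean₋ R̄^0.7 + 2 mean₊ R̄^0.7)`
computed from the realized reward history (the logged one for
simulations; an EWMA of the observed reward column, with configurable
τ, for real data). The Dhawale19 correction is implemented exactly as
printed; it omits the 2.18 scale of the control function, which is one
reason Dhawale19 similarity ratios are erratic.

**ATTC** (lag-2): changes `Δ(t) = EP(t) − EP(t−2)` are classified by
the reward triple (R(t−3), R(t−2), R(t−1)) into sets A = (0,0,·),
B = (1,0,·), C = (0,1,·), D = (1,1,·), signed by R(t−1). Only C and D
enter the estimate: in those sets the post-failure minus post-success
difference of median squared changes isolates exactly one exploration
draw, so the single-draw factor 2.19 ≈ 1/median(χ²₁) converts it to a
variance (no π/4 needed). The two set estimates are combined by weights
`w_Nη` (3 for C, 1 for D — the number of exploration draws per change)
times `w_Ntrials` (the smaller of the pair's sequence counts), then
scaled by the same correction factor a. The digit convention was fixed
by symbolic verification: with σ_m = 0 the realized change in every
class equals the closed-form expression in the exploration draws (the
C+ class realizes with opposite sign, which squaring removes).

Numerical and degenerate-input choices:

- The literal constant 2.19 is used in the estimate; the derivation
  1/χ²₁-median ≈ 2.198 is exposed separately
  (`single_draw_factor_derived`).
- Negative estimates are genuine outcomes of subtracting medians and
  are never clipped.
- An empty reward category (TTC) or no computable class pair (ATTC)
  yields an undefined estimate (NaN) carrying diagnostic counts; if
  exactly one of C/D is computable the estimate is based on it alone
  and flagged. Fewer than 5 changes in a used class raises a
  low-reliability warning (configurable).
- Change classification starts at the first fully observed context
  (t ≥ 2 for TTC, t ≥ 4 for ATTC); the zero-initialized pre-experiment
  "reward" is never used as classification context, to avoid seeding
  the post-failure categories with an artificial failure.
- Summary statistics over simulation sets use the population SD
  (ddof 0), and undefined estimates are excluded from means with the
  excluded fraction reported explicitly.

## Learning metric and diagnostics

Learning is scored as the area under the endpoint curve smoothed by a
**trailing** 20-trial running average (shrinking partial windows at the
start), divided by the area under the target, × 100%. Centered versus
trailing alignment shifts the score by < 2% at 500 trials; the choice
is configurable. Overshooting series may exceed 100% and are not
clipped; the metric is undefined for a zero target.

`noise_exploration_correlation` computes the sample correlation between
the realized exploration and motor-noise draws separately on rewarded
and non-rewarded trials. Under performance-dependent criteria it is
negative on rewarded trials (success requires the two draws to offset),
which violates the variance-additivity assumption both estimators rest
on; under the random criterion it vanishes as trial counts grow.

## What the synthetic data does and does not emulate

The simulators are the study's data source, not a fixture: validation
is parameter recovery on data whose ground truth is known. They emulate
the trial structure of one-dimensional reinforcement tasks (binary
feedback, no error vector) with stationary Gaussian noise sources. They
do **not** emulate systematic (non-random) exploration strategies,
correlated noise sources, multi-dimensional endpoints, lapses, or
learning mechanisms outside the four update rules — so passing recovery
tests shows the estimators work *if* behavior follows one of these
generative families, not that human data does.

## Problem sizes and tolerances

The full study scale is 1000 simulations × 500 trials per set; the
acceptance script and the simulation-based acceptance tests use that
scale (a set simulates in ~2 s here). Unit and property tests use
reduced sets (tens to hundreds of simulations) with tolerances derived
from the sampling spread at that scale. Analytic constants are checked
at the printed precision (two decimals).

## Known limitations

- Under performance-dependent criteria combined with full-exploration
  updating (Therrien16/18 at defaults), the ATTC mean similarity ratio
  sits ~15–20% above 1 (see example 03): conditioning on the C/D reward
  sequences leaves the reference trial's motor-noise draw differently
  distributed in the subtracted classes, so the shared motor-noise term
  does not cancel exactly. This residual selection sensitivity is a
  property of the estimator, not a numerical artifact — it vanishes
  under the random criterion (mean SR ≈ 1.0).
- The TTC drop at zero learning fraction is deeper under an adaptive
  criterion (≈60% below the nonzero-α level; see example 05 and the
  acceptance script) than the ≈50% seen under the random criterion,
  because both pitfalls act simultaneously there.
- Dhawale19's reward-history-regulated exploration cannot be summarized
  by a single variance; both estimators recover it erratically (large
  spread, occasional negative estimates). Estimating the full
  variability control function is out of scope.
- Estimators assume a scalar endpoint; no 2-D/angular geometry.
- No fitting of model parameters to experimental data is provided.
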