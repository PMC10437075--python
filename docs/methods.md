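# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind the package, and what the simulator does and does
not attempt to emulate.

## Stimulus model

The generative process is a first-order Markov chain over four symbols. The
default topology is a double cycle in which every context has exactly one
frequent and one infrequent successor (probabilities `p_high` and
`1 − p_high`) and two impossible successors. Two properties motivate this
choice:

- the transition matrix is **doubly stochastic**, so the stationary
  distribution is uniform and each context contributes equally to every
  weighted metric (context weights default to the stationary distribution,
  computed by a least-squares solve of the stationarity equations with an
  explicit reachability check);
- every symbol serves as both a frequent and an infrequent target, so
  simple symbol-frequency counting cannot mimic learning of the
  conditionals.

Trials are sequences of 9–13 symbols (length uniform on the range) ending in
a prediction prompt. The scored "truth" for a trial is a **hidden target**
sampled from the same conditional row as the visible stream, so even a
perfect learner is right only `0.68` of the time when matching and `p_high`
when maximizing. Random test blocks use i.i.d. uniform symbols. Inter-
stimulus intervals are fixed at 400 ms or jittered uniformly on a 20 ms grid
over 100–700 ms (mean 400 ms) so the fixed and jittered designs are matched
on average pacing.

## Response model

Agents respond with a probability vector over the four symbols and a sampled
key press. Policies:

- `matching` reproduces the conditional row; `maximizing` is a point mass on
  the frequent target; `interpolated` mixes them with weight `lambda_mix`
  (0 = matching, 1 = maximizing), so a planted cohort spans the strategy
  continuum with known ground truth;
- `learning` maintains Dirichlet-style transition counts updated by
  exposure (every adjacent pair in every stream) and, during training, by a
  feedback bonus: `feedback_sensitivity × learn_rate` added to the
  (context, chosen) cell after correct trial-level feedback. Under
  uncorrelated feedback the bonus lands on a random cell, which degrades the
  belief — the mechanism by which noncontingent feedback hurts learning in
  the simulation.
- A lapse rate `p_null = 0.009` produces null responses, registered as the
  uniform vector 0.25 — a null carries no information about the
  conditional, and this convention keeps response tables normalized without
  discarding rows.

## Performance Index

`PI = Σ_c w_c Σ_t min(P_resp(t|c), P_pres(t|c))` is the weighted overlap
(intersection) of the response and presentation conditionals: 1 for
identical distributions, 0.45 for a uniform responder under 80/20
contingencies, 0.50 under 60/40 (closed form:
`Σ_c w_c [0.25 + min(0.25, 1 − p_high)]` when `p_high ≥ 0.25`). Normalized
PI subtracts the random baseline, and a post-training normalized PI **of at
least 0.10 (inclusive)** classifies a learner. Contexts never observed in a
window are excluded by renormalizing the weights over supported contexts;
computing a PI over an unsupported weighted context raises instead of
guessing.

## Strategy index

Per training block the response conditional `R` is compared with the two
pure strategies via `ΔKL = KL(M_match ‖ R) − KL(M_max ‖ R)` (natural log,
reference model as the first argument, so terms with zero reference
probability vanish exactly). `R` is smoothed as `(R + ε)/(1 + 4ε)` with
`ε = 1e-3` so empirical zeros are penalized finitely; the pure reference
models are not smoothed. An exact matcher has `ΔKL = ln(p_high) ≈ −0.223`
at `p_high = 0.8`; a uniform responder sits near `−0.500`; maximizers are
positive. The index sums block deltas above a matching reference
(rectangle rule over blocks; a trapezoid option exists).

**Finite-sample reference.** At 60 trials per block the plug-in KL is biased
upward: infrequent targets often draw zero counts and hit the smoothing
floor. The analysis pipeline therefore uses the *exact expected ΔKL of a
matching responder at the realized block size*, computed by nested binomial
sums (context occupancy ~ Binomial(n, w_c) conditioned on ≥ 1 visit;
frequent-target count ~ Binomial(m, p_high)). At n = 60 this reference is
−0.1627 rather than the asymptotic −0.2231; using it centres exact-matching
agents at an index of zero without any tuned constant. Rankings across the
`lambda` grid are unchanged for ε anywhere in [1e-4, 1e-2].

## Protocol and group designs

Each simulated participant completes a pre-test (structured / random /
structured, 40 trials each, no feedback), 23 structured training blocks of
60 trials under the group's feedback regime, and an identical post-test
(optionally a retest). Groups: (1) `p_high = 0.8`, fixed ISI, block
feedback — the reference design; (2) 0.6 contingencies; (3) jittered ISI;
(4) trial-by-trial feedback; (5) no feedback; (6) feedback uncorrelated
with performance. Trial feedback scores the key press against the hidden
target (nulls count as incorrect); block and no-feedback modes emit no
trial-level signal. Trial logs are flat CSVs, one row per trial, with the
full response probability vector, validated on read and write (exact column
order, probability sums within 1e-9) and written with 12 significant digits
so round trips are lossless.

## Staircase

The working-memory covariate is a two-down one-up staircase over set size
(integer number of dots, floor 2): two consecutive corrects make the display
one dot harder, one error makes it easier. The rule's equilibrium accuracy
is √0.5 ≈ 70.7% for any monotone psychometric function crossing that level —
confirmed here by an exact birth–death stationary computation
(`stationary_accuracy`), with up-rate p², down-rate 1 − p² and mean dwell
1 + p trials per decision. The simulated observer is logistic in set size
with a 0.5 guess floor (midpoint 6 dots, width 1.5 — a mid-range adult
profile; the convergence accuracy is insensitive to these within wide
ranges). A run ends after 10 reversals; a run's threshold is the mean of
the last ⌈2k/3⌉ reversal levels and a session averages three runs. Within a
session, runs 2 and 3 **continue from the previous run's final level**
(standard adaptive-testing practice); restarting every run at two dots
spends a third of each run climbing and inflates session accuracy by about
3 percentage points above the 70.7% equilibrium.

## Cohort statistics and parameter recovery

Correlations are Pearson with Fisher-z 95% intervals (degenerate interval
(−1, 1) at n = 3, where the Fisher standard error is undefined).
Incremental R² compares least-squares fits of a base design (intercept plus
group indicators) with and without the strategy index; a collinear addition
yields exactly 0, and only a rank-deficient *base* is an error.

The recovery experiment plants `interpolated` agents on a `lambda` grid and
checks that the estimated strategy index orders them correctly. Two modes:

- **pure grid** (default): agents apply their policy to the true transition
  table. Because exact matching maximizes the min-overlap PI, post-test PI
  *decreases* in `lambda` and the cohort index–performance correlation is
  necessarily negative. The package reports this honestly rather than
  reshaping the estimator.
- **quality-linked** (`quality_linked=True`): the grid value is an ability
  that drives both the strategy (`lambda` = ability) and the fidelity of
  the agent's internal estimate of the table (a convex mix of the true rows
  with Dirichlet noise, noise weight `0.5 × (1 − fidelity)`). Under this
  explicitly assumed link — weak learners both hold noisier estimates and
  match more — the index–performance correlation is positive, the direction
  observed across human cohorts. This is an assumption of the synthetic
  cohort, not a consequence of the estimators.

## What the simulator does and does not emulate

Emulated: the stimulus statistics, session structure, feedback regimes,
response registration (including lapses), and the full metric/analysis
pipeline. Not emulated: reaction-time dynamics (only a coarse proxy),
fatigue or forgetting across training days (blocks are exchangeable),
individual psychometric diversity beyond the observer midpoint draw, and
human-cohort effect sizes — the synthetic cohort reproduces directions and
orderings, not published magnitudes (those depend on participant data the
package does not ship).

## Numerical conventions

- All randomness flows through `numpy.random.Generator`; seeds make every
  simulation bit-reproducible.
- KL uses natural logarithms; `0 · log 0 = 0` exactly.
- Stationary distributions come from a least-squares solve rather than
  eigendecomposition, with a reachability check naming unreachable states.
- Monte-Carlo tolerances in tests are set at ≥ 3 standard errors of the
  statistic at the simulated sample size; closed-form identities are tested
  to 1e-10 or tighter against from-definition oracles.
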