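# Methods

This note documents the modelling choices behind `cprlab`: the game
environment, the synthetic behavioral cohort that replaces human
participants, the statistical estimators, and the limits of what the
synthetic pipeline can show.

## Game environment

Two renewable resources are harvested by three players over 22
payoff-independent rounds (the ecosystem resets each round).  Efforts
are integers in 0..20 hours, so all optimisation is exact brute force
over the grid; both solvers use deterministic tie-breaking (most equal
red/blue split, then lowest total effort for the social optimum; lowest
effort for best responses).

**Yield form.** The yield curve is a truncated inverted parabola
`P·max(0, 1 − ((E−E*)/w)²)` with width equal to the optimum, which
forces zero yield at zero effort and gives a hard collapse region
(zero yield beyond one width) — the maximum-sustainable-yield intuition
that over- and under-utilisation both destroy harvest.  A Gaussian bump
`P·exp(−((E−E*)/w)²)` is selectable via `yield_form: gauss` behind the
same contract; its tails are strictly positive, so the collapse region
is a parabola-only feature.  The exact functional family of the
original platform is not published; the parabola is the package's
documented stand-in, calibrated as below.

**Coupling.** Interdependency multiplies a resource's *peak* by
`max(0, 1 − κ·d/E*)` where `d` is the other resource's same-round
absolute deviation from its optimum.  Scaling peaks only (never
locations) keeps both optima parameter-fixed at 11 and 14 joint hours
regardless of the coupling state, which is what makes the 11/7/7 social
optimum well-defined.  Same-round deviations are used — no lag — since
rounds are ecologically independent.  Default `κ = 0.5`.

**Calibration of scale.** Individual peak earnings are 25 coins
(the observed per-individual maximum in the reference arm statistics),
hence a 50-coin peak for the two-sharer pool.  Coins are continuous;
display rounding is one decimal.  Proportional sharing implies a lone
sharer can take the pool's entire yield (up to 50 coins); the
per-individual *mean* earnings measure used throughout the analysis is
bounded by 25.

## Synthetic cohort

The generator emulates group-level *outcome* behaviour, not individual
cognition.  The reference arm statistics combine a moderate mean hour
-deviation (≈3.5 h) with a large coin deficit in the worst arm, and
under a truncated-quadratic yield that combination is only reachable
when deviations are *concentrated*: many rounds must lose the shared
pool entirely (red+blue total ≥ one width from 14 h, costing all 50
coins for an hour-cost of only 14/3 per round), while other rounds sit
near the optimum.  A smooth "drift toward the target" rule spreads the
same hour-budget thinly and cannot lose enough coins.  The generator is
therefore a two-state process per group-round:

* **coordinated** — players target 11/7/7; each sharer independently
  defects to the selfish best response (10 h) with probability
  `defection_prob`;
* **coordination failure** — the sharers miss the pool optimum by
  `initial_bias` hours: *herded* (both high or both low, collapsing the
  pool) or, with probability `balance_prob`, *balanced* (offsetting
  deviations: total right, split lopsided — the kind of silent
  compensation that per-player information makes possible without a
  chat channel).  Yellow independently deviates by `yellow_bias`.

Integer-rounded Gaussian noise (`exploration_sd`) is added everywhere
and efforts are clipped to 0..20.  The failure probability starts at
`collapse_prob` and decays geometrically at `convergence_rate` per
round after `convergence_onset`, giving the treatment-specific learning
profiles: the communication-only arm improves from about round 3, the
communication-plus-information arm only from about round 7 and more
slowly, and the no-communication arms show no systematic improvement
within the game.

**Calibration.** `calibrate_presets` runs a nested bisection with
common random numbers: an inner knob (failure probability, in which the
hour metric is monotone) is solved against the hour target for each
trial value of an outer knob (failure magnitude, balance share, or
learning rate) that is solved against the coin target.  The packaged
presets are the output of this search against the reference arm-level
means and reproduce them within ±0.5 coins and ±0.3 hours (checked at
200 groups per arm in the test suite):

| arm | info | comm | groups | failure p | bias (h) | balance | onset | rate |
|-----|------|------|--------|-----------|----------|---------|-------|------|
| A   | no   | no   | 7      | 0.763     | 6.13     | 0.00    | —     | 0    |
| B   | yes  | no   | 12     | 0.662     | 7.00     | 0.23    | —     | 0    |
| C   | no   | yes  | 8      | 0.808     | 7.00     | 0.10    | 3     | 0.18 |
| D   | yes  | yes  | 19     | 0.813     | 6.17     | 0.20    | 7     | 0.12 |

Group counts are the reference per-arm observation counts divided by
22 rounds (7 + 12 + 8 + 19 = 46 groups, 138 players, 1012 group-round
rows).  Chat-topic counts are Poisson with per-round expectation equal
to the arm's configured mean-messages-per-game divided by 22, for each
of the 20 sub-categories; rates are taken from the reference
communication-arm message tables.  An optional `linkage` map modulates
a topic's rate by the round's standardized coin performance, injecting
a known topic–performance association for regression-recovery tests;
`simulate_topic_panel` additionally provides a direct random-intercept
panel generator with an exactly known per-message effect.

**Seed discipline.** One master seed; per-group child seeds are spawned
with `numpy.random.SeedSequence(master_seed).spawn(...)` in design
order, so any generated object is a pure function of (preset,
parameters, seed).

## Estimators

* **Pairwise treatment models**: pooled OLS of the group-round outcome
  on a treatment indicator plus linear round, with group-clustered
  heteroskedasticity-robust errors.  The indicator marks the *first*
  arm of the pair, so the coefficient is the first arm's performance
  relative to the second.  On a balanced panel the indicator is
  orthogonal to round and the coefficient equals the arm-mean
  difference exactly — the closed-form oracle used in the tests.
* **Multiplicity**: Bonferroni threshold `α/m` (0.05/6 for the six
  pairs) and Benjamini–Hochberg step-up at FDR 0.25, applied per
  outcome family; BH adjusted p-values are the monotone step-up
  quantities, verified against an exhaustive enumeration.
* **Topic models**: per sub-category, outcome on the per-round topic
  count, 21 round indicators (round 1 base) and total messages, with a
  group random intercept estimated by REML (statsmodels `MixedLM`).
  The optimiser falls back from L-BFGS to Powell when the random
  -intercept variance collapses; topics with constant counts, rank
  -deficient designs or non-finite fits are reported per topic as
  degenerate without aborting the batch.
* **Welch tests** on per-game topic totals, with Welch–Satterthwaite
  degrees of freedom; two identical degenerate samples give t = 0,
  p = 1, other zero-variance cases are errors.

Numerical conventions: two-sided p-values throughout; coin outcomes are
floats with conservation of the pool split enforced to 1e-9; rounds are
1-based; CSV output is comma-separated UTF-8 with period decimals.

## Problem sizes

The test suite and the acceptance script run everything at sizes chosen
to keep the full pipeline in the tens of seconds on a single core:
200-group arms for calibration-recovery and treatment-coefficient
checks (group-round SE ≈ 0.1 coins, comfortably inside the ±0.5
tolerance), 250 replicate null cohorts for the type-I check at the
0.05/6 threshold, and 25 replicates for random-effects recovery of an
injected per-message effect.

## Limitations

* The generator matches arm-level *means* of the two performance
  metrics (and qualitative time profiles); pooled standard deviations,
  between/within-group variance decomposition, and min/max extremes
  are emergent, not calibrated.
* Chat counts are counts only — no text, no within-game timing
  structure beyond a uniform rate, and no behavioral feedback from
  messages to play unless a linkage is configured.  Topic-model results
  on synthetic cohorts therefore validate the estimator, not any
  substantive claim about how conversation topics affect play.
* The two-state behavioral rule is a parsimonious outcome-level
  emulation; it is not a cognitive model, and passing recovery tests on
  it says nothing about how real groups learn.
* The yield/coupling functional forms are documented stand-ins for an
  unpublished ecological model; all downstream quantities are exact
  properties of *this* calibration.
* No multi-round stock dynamics (depletion/regrowth) and no analytic
  continuous-effort solvers: the per-round reset makes the integer grid
  exhaustive search complete.
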