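# Methods

## Task model

A game is a finite-horizon, fully observed MDP over four states in the
fixed index order (LOW_PENDING, HIGH_OBTAINED, WITHDRAWN, ACCEPTED_LOW);
all states except LOW_PENDING are absorbing. Trials are 1-based. On each
trial the player holds the low offer and chooses WAIT or ACCEPT. Under
WAIT the offer is withdrawn with probability r_t, replaced by the high
offer with probability q_t, and carried over otherwise; ACCEPT moves
deterministically to ACCEPTED_LOW. A game ending in LOW_PENDING (never
accepted, never resolved) pays 0.

The event schedules are generated from hazard rates:

- withdrawal: cumulative geometric hazard r_t = 1 − (1 − h)^t with
  per-trial hazard h = `base_withdrawal_hazard`, capped at 1 − q_t so the
  two events never exceed unit probability;
- high offer: geometric decay q_t = `base_offer_prob` · `offer_decay`^(t−1).

This is the minimal three-scalar parameterisation with the required
monotonicities (withdrawal increasingly likely, high offer decreasingly
likely) and a single subjective scaling knob: an agent's hazard belief is
the same construction with h replaced by η·h. The *world* always runs at
η = 1; only the agent's policy evaluation uses its subjective schedule.
This subjective/objective split is the mechanism for risk-seeking (η < 1:
withdrawal believed unlikely, over-waiting) and over-caution (η > 1).

Defaults (package conventions — the task's defining publications show the
schedules only schematically): horizon 8, low offer 35p, high offer 80p,
h = 0.12, q_1 = 0.15, decay 0.8. Utilities are in pence and normalised by
the high offer before exponentiation so the sensitivity c is dimensionless:
the goal prior is d ∝ exp(c·u/80) with u = (0, 80, 0, low). With these
defaults and c = 6 the three behavioural contrasts the model is known for
(latency shift with α, early acceptance with η, phenotype dissociation)
hold in 256-game cohorts for every seed we test. A smaller low offer or
sensitivity makes certain acceptance so unattractive relative to the
high-offer-weighted goal that acceptances become too rare to characterise;
the defaults sit comfortably inside the regime where accepting is a live
option, which is also the regime the task was designed to probe.

## Decision rule

From trial t the policy set is {ACCEPT_AT_k : k = t…T} ∪ {NEVER_ACCEPT}
(T − t + 2 policies, each a deterministic WAIT-then-ACCEPT sequence). Each
policy's value is the negative Kullback-Leibler divergence from its
predicted *terminal* state distribution to the goal prior,
Q(π) = −KL(p(s_T|π) ‖ d) ≤ 0. Goals are expressed over endings only, not
per-trial visits, matching the outcome framing of the task. One
consequence worth knowing: KL-to-goal control is not expected utility —
a risky mixture can sit closer (in KL) to a spread goal than a certain
mediocre outcome does, so even a "flat" goal (c = 0) discriminates
policies by outcome entropy. True indifference arises only when all
policies predict point-mass endings (the zero-hazard limit).

Policies are selected by a softmax posterior q(π) ∝ exp(γ̂·Q(π)) whose
inverse temperature γ̂ is itself inferred: precision carries a Gamma
belief with fixed prior rate b₀ = 1 and shape a = α·b₀, updated as
b = b₀ − E_q[Q]. Since Q ≤ 0, b ≥ b₀ and hence γ̂ = a/b ≤ α: the prior
precision α is an upper bound reached exactly when the goal is believed
fully attainable. The two updates are alternated from γ̂₀ = α, with
damping 0.5 on γ̂, to a fixed point (tolerance 1e-6 on both γ̂ and the
posterior, max 64 iterations; non-convergence is flagged and warned, the
best iterate returned). The fixed point is verified in the tests against
an independent scalar root solve of γ = αb₀/(b₀ − softmax(γQ)·Q) to 1e-8.

The probability of accepting at trial t is the posterior mass of
ACCEPT_AT_t; all other policies begin by waiting. Because the task is
fully observed and we re-infer precision from its prior at every trial,
the action probability depends only on (trial, state), not on the path —
the per-trial evaluations are cached and reused. Re-inference each trial
(rather than carrying the precision posterior forward) matches the
end-of-trial framing of the precision trajectories we emulate; carrying
it forward is a one-line change in `AgentView` if ever needed.

The end-of-trial expected precision recorded in a game is re-computed
from the post-event state: after an uneventful wait it is the next
trial's LOW_PENDING fixed point; after withdrawal/high offer/acceptance
it is the (closed-form) fixed point of the degenerate outcome. Its first
difference, with γ̂₀ = α as baseline, is the simulated dopamine trace:
negative at withdrawal with magnitude increasing in α, positive at
high-offer receipt, near zero during settled waiting. The first entry is
a settling transient (the trial-1 fixed point sits well below α whenever
the goal is not surely attainable) and is not an event response.

## Simulation

`simulate_game` alternates agent and world: evaluate the subjective model,
sample ACCEPT/WAIT from the acceptance probability, then sample the
world's event from the objective schedule. Games stop at absorption;
timed-out games are a distinct zero-payoff outcome. Cohorts use one master
`SeedSequence` with per-game spawned children, so any game is reproducible
independently of cohort size. Phenotype presets (package conventions, not
published values): control (α=16, η=1, c=6), addiction (α=4, η=0.4, c=6),
ocd_like (α=8, η=3, c=6).

The cohort CSV is a long-format table (one row per recorded trial) with
columns game_id, trial, horizon, low_offer, high_offer, state, p_accept,
action, event, gamma_hat, outcome, payoff. Writing and re-reading is
lossless (floats are parsed in round-trip mode); the hazard parameters are
not part of the schema and must be supplied when refitting data from a
non-default task.

## Inversion

Only LOW_PENDING rows are decision points; per-trial accept/wait counts
are sufficient statistics for the likelihood (the acceptance probability
is history-free), with probabilities floored at 1e-12 before the log.
MAP estimation works on (log α, log η, log c) with independent Gaussian
priors (location at the control preset, scale 1 — weakly informative) and
proceeds in two deterministic stages: a 5×5×5 log-spaced grid (α ∈ [2,32],
η ∈ [0.25,4], c ∈ [1.5,24]) followed by Nelder-Mead from the grid optimum.
Standard errors come from a finite-difference Hessian of the negative
log-posterior at the optimum, mapped to the natural scale by the delta
method; they are approximate and can be optimistic when η and c trade off
(the two parameters both flatten the early acceptance profile, and
occasional fits settle in that exchange direction).

`recovery_study` closes the loop: simulate cohorts at known parameters,
refit, and report per-parameter bias, RMSE and Spearman rank correlation.
At the study scale (256 games per cohort, 10 replicates) the three prior
precision levels 4/8/16 are separated with rank correlation above 0.9.
η is flagged as unidentifiable when the acceptance probabilities do not
respond to it across the search range (the task configuration rejects
exactly-zero hazards, so this arises only for near-degenerate schedules).

## What the generator does and does not emulate

The synthetic cohorts emulate the task's structure exactly as the agent
models it: hazard-governed events, a single low and high offer, full
observability, no learning within or across games. Real behaviour adds
reaction times, fatigue and session effects, hazard-rate learning, and
lapses unrelated to precision — none of which are modelled, so passing
tests certify internal consistency of the model and recoverability of its
parameters from data *generated by the model*, not fit quality on human
data.

## Numerical notes and limitations

- All probability rows are validated to sum to 1 within 1e-12; the stay
  probability is clamped at 0 where the withdrawal cap binds (guards
  against −1e-17 leakage into KL).
- Softmax uses max-subtraction; ties at infinite precision split uniformly.
- The likelihood is invariant to duplicating games (tested) and the MAP
  refinement can never end below the grid optimum (tested).
- Horizons are small (≤ 8 in all shipped configurations); policy
  enumeration is linear in horizon, so longer games are cheap, but the
  package deliberately has no epistemic (information-gain) term, no
  partial observability, and no hierarchical/group-level fitting.
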