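# limitedoffer

Active-inference modelling of the **limited-offer waiting task** — a
sequential decision game used in computational psychiatry to phenotype
impulsive, risk-seeking and over-cautious choice.

In each game a player holds a small standing offer (9–35 pence) for up to
*T* trials (4 or 8). On every trial they either **accept** it or **wait**
for a high offer (80 pence). Waiting is risky: the low offer may be
withdrawn (probability *r<sub>t</sub>*, rising with *t*) or replaced by the
high offer (probability *q<sub>t</sub>*, falling with *t*), both governed
by hazard rates. Waiting out the whole game pays nothing. The player must
infer the optimal time to accept.

## The model

The agent treats choice as inference in a finite-horizon Markov decision
problem with states {LOW_PENDING, HIGH_OBTAINED, WITHDRAWN, ACCEPTED_LOW}.
At trial *t* it enumerates the remaining policies π ∈ {accept at *k* for
*k* = *t*…*T*, never accept} and scores each by how surprising its
predicted ending would be under the goal prior:

  *Q*(π) = −KL( p(s_T | π) ‖ d ),  d ∝ exp(c·u/u_max),

where u = (0, 80, 0, low) pence are the outcome utilities and *c* ≥ 0 is
the subject's **sensitivity**. Policies are selected through a softmax
posterior q(π) ∝ exp(γ̂·Q(π)) whose inverse temperature γ̂ — the
**expected precision** — is not a fixed parameter but the mean of a Gamma
belief updated from the evidence itself:

  a = α·b₀,  b = b₀ − E_q[Q],  γ̂ = a/b,

iterated with the policy posterior to a variational fixed point. The prior
precision **α** ("trait confidence") caps γ̂ (γ̂ ≤ α, with equality only
when the goal is believed fully attainable). Trial-to-trial changes in γ̂
are the model's simulated dopamine responses: γ̂ collapses when the offer
is withdrawn (more steeply for higher α) and jumps when the high offer
arrives. The agent evaluates policies under its *own* hazard belief — the
withdrawal hazard scaled by **η** — while the world runs at η = 1, so
η < 1 produces risk-seeking over-waiting and η > 1 premature acceptance.

Given trial-by-trial choices, the three subject-level parameters (α, η, c)
are recovered by MAP estimation: choice log-likelihood under the engine
plus weakly informative Gaussian priors on the log-parameters, maximised
by grid search and Nelder-Mead refinement.

## Worked example

```python
from limitedoffer import (LimitedOfferModel, TaskConfig, acceptance_profile,
                          phenotype_preset, simulate_cohort)

data = simulate_cohort(phenotype_preset("control"), TaskConfig(),
                       n_games=256, seed=7)
prof = acceptance_profile(data)
print("outcomes:", data.outcome_counts())
print(f"mean acceptance latency: {prof.mean_latency:.2f} trials")
print(LimitedOfferModel(data).fit().summary())
```

prints

```
outcomes: {'accepted_low': 58, 'high_offer': 52, 'withdrawn': 146, 'timed_out': 0}
mean acceptance latency: 3.57 trials
            Limited-Offer Active-Inference Model (MAP)
================================================================
No. games:             256     No. decisions:       668
Log-likelihood:       -143.461 Log-posterior:      -146.243
Converged:            True     NM iterations:       118
----------------------------------------------------------------
                      estimate     std err
prior_precision        14.2715      3.0439
hazard_scale            1.1246      0.6140
sensitivity             5.1547      2.6666
================================================================
```

The control phenotype was simulated at α = 16, η = 1, c = 6: over 256
eight-trial games it accepted the low offer in 58 games (on average after
3.6 trials), won the high offer in 52 and lost the offer in 146; inverting
the model from those choices alone recovers α̂ ≈ 14.3 with η̂ ≈ 1.1 —
the generating parameters within one standard error.

The same machinery drives three bundled phenotypes: `control` (high α,
calibrated η), `addiction` (low α, optimistic η < 1: stochastic, impulsive
*and* risk-seeking), and `ocd_like` (moderate α, pessimistic η > 1: early,
habitual acceptance).

## Command line

```bash
limitedoffer simulate --config examples/run.yaml --out cohort.csv
limitedoffer fit cohort.csv --config examples/run.yaml --out fit.json
limitedoffer recover --config examples/run.yaml --out recovery.csv
```

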