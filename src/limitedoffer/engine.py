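"""Active-inference decision rule for the limited-offer game.

At each trial the agent enumerates the remaining policies (accept now,
accept at any later trial, or never accept), scores each by the negative
Kullback-Leibler divergence from its predicted terminal-state distribution
to the goal (desired-outcome) distribution, and forms a softmax posterior
over policies whose inverse temperature is the *expected precision* — the
mean of a Gamma belief that is itself updated from the posterior-weighted
policy values.  Policy posterior and precision belief are iterated to a
variational fixed point; the acceptance probability is the posterior mass
of the accept-now policy.

Precision is re-inferred from its prior at every trial (the belief over
hidden states is a point mass in this fully observed task, so nothing else
carries over), and the trajectory of fixed-point precisions is the model's
simulated dopamine signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr, softmax

from .task import (
    Action,
    DesiredOutcome,
    N_STATES,
    State,
    TaskConfig,
    build_desired_outcome,
    build_hazard_schedule,
    build_transitions,
)

__all__ = [
    "Policy",
    "BeliefState",
    "PrecisionBelief",
    "VariationalState",
    "policy_set",
    "predict_terminal",
    "policy_value",
    "policy_posterior",
    "precision_update",
    "variational_fixed_point",
    "action_probability",
    "AgentView",
]


@dataclass(frozen=True)
class Policy:
    """Deterministic action sequence: WAIT until ``accept_trial``, then ACCEPT.

    ``accept_trial = None`` encodes the never-accept policy (wait out the
    whole game).
    """

    accept_trial: int | None

    def action_at(self, trial: int) -> Action:
        if self.accept_trial is not None and trial >= self.accept_trial:
            return Action.ACCEPT
        return Action.WAIT

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.accept_trial is None:
            return "Policy(NEVER_ACCEPT)"
        return f"Policy(ACCEPT_AT_{self.accept_trial})"


def policy_set(trial: int, horizon: int) -> list[Policy]:
    """Policies available from ``trial``: accept at k for k = trial..T, or never."""
    if not 1 <= trial <= horizon:
        raise ValueError(f"trial must lie in 1..{horizon}, got {trial}")
    return [Policy(k) for k in range(trial, horizon + 1)] + [Policy(None)]


@dataclass(frozen=True)
class BeliefState:
    """Point-mass belief over game states at the start of ``trial``."""

    probs: np.ndarray
    trial: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (N_STATES,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("belief must be a length-4 probability vector")

    @classmethod
    def point_mass(cls, state: State, trial: int) -> "BeliefState":
        p = np.zeros(N_STATES)
        p[state] = 1.0
        return cls(probs=p, trial=trial)


@dataclass(frozen=True)
class PrecisionBelief:
    """Gamma belief over precision with mean ``expected_precision = shape/rate``."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("Gamma shape and rate must be positive")

    @property
    def expected_precision(self) -> float:
        return self.shape / self.rate


@dataclass(frozen=True)
class VariationalState:
    """Converged policy posterior and precision belief at one decision point."""

    policies: tuple[Policy, ...]
    posterior: np.ndarray
    precision: PrecisionBelief
    iterations: int
    converged: bool


def predict_terminal(
    belief: BeliefState, policy: Policy, transitions: np.ndarray
) -> np.ndarray:
    """Terminal-state distribution at the end of the game under ``policy``.

    Chains the policy's action-conditioned transition rows from the
    belief's trial through trial T.  Absorbing states are unaffected by
    either action, so the result from an absorbing state is a point mass.
    """
    T = transitions.shape[0]
    if policy.accept_trial is not None and policy.accept_trial < belief.trial:
        raise ValueError(
            f"policy {policy!r} starts before the current trial {belief.trial}"
        )
    p = belief.probs
    for t in range(belief.trial, T + 1):
        p = p @ transitions[t - 1, policy.action_at(t)]
    return p


def policy_value(terminal: np.ndarray, desired: DesiredOutcome) -> float:
    """Negative KL divergence -KL(terminal || desired), in nats.

    Zero iff the predicted terminal distribution equals the goal; always
    non-positive.  The goal distribution is strictly positive by
    construction (softmax), so the divergence is finite.
    """
    d = desired.probs
    if np.any(d <= 0):
        raise ValueError("desired outcome must be strictly positive")
    return -float(rel_entr(terminal, d).sum())


def policy_posterior(Q: np.ndarray, expected_precision: float) -> np.ndarray:
    """Softmax policy posterior with the expected precision as inverse temperature."""
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("policy values must be finite")
    if np.isinf(expected_precision):
        best = Q == Q.max()
        return best / best.sum()
    return softmax(expected_precision * Q)


def precision_update(
    Q: np.ndarray,
    posterior: np.ndarray,
    prior_precision: float,
    prior_rate: float = 1.0,
) -> PrecisionBelief:
    """Bayes-optimal Gamma update of the precision belief.

    Shape is fixed at ``alpha * b0``; the rate grows by the expected KL
    cost of the policy posterior, ``b = b0 - E_pi[Q]``.  Because Q <= 0 the
    rate never falls below its prior, so expected precision never exceeds
    the prior precision alpha — equality holds exactly when the goal is
    believed fully attainable (posterior-weighted Q of zero).
    """
    if not (prior_precision > 0 and prior_rate > 0):
        raise ValueError("prior_precision and prior_rate must be positive")
    expected_cost = float(np.dot(posterior, Q))
    return PrecisionBelief(
        shape=prior_precision * prior_rate,
        rate=prior_rate - expected_cost,
    )


def variational_fixed_point(
    Q: np.ndarray,
    policies: list[Policy] | tuple[Policy, ...] | None = None,
    prior_precision: float = 8.0,
    prior_rate: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 64,
    damping: float = 0.5,
) -> VariationalState:
    """Alternate policy-posterior and precision updates to self-consistency.

    Starts from the prior expectation ``gamma = alpha`` and iterates

        pi    <- softmax(gamma * Q)
        gamma <- (1 - damping) * gamma + damping * alpha*b0 / (b0 - pi.Q)

    until both the precision and the posterior change by less than ``tol``.
    Non-convergence within ``max_iter`` returns the best iterate with the
    ``converged`` flag unset and emits a warning.
    """
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    Q = np.asarray(Q, dtype=float)
    if policies is None:
        policies = [Policy(k) for k in range(1, len(Q) + 1)]
    gamma = prior_precision
    post = policy_posterior(Q, gamma)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        belief = precision_update(Q, post, prior_precision, prior_rate)
        gamma_new = (1.0 - damping) * gamma + damping * belief.expected_precision
        post_new = policy_posterior(Q, gamma_new)
        if (
            abs(gamma_new - gamma) < tol
            and np.max(np.abs(post_new - post)) < tol
        ):
            gamma, post = gamma_new, post_new
            converged = True
            break
        gamma, post = gamma_new, post_new
    if not converged:
        warnings.warn(
            f"variational fixed point did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    final = precision_update(Q, post, prior_precision, prior_rate)
    return VariationalState(
        policies=tuple(policies),
        posterior=post,
        precision=final,
        iterations=iterations,
        converged=converged,
    )


def action_probability(vs: VariationalState, current_trial: int) -> tuple[float, float]:
    """(P(ACCEPT), P(WAIT)) at ``current_trial`` from the policy posterior.

    Accepting now is exactly the posterior mass of the accept-at-current-
    trial policy; every other policy begins by waiting.
    """
    p_accept = 0.0
    for pol, w in zip(vs.policies, vs.posterior):
        if pol.accept_trial == current_trial:
            p_accept += float(w)
    return p_accept, 1.0 - p_accept


class AgentView:
    """An agent's subjective model of one game, ready for per-trial evaluation.

    Bundles the subjective (hazard-scaled) transition kernel, the goal
    distribution and the precision prior, and caches the per-trial
    fixed-point evaluations, which depend only on (trial, state) in this
    fully observed task.
    """

    def __init__(
        self,
        config: TaskConfig,
        prior_precision: float,
        hazard_scale: float = 1.0,
        sensitivity: float = 6.0,
        prior_rate: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 64,
        damping: float = 0.5,
    ):
        self.config = config
        self.prior_precision = float(prior_precision)
        self.prior_rate = float(prior_rate)
        self.schedule = build_hazard_schedule(config, hazard_scale)
        self.transitions = build_transitions(self.schedule)
        self.desired = build_desired_outcome(config, sensitivity)
        self._fp_opts = dict(tol=tol, max_iter=max_iter, damping=damping)
        self._cache: dict[tuple[int, State], VariationalState] = {}

    def policy_values(self, trial: int, state: State = State.LOW_PENDING) -> tuple[list[Policy], np.ndarray]:
        """Policies available from (trial, state) and their KL values."""
        policies = policy_set(trial, self.config.horizon)
        belief = BeliefState.point_mass(state, trial)
        Q = np.array(
            [
                policy_value(predict_terminal(belief, pol, self.transitions), self.desired)
                for pol in policies
            ]
        )
        return policies, Q

    def evaluate(self, trial: int, state: State = State.LOW_PENDING) -> VariationalState:
        """Converged variational state at one decision point (cached)."""
        key = (trial, State(state))
        if key not in self._cache:
            policies, Q = self.policy_values(trial, state)
            self._cache[key] = variational_fixed_point(
                Q,
                policies=policies,
                prior_precision=self.prior_precision,
                prior_rate=self.prior_rate,
                **self._fp_opts,
            )
        return self._cache[key]

    def accept_probability(self, trial: int) -> float:
        """P(ACCEPT) at ``trial`` from LOW_PENDING."""
        vs = self.evaluate(trial, State.LOW_PENDING)
        return action_probability(vs, trial)[0]

    def accept_probabilities(self) -> np.ndarray:
        """P(ACCEPT) for every trial 1..T from LOW_PENDING."""
        return np.array(
            [self.accept_probability(t) for t in range(1, self.config.horizon + 1)]
        )

    def expected_precision(self, trial: int, state: State = State.LOW_PENDING) -> float:
        return self.evaluate(trial, state).precision.expected_precision

    def terminal_precision(self, state: State) -> float:
        """End-of-game precision given a terminal state (degenerate outcome).

        All policies predict the same point-mass terminal distribution, so
        the fixed point has a closed form; evaluating at the final trial is
        exact for any absorbing state and for a timed-out LOW_PENDING.
        """
        if state is State.LOW_PENDING:
            # timed out: outcome is a certain LOW_PENDING ending
            Q0 = policy_value(
                BeliefState.point_mass(state, self.config.horizon).probs, self.desired
            )
            b = self.prior_rate - Q0
            return self.prior_precision * self.prior_rate / b
        return self.expected_precision(self.config.horizon, state)
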