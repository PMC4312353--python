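"""The limited-offer waiting game.

A game lasts ``horizon`` trials.  The player holds a small standing offer
(``low_offer`` pence) and on every trial chooses to ACCEPT it or WAIT.
Waiting risks the offer being withdrawn (probability ``r_t``) but may be
rewarded by a large replacement offer of ``high_offer`` pence (probability
``q_t``).  Both event probabilities are governed by hazard rates: withdrawal
becomes more likely, and the high offer less likely, the longer one waits.
A game that ends with the low offer still pending pays nothing.

This module defines the task's state space, hazard schedules,
action-conditioned transition kernel and the goal (desired-outcome)
distribution that a KL-control agent steers towards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import IntEnum
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "State",
    "Action",
    "N_STATES",
    "TaskConfig",
    "HazardSchedule",
    "DesiredOutcome",
    "build_hazard_schedule",
    "build_transitions",
    "build_desired_outcome",
    "DEFAULT_CONFIG",
]

_PROB_ATOL = 1e-12


class State(IntEnum):
    """Game states, in the fixed index order used throughout the package."""

    LOW_PENDING = 0
    HIGH_OBTAINED = 1
    WITHDRAWN = 2
    ACCEPTED_LOW = 3

    @property
    def absorbing(self) -> bool:
        return self is not State.LOW_PENDING


class Action(IntEnum):
    WAIT = 0
    ACCEPT = 1


N_STATES = 4


@dataclass(frozen=True)
class TaskConfig:
    """Objective parameters of one limited-offer game.

    Parameters
    ----------
    horizon
        Number of trials T (>= 2).  Trials are numbered 1..T.
    low_offer, high_offer
        Standing and replacement offer magnitudes in pence,
        0 < low_offer < high_offer.
    base_withdrawal_hazard
        Per-trial conditional withdrawal probability h in (0, 1); the
        cumulative withdrawal probability at trial t is 1 - (1-h)^t.
    base_offer_prob
        High-offer probability on trial 1, in (0, 1).
    offer_decay
        Multiplicative per-trial decay of the high-offer probability,
        in (0, 1].
    """

    horizon: int = 8
    low_offer: float = 35.0
    high_offer: float = 80.0
    base_withdrawal_hazard: float = 0.12
    base_offer_prob: float = 0.15
    offer_decay: float = 0.80

    def __post_init__(self) -> None:
        if int(self.horizon) != self.horizon or self.horizon < 2:
            raise ValueError(f"horizon must be an integer >= 2, got {self.horizon}")
        if not (0 < self.low_offer < self.high_offer):
            raise ValueError(
                "offers must satisfy 0 < low_offer < high_offer, got "
                f"low={self.low_offer}, high={self.high_offer}"
            )
        if not (0 < self.base_withdrawal_hazard < 1):
            raise ValueError("base_withdrawal_hazard must lie in (0, 1)")
        if not (0 < self.base_offer_prob < 1):
            raise ValueError("base_offer_prob must lie in (0, 1)")
        if not (0 < self.offer_decay <= 1):
            raise ValueError("offer_decay must lie in (0, 1]")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown TaskConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "TaskConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of TaskConfig fields")
        return cls.from_dict(data)


#: Default task: the long (8-trial) game with a mid-range initial offer.
DEFAULT_CONFIG = TaskConfig()


@dataclass(frozen=True)
class HazardSchedule:
    """Per-trial event probabilities r_1..r_T (withdrawal), q_1..q_T (high offer)."""

    withdrawal: np.ndarray
    high_offer: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.withdrawal, dtype=float)
        q = np.asarray(self.high_offer, dtype=float)
        object.__setattr__(self, "withdrawal", r)
        object.__setattr__(self, "high_offer", q)
        if r.shape != q.shape or r.ndim != 1:
            raise ValueError("withdrawal and high_offer must be 1-d and equal length")
        if np.any((r < 0) | (r > 1)) or np.any((q < 0) | (q > 1)):
            raise ValueError("hazard probabilities must lie in [0, 1]")
        if np.any(np.diff(r) < -_PROB_ATOL):
            raise ValueError("withdrawal probabilities must be non-decreasing")
        if np.any(np.diff(q) > _PROB_ATOL):
            raise ValueError("high-offer probabilities must be non-increasing")
        if np.any(r + q > 1 + _PROB_ATOL):
            raise ValueError("r_t + q_t must not exceed 1")

    @property
    def horizon(self) -> int:
        return len(self.withdrawal)


def build_hazard_schedule(config: TaskConfig, hazard_scale: float = 1.0) -> HazardSchedule:
    """Construct the per-trial event schedule from hazard rates.

    The withdrawal probability at trial t is the cumulative geometric hazard
    ``1 - (1 - h)^t`` with per-trial hazard ``h = hazard_scale *
    base_withdrawal_hazard`` (clipped into [0, 1]), capped at ``1 - q_t`` so
    the two events never exceed unit probability.  The high-offer
    probability decays geometrically, ``q_t = base_offer_prob *
    offer_decay**(t-1)``, and is not affected by ``hazard_scale``.

    ``hazard_scale = 1`` gives the objective (world) schedule; an agent's
    subjective schedule uses its own scale (its hazard-rate belief).
    """
    if not (np.isfinite(hazard_scale) and hazard_scale > 0):
        raise ValueError(f"hazard_scale must be a positive finite real, got {hazard_scale}")
    t = np.arange(1, config.horizon + 1)
    q = config.base_offer_prob * config.offer_decay ** (t - 1)
    h = float(np.clip(hazard_scale * config.base_withdrawal_hazard, 0.0, 1.0))
    r = np.minimum(1.0 - q, 1.0 - (1.0 - h) ** t)
    return HazardSchedule(withdrawal=r, high_offer=q)


def build_transitions(schedule: HazardSchedule) -> np.ndarray:
    """Action-conditioned transition kernel.

    Returns an array of shape ``(T, 2, 4, 4)`` indexed by (trial-1, action,
    current state, next state).  Rows are stochastic; absorbing states map
    to themselves under both actions.  From LOW_PENDING, WAIT moves to
    WITHDRAWN with probability r_t, to HIGH_OBTAINED with q_t and stays put
    otherwise; ACCEPT moves to ACCEPTED_LOW with certainty.
    """
    T = schedule.horizon
    P = np.zeros((T, 2, N_STATES, N_STATES))
    eye = np.eye(N_STATES)
    for i in range(T):
        r, q = schedule.withdrawal[i], schedule.high_offer[i]
        for a in Action:
            P[i, a] = eye.copy()
        # max() guards against -1e-17 stay probabilities when r is capped at 1-q
        P[i, Action.WAIT, State.LOW_PENDING] = (max(0.0, 1.0 - r - q), q, r, 0.0)
        P[i, Action.ACCEPT, State.LOW_PENDING] = (0.0, 0.0, 0.0, 1.0)
    return P


@dataclass(frozen=True)
class DesiredOutcome:
    """Goal prior over terminal states.

    Built as a softmax over normalised outcome utilities: with utilities
    ``u = (0, high_offer, 0, low_offer)`` pence for (LOW_PENDING,
    HIGH_OBTAINED, WITHDRAWN, ACCEPTED_LOW), the goal distribution is
    proportional to ``exp(c * u / high_offer)``.  The sensitivity ``c`` is
    dimensionless; ``c = 0`` gives an indifferent (uniform) goal and large
    ``c`` concentrates the goal on the high offer.
    """

    probs: np.ndarray
    sensitivity: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (N_STATES,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p <= 0):
            raise ValueError("desired outcome must be a strictly positive length-4 probability vector")


def build_desired_outcome(config: TaskConfig, sensitivity: float) -> DesiredOutcome:
    if not (np.isfinite(sensitivity) and sensitivity >= 0):
        raise ValueError(f"sensitivity must be a non-negative finite real, got {sensitivity}")
    u = np.array([0.0, config.high_offer, 0.0, config.low_offer])
    logits = sensitivity * u / config.high_offer
    p = np.exp(logits - logits.max())
    return DesiredOutcome(probs=p / p.sum(), sensitivity=float(sensitivity))
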