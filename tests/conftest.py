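"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own computation paths:
terminal-state distributions come from exhaustive recursion over event
sequences, KL values from the textbook formula, and the variational fixed
point from a scalar root bracket.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import brentq

from limitedoffer import TaskConfig

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def default_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture
def tiny_config() -> TaskConfig:
    """A 3-trial game small enough for exhaustive path enumeration."""
    return TaskConfig(
        horizon=3,
        low_offer=35,
        high_offer=80,
        base_withdrawal_hazard=0.15,
        base_offer_prob=0.2,
        offer_decay=0.8,
    )


# -- independent oracles ---------------------------------------------------


def enumerate_terminal(r, q, horizon, accept_trial, start_trial=1):
    """Terminal-state distribution by exhaustive recursion over event paths.

    States indexed (LOW_PENDING, HIGH_OBTAINED, WITHDRAWN, ACCEPTED_LOW).
    ``accept_trial=None`` means never accept.
    """
    probs = np.zeros(4)

    def walk(t, p):
        if t > horizon:
            probs[0] += p  # survived the whole game without accepting
            return
        if accept_trial is not None and t >= accept_trial:
            probs[3] += p
            return
        probs[2] += p * r[t - 1]
        probs[1] += p * q[t - 1]
        walk(t + 1, p * (1.0 - r[t - 1] - q[t - 1]))

    walk(start_trial, 1.0)
    return probs


def kl_oracle(p, d):
    """KL(p || d) by the textbook sum, with 0 log 0 = 0."""
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / d[mask])))


def fixed_point_oracle(Q, alpha, b0=1.0):
    """Scalar root of gamma = alpha*b0 / (b0 - softmax(gamma*Q) . Q)."""
    Q = np.asarray(Q, dtype=float)

    def F(g):
        z = g * Q
        w = np.exp(z - z.max())
        w /= w.sum()
        return alpha * b0 / (b0 - w @ Q) - g

    return brentq(F, 1e-12, alpha, xtol=1e-13)
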