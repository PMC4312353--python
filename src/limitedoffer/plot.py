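"""Simple diagnostic plots (requires matplotlib, installed separately).

Quick visual checks of a simulation or fit: how games ended per trial,
and the within-game precision trajectory whose jumps are the simulated
dopamine responses.
"""

from __future__ import annotations

import numpy as np

from .simulate import AcceptanceProfile, GameRecord


def plot_acceptance_profile(profile: AcceptanceProfile, ax=None):
    """Stacked per-trial bars of acceptances, high offers and withdrawals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    trials = np.arange(1, profile.horizon + 1)
    bottom = np.zeros(profile.horizon)
    for counts, label in (
        (profile.accepted, "accepted low"),
        (profile.high_offer, "high offer"),
        (profile.withdrawn, "withdrawn"),
    ):
        ax.bar(trials, counts, bottom=bottom, label=label)
        bottom += counts
    ax.set_xlabel("trial")
    ax.set_ylabel("games")
    ax.set_title(f"game endings per trial (n={profile.n_games})")
    ax.legend()
    return ax


def plot_precision_trace(game: GameRecord, prior_precision: float, ax=None):
    """End-of-trial expected precision for one game, with the prior baseline."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    trials = [0] + [row.trial for row in game.rows]
    gammas = [prior_precision] + [row.gamma_hat for row in game.rows]
    ax.plot(trials, gammas, marker="o")
    ax.axhline(prior_precision, ls=":", color="grey", label=r"prior $\alpha$")
    ax.set_xlabel("trial")
    ax.set_ylabel(r"expected precision $\hat\gamma$")
    ax.set_title(f"precision trajectory (outcome: {game.outcome})")
    ax.legend()
    return ax
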