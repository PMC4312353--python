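"""Simulation of limited-offer games and cohorts.

The agent chooses under its *subjective* model — its own hazard-rate belief
(``hazard_scale``-scaled withdrawal hazard), goal sensitivity and precision
prior — while the world evolves under the objective schedule.  The mismatch
between the two is the mechanism behind the phenotypes: an agent that
underestimates the withdrawal hazard waits too long (risk-seeking), one
that overestimates it accepts immediately (over-cautious), and a low
precision prior makes choice stochastic and impulsive regardless of the
hazard belief.

Each simulated game records, per trial, the acceptance probability, the
sampled action, the world event and the end-of-trial expected precision;
trial-to-trial changes in that precision are the model's simulated
dopamine responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import AgentView
from .task import Action, State, TaskConfig, build_hazard_schedule

__all__ = [
    "AgentParams",
    "TrialRow",
    "GameRecord",
    "CohortDataset",
    "AcceptanceProfile",
    "PHENOTYPE_PRESETS",
    "phenotype_preset",
    "simulate_game",
    "scripted_game",
    "simulate_cohort",
    "dopamine_trace",
    "acceptance_profile",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Terminal outcome labels.
OUTCOMES = ("accepted_low", "high_offer", "withdrawn", "timed_out")

_EVENTS = ("none", "withdrawal", "high_offer")


@dataclass(frozen=True)
class AgentParams:
    """Subject-level parameters of the active-inference agent.

    prior_precision
        alpha > 0, the prior expectation of precision ("trait confidence");
        low values give stochastic, impulsive choice.
    hazard_scale
        eta > 0, multiplicative bias on the believed withdrawal hazard;
        eta < 1 is optimism about keeping the offer (risk-seeking),
        eta > 1 pessimism (over-caution).  The world always runs at eta = 1.
    sensitivity
        c >= 0, utility scaling inside the goal distribution.
    """

    prior_precision: float = 16.0
    hazard_scale: float = 1.0
    sensitivity: float = 6.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.prior_precision) and self.prior_precision > 0):
            raise ValueError("prior_precision must be positive and finite")
        if not (np.isfinite(self.hazard_scale) and self.hazard_scale > 0):
            raise ValueError("hazard_scale must be positive and finite")
        if not (np.isfinite(self.sensitivity) and self.sensitivity >= 0):
            raise ValueError("sensitivity must be non-negative and finite")

    def view(self, config: TaskConfig) -> AgentView:
        return AgentView(
            config,
            prior_precision=self.prior_precision,
            hazard_scale=self.hazard_scale,
            sensitivity=self.sensitivity,
        )


# Preset parameter values are package conventions chosen to express the
# hypothesised phenotypes, not values taken from any dataset:
# the addiction-like profile pairs low trait confidence (stochastic,
# impulsive choice) with an optimistic withdrawal-hazard belief
# (risk-seeking waiting); the OCD-like profile pairs intermediate
# confidence with a pessimistic hazard belief (early, habitual acceptance).
PHENOTYPE_PRESETS: dict[str, AgentParams] = {
    "control": AgentParams(prior_precision=16.0, hazard_scale=1.0, sensitivity=6.0),
    "addiction": AgentParams(prior_precision=4.0, hazard_scale=0.4, sensitivity=6.0),
    "ocd_like": AgentParams(prior_precision=8.0, hazard_scale=3.0, sensitivity=6.0),
}


def phenotype_preset(name: str) -> AgentParams:
    """Agent parameters for a named choice phenotype."""
    try:
        return PHENOTYPE_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown phenotype {name!r}; valid presets: {sorted(PHENOTYPE_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class TrialRow:
    trial: int
    state: State
    p_accept: float
    action: Action
    event: str
    gamma_hat: float


@dataclass(frozen=True)
class GameRecord:
    """One simulated game: per-trial rows up to absorption, outcome and payoff.

    ``gamma_hat`` in each row is the expected precision at the end of that
    trial, i.e. re-inferred after the trial's event was observed; its
    first difference (with the prior precision as baseline) is the
    simulated dopamine trace.
    """

    game_id: int
    rows: tuple[TrialRow, ...]
    outcome: str
    payoff: float

    @property
    def accepted_trial(self) -> int | None:
        if self.outcome != "accepted_low":
            return None
        return self.rows[-1].trial

    @property
    def n_trials(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class CohortDataset:
    """A set of games under one task configuration (and one agent, if simulated)."""

    config: TaskConfig
    games: tuple[GameRecord, ...]
    agent: AgentParams | None = None
    seed: int | None = None

    @property
    def n_games(self) -> int:
        return len(self.games)

    def outcome_counts(self) -> dict[str, int]:
        counts = {o: 0 for o in OUTCOMES}
        for g in self.games:
            counts[g.outcome] += 1
        return counts


def _end_of_trial_precision(view: AgentView, trial: int, state: State) -> float:
    """Expected precision re-inferred after trial ``trial``'s event."""
    T = view.config.horizon
    if state is State.LOW_PENDING:
        if trial >= T:  # timed out: certain zero-payoff ending
            return view.terminal_precision(State.LOW_PENDING)
        return view.expected_precision(trial + 1, State.LOW_PENDING)
    return view.expected_precision(min(trial + 1, T), state)


def _play(
    view: AgentView,
    game_id: int,
    choose,
    draw_event,
) -> GameRecord:
    """Run one game given action- and event-sampling callables."""
    config = view.config
    T = config.horizon
    rows: list[TrialRow] = []
    outcome, payoff = "timed_out", 0.0
    for t in range(1, T + 1):
        p_accept = view.accept_probability(t)
        action = choose(t, p_accept)
        if action == Action.ACCEPT:
            state_after = State.ACCEPTED_LOW
            event = "none"
            outcome, payoff = "accepted_low", config.low_offer
        else:
            event = draw_event(t)
            if event == "withdrawal":
                state_after = State.WITHDRAWN
                outcome, payoff = "withdrawn", 0.0
            elif event == "high_offer":
                state_after = State.HIGH_OBTAINED
                outcome, payoff = "high_offer", config.high_offer
            else:
                state_after = State.LOW_PENDING
        gamma = _end_of_trial_precision(view, t, state_after)
        rows.append(
            TrialRow(
                trial=t,
                state=State.LOW_PENDING,
                p_accept=p_accept,
                action=Action(action),
                event=event,
                gamma_hat=gamma,
            )
        )
        if state_after is not State.LOW_PENDING:
            break
    return GameRecord(game_id=game_id, rows=tuple(rows), outcome=outcome, payoff=payoff)


def simulate_game(
    agent: AgentParams,
    config: TaskConfig = None,
    rng_seed: int | np.random.SeedSequence | None = 0,
    game_id: int = 0,
    view: AgentView | None = None,
) -> GameRecord:
    """Simulate one game: agent decides subjectively, world runs objectively.

    ``rng_seed`` is mandatory for reproducibility (pass an integer or a
    ``numpy.random.SeedSequence``).  A prebuilt ``view`` may be supplied to
    reuse cached policy evaluations across games.
    """
    if config is None:
        config = TaskConfig()
    if view is None:
        view = agent.view(config)
    rng = np.random.default_rng(rng_seed)
    objective = build_hazard_schedule(config, hazard_scale=1.0)

    def choose(t: int, p_accept: float) -> Action:
        return Action.ACCEPT if rng.random() < p_accept else Action.WAIT

    def draw_event(t: int) -> str:
        r = objective.withdrawal[t - 1]
        q = objective.high_offer[t - 1]
        u = rng.random()
        if u < r:
            return "withdrawal"
        if u < r + q:
            return "high_offer"
        return "none"

    return _play(view, game_id, choose, draw_event)


def scripted_game(
    agent: AgentParams,
    config: TaskConfig = None,
    events: dict[int, str] | None = None,
    actions: dict[int, Action] | None = None,
    game_id: int = 0,
) -> GameRecord:
    """Deterministically replay a game with scripted events and/or actions.

    Events default to ``none`` and actions default to WAIT on trials not
    listed; acceptance probabilities and precision are still computed by
    the engine, so this reproduces event-locked traces (e.g. a withdrawal
    at trial 3) without Monte-Carlo sampling.
    """
    if config is None:
        config = TaskConfig()
    events = dict(events or {})
    actions = dict(actions or {})
    for t, e in events.items():
        if e not in _EVENTS:
            raise ValueError(f"unknown event {e!r} at trial {t}; valid: {_EVENTS}")
    view = agent.view(config)
    return _play(
        view,
        game_id,
        choose=lambda t, p: actions.get(t, Action.WAIT),
        draw_event=lambda t: events.get(t, "none"),
    )


def simulate_cohort(
    agent: AgentParams,
    config: TaskConfig = None,
    n_games: int = 256,
    seed: int = 0,
) -> CohortDataset:
    """Simulate ``n_games`` independent games with per-game derived seeds.

    Per-game randomness comes from ``SeedSequence(seed).spawn``, so every
    game has an independent, reproducible stream regardless of how many
    games precede it.
    """
    if config is None:
        config = TaskConfig()
    if n_games < 1:
        raise ValueError("n_games must be >= 1")
    view = agent.view(config)
    children = np.random.SeedSequence(seed).spawn(n_games)
    games = tuple(
        simulate_game(agent, config, rng_seed=child, game_id=i, view=view)
        for i, child in enumerate(children)
    )
    return CohortDataset(config=config, games=games, agent=agent, seed=seed)


def dopamine_trace(game: GameRecord, prior_precision: float | None = None) -> np.ndarray:
    """Per-trial precision changes, the model's simulated dopamine response.

    Returns ``gamma_t - gamma_{t-1}`` over the recorded trials.  When
    ``prior_precision`` is given it serves as the ``gamma_0`` baseline and
    the trace has one entry per trial; without it only within-game
    differences are available (a single-trial game then yields an empty
    trace).
    """
    gammas = np.array([row.gamma_hat for row in game.rows])
    if prior_precision is not None:
        return np.diff(gammas, prepend=float(prior_precision))
    return np.diff(gammas)


@dataclass(frozen=True)
class AcceptanceProfile:
    """Per-trial accounting of how games ended, plus latency statistics."""

    horizon: int
    accepted: np.ndarray  # count of low-offer acceptances per trial
    high_offer: np.ndarray  # count of high-offer receipts per trial
    withdrawn: np.ndarray  # count of withdrawals per trial
    timed_out: int
    n_games: int

    @property
    def mean_latency(self) -> float:
        """Mean acceptance trial among games that accepted the low offer."""
        n = self.accepted.sum()
        if n == 0:
            return float("nan")
        trials = np.arange(1, self.horizon + 1)
        return float((trials * self.accepted).sum() / n)

    @property
    def latency_entropy(self) -> float:
        """Shannon entropy (nats) of the acceptance-latency distribution."""
        n = self.accepted.sum()
        if n == 0:
            return float("nan")
        p = self.accepted[self.accepted > 0] / n
        return float(-(p * np.log(p)).sum())

    def accept_frequency(self, trial: int) -> float:
        """Fraction of still-waiting games that accepted at ``trial``."""
        at_risk = self.n_games - (
            self.accepted[: trial - 1].sum()
            + self.high_offer[: trial - 1].sum()
            + self.withdrawn[: trial - 1].sum()
        )
        if at_risk == 0:
            return float("nan")
        return float(self.accepted[trial - 1] / at_risk)


def acceptance_profile(dataset: CohortDataset) -> AcceptanceProfile:
    T = dataset.config.horizon
    accepted = np.zeros(T, dtype=int)
    high = np.zeros(T, dtype=int)
    withdrawn = np.zeros(T, dtype=int)
    timed_out = 0
    for g in dataset.games:
        last = g.rows[-1]
        if g.outcome == "accepted_low":
            accepted[last.trial - 1] += 1
        elif g.outcome == "high_offer":
            high[last.trial - 1] += 1
        elif g.outcome == "withdrawn":
            withdrawn[last.trial - 1] += 1
        else:
            timed_out += 1
    profile = AcceptanceProfile(
        horizon=T,
        accepted=accepted,
        high_offer=high,
        withdrawn=withdrawn,
        timed_out=timed_out,
        n_games=dataset.n_games,
    )
    assert accepted.sum() + high.sum() + withdrawn.sum() + timed_out == dataset.n_games
    return profile


# -- cohort CSV ------------------------------------------------------------

_CSV_COLUMNS = [
    "game_id",
    "trial",
    "horizon",
    "low_offer",
    "high_offer",
    "state",
    "p_accept",
    "action",
    "event",
    "gamma_hat",
    "outcome",
    "payoff",
]


def cohort_to_frame(dataset: CohortDataset) -> pd.DataFrame:
    """Long-format per-trial table of a cohort (one row per recorded trial)."""
    records = []
    cfg = dataset.config
    for g in dataset.games:
        for row in g.rows:
            records.append(
                {
                    "game_id": g.game_id,
                    "trial": row.trial,
                    "horizon": cfg.horizon,
                    "low_offer": cfg.low_offer,
                    "high_offer": cfg.high_offer,
                    "state": State(row.state).name,
                    "p_accept": row.p_accept,
                    "action": Action(row.action).name,
                    "event": row.event,
                    "gamma_hat": row.gamma_hat,
                    "outcome": g.outcome,
                    "payoff": g.payoff,
                }
            )
    return pd.DataFrame.from_records(records, columns=_CSV_COLUMNS)


def write_cohort_csv(dataset: CohortDataset, path: str | Path) -> None:
    cohort_to_frame(dataset).to_csv(path, index=False)


def frame_to_cohort(
    df: pd.DataFrame,
    config: TaskConfig | None = None,
    agent: AgentParams | None = None,
    seed: int | None = None,
) -> CohortDataset:
    """Rebuild a :class:`CohortDataset` from the long-format table.

    The CSV schema carries the horizon and offer magnitudes but not the
    hazard parameters; pass ``config`` to supply them, otherwise package
    defaults are used for the hazard fields.
    """
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError("cohort table has no rows")
    first = df.iloc[0]
    if config is None:
        config = TaskConfig(
            horizon=int(first["horizon"]),
            low_offer=float(first["low_offer"]),
            high_offer=float(first["high_offer"]),
        )
    games = []
    for gid, gdf in df.groupby("game_id", sort=True):
        gdf = gdf.sort_values("trial")
        rows = []
        for i, (_, r) in enumerate(gdf.iterrows()):
            try:
                rows.append(
                    TrialRow(
                        trial=int(r["trial"]),
                        state=State[str(r["state"])],
                        p_accept=float(r["p_accept"]),
                        action=Action[str(r["action"])],
                        event=str(r["event"]),
                        gamma_hat=float(r["gamma_hat"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"malformed cohort row (game {gid}, line {r.name + 2}): {exc}"
                ) from exc
        games.append(
            GameRecord(
                game_id=int(gid),
                rows=tuple(rows),
                outcome=str(gdf.iloc[-1]["outcome"]),
                payoff=float(gdf.iloc[-1]["payoff"]),
            )
        )
    return CohortDataset(config=config, games=tuple(games), agent=agent, seed=seed)


def read_cohort_csv(
    path: str | Path, config: TaskConfig | None = None
) -> CohortDataset:
    """Read a cohort CSV (accepts LF or CRLF line endings)."""
    # round_trip parsing keeps write->read lossless at full double precision
    df = pd.read_csv(path, float_precision="round_trip")
    return frame_to_cohort(df, config=config)
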