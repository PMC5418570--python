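"""Learning heuristics and the seeded paired-play simulation engine.

Four decision rules from the experimental-games literature are implemented as
pure prescription functions over a pair's play history, plus a trivial
``stay`` rule:

``imitate_best``
    Copy the opponent's previous action iff the opponent chose a strictly
    higher action *and* earned a strictly higher payoff; otherwise keep the
    own previous action.  In a contest the higher action always earns the
    higher relative payoff, so imitation ratchets play toward maximal
    competition.
``match``
    Copy the opponent's previous action unconditionally (tit-for-tat-like
    alignment).
``wclr``
    Win-Continue, Lose-Reverse: repeat the previous own adjustment direction
    if the own payoff improved, reverse it if the payoff declined; a
    gradient-free rule that climbs the own-payoff landscape and, in pairs,
    pushes play toward the joint-profit maximum.
``myopic_br``
    Jump to the best reply against the opponent's last observed action;
    drives play to the one-period Nash equilibrium.

The execution layer (:func:`step_agent`) wraps a rule with slider inertia
(probability of not touching the slider at all), imperfect adherence (with
the complementary probability the agent explores uniformly), and an additive
Gaussian tremble applied whenever the slider moves.  Rules can be swapped at
a configured period to emulate two-tier behaviour: a naive heuristic early,
an adapted one later.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import game as _game
from .errors import ConfigError, StateError

__all__ = [
    "RULES",
    "PairHistory",
    "AgentSpec",
    "Trajectory",
    "prescribe_imitate_best",
    "prescribe_match",
    "prescribe_wclr",
    "prescribe_myopic_br",
    "prescribe_stay",
    "step_agent",
    "run_pair",
]

RULES = ("imitate_best", "match", "wclr", "myopic_br", "stay")


class PairHistory:
    """Append-only record of both players' actions and payoffs (cents).

    Rows are periods (1-based externally); columns are the two players.
    """

    def __init__(self, params: _game.ContestParams) -> None:
        self.params = params
        self._actions: list[tuple[float, float]] = []
        self._payoffs: list[tuple[float, float]] = []

    def __len__(self) -> int:
        return len(self._actions)

    def append(self, x_a: float, x_b: float) -> None:
        pi_a = _game.payoff(x_a, x_b, self.params)
        pi_b = _game.payoff(x_b, x_a, self.params)
        self._actions.append((x_a, x_b))
        self._payoffs.append((pi_a, pi_b))

    def action(self, t: int, player: int) -> float:
        """Action of ``player`` in 1-based period ``t``."""
        return self._actions[t - 1][player]

    def payoff(self, t: int, player: int) -> float:
        return self._payoffs[t - 1][player]

    @property
    def actions(self) -> np.ndarray:
        return np.asarray(self._actions, dtype=float)

    @property
    def payoffs(self) -> np.ndarray:
        return np.asarray(self._payoffs, dtype=float)


def _require(history: PairHistory, n: int, rule: str) -> None:
    if len(history) < n:
        raise StateError(f"{rule} needs a history of >= {n} period(s), got {len(history)}")


def prescribe_imitate_best(history: PairHistory, self_index: int) -> float:
    """Opponent's previous action if it was strictly higher and earned strictly more."""
    _require(history, 1, "imitate_best")
    t = len(history)
    opp = 1 - self_index
    own_x, opp_x = history.action(t, self_index), history.action(t, opp)
    own_pi, opp_pi = history.payoff(t, self_index), history.payoff(t, opp)
    if opp_x > own_x and opp_pi > own_pi:
        return opp_x
    return own_x


def prescribe_match(history: PairHistory, self_index: int) -> float:
    """Opponent's previous action, unconditionally."""
    _require(history, 1, "match")
    return history.action(len(history), 1 - self_index)


def prescribe_wclr(history: PairHistory, self_index: int, step_size: float) -> float:
    """Signed WCLR increment given the last own adjustment and payoff change.

    Continue the previous direction if the own payoff rose (or stayed exactly
    constant), reverse it if the payoff fell.  With no previous own
    adjustment there is no direction to continue or reverse, so the
    prescription is 0 (the engine substitutes a fresh random nudge in that
    case).
    """
    _require(history, 2, "wclr")
    t = len(history)
    d_prev = history.action(t, self_index) - history.action(t - 1, self_index)
    if d_prev == 0.0:
        return 0.0
    d_pi = history.payoff(t, self_index) - history.payoff(t - 1, self_index)
    direction = np.sign(d_prev) if d_pi >= 0 else -np.sign(d_prev)
    return float(direction) * step_size


def prescribe_myopic_br(history: PairHistory, self_index: int) -> float:
    """Best reply against the opponent's previous action."""
    _require(history, 1, "myopic_br")
    return _game.best_reply(history.action(len(history), 1 - self_index), history.params)


def prescribe_stay(history: PairHistory, self_index: int) -> float:
    _require(history, 1, "stay")
    return history.action(len(history), self_index)


@dataclass(frozen=True)
class AgentSpec:
    """A heuristic rule plus its stochastic execution parameters.

    Parameters
    ----------
    rule:
        Active heuristic from :data:`RULES`.
    adherence:
        Probability of following the rule's prescription in a moving period;
        with the complementary probability the agent explores with a uniform
        draw on the action space.
    inertia:
        Probability of leaving the slider untouched in a period.
    step_size:
        Action units of one WCLR adjustment.
    tremble_sd:
        Standard deviation of the additive Gaussian tremble applied whenever
        the slider moves (0 disables trembles).
    switch_period:
        Optional 1-based period from which ``post_switch_rule`` replaces
        ``rule``.
    post_switch_rule:
        The adapted rule active from ``switch_period`` onward.
    wclr_initial_direction:
        Optional +1/-1 fixing the seeding nudge WCLR uses when no previous
        own adjustment exists; ``None`` draws the direction at random.
    """

    rule: str
    adherence: float = 1.0
    inertia: float = 0.0
    step_size: float = 0.25
    tremble_sd: float = 0.0
    switch_period: Optional[int] = None
    post_switch_rule: Optional[str] = None
    wclr_initial_direction: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ConfigError(f"unknown rule {self.rule!r}; choose from {RULES}")
        for name in ("adherence", "inertia"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not self.step_size > 0:
            raise ConfigError(f"step_size must be > 0, got {self.step_size}")
        if self.tremble_sd < 0:
            raise ConfigError(f"tremble_sd must be >= 0, got {self.tremble_sd}")
        if self.switch_period is not None:
            if self.switch_period < 2:
                raise ConfigError(f"switch_period must be >= 2, got {self.switch_period}")
            if self.post_switch_rule is None:
                raise ConfigError("switch_period set but post_switch_rule missing")
            if self.post_switch_rule not in RULES:
                raise ConfigError(f"unknown post_switch_rule {self.post_switch_rule!r}")
        if self.wclr_initial_direction not in (None, 1, -1):
            raise ConfigError("wclr_initial_direction must be +1, -1 or None")

    def active_rule(self, period: int) -> str:
        """Rule in force when choosing the action of 1-based ``period``."""
        if self.switch_period is not None and period >= self.switch_period:
            return self.post_switch_rule  # type: ignore[return-value]
        return self.rule

    def rule_label(self) -> str:
        """Compact ground-truth label, e.g. ``imitate_best->match``."""
        if self.switch_period is not None:
            return f"{self.rule}->{self.post_switch_rule}"
        return self.rule


def _wclr_memory_increment(
    history: PairHistory, self_index: int, step_size: float
) -> float:
    """WCLR increment using the *last actual* own slider move as direction.

    Subjects often wait between adjustments, so "the previous adjustment" is
    naturally the most recent period in which the slider moved.  The
    win/lose judgement compares the current payoff with the payoff just
    before that move, so the whole development since the adjustment — own
    effect plus the opponent's reaction — is credited to it.  While the
    opponent has not yet reacted at all, the agent holds course (continues)
    rather than judging the move on its own transient payoff dip; this is
    the patience that lets asynchronous adjusters discover the cooperative
    descent a synchronized pair finds automatically.  When both players move
    every period this coincides with :func:`prescribe_wclr`.  Returns 0.0
    when the slider has never moved.
    """
    t = len(history)
    s = None
    for back in range(t, 1, -1):
        if history.action(back, self_index) != history.action(back - 1, self_index):
            s = back
            break
    if s is None:
        return 0.0
    direction = np.sign(history.action(s, self_index) - history.action(s - 1, self_index))
    opp = 1 - self_index
    partner_moved = any(
        history.action(u, opp) != history.action(u - 1, opp)
        for u in range(max(s, 2), t + 1)
    )
    if not partner_moved:
        return float(direction) * step_size
    d_pi = history.payoff(t, self_index) - history.payoff(s - 1, self_index)
    return float(direction if d_pi >= 0 else -direction) * step_size


def step_agent(
    spec: AgentSpec,
    history: PairHistory,
    self_index: int,
    rng: np.random.Generator,
    period: int | None = None,
    action_grid: float | None = None,
) -> float:
    """One stochastic decision: the agent's action for the next period.

    Order of stochastic stages: inertia gate, adherence gate, prescription
    (or uniform exploration), Gaussian tremble when the slider moves, clip to
    the action bounds.  ``action_grid`` optionally snaps the chosen action to
    a finite slider resolution.
    """
    _require(history, 1, spec.rule)
    params = history.params
    t_next = (period if period is not None else len(history) + 1)
    own_prev = history.action(len(history), self_index)

    if rng.random() < spec.inertia:
        return own_prev

    rule = spec.active_rule(t_next)
    if rng.random() < spec.adherence:
        if rule == "wclr":
            increment = 0.0
            if len(history) >= 2:
                increment = _wclr_memory_increment(history, self_index, spec.step_size)
            if increment == 0.0:
                # no direction yet (slider never moved): seed a fresh nudge
                if spec.wclr_initial_direction is not None:
                    direction = float(spec.wclr_initial_direction)
                else:
                    direction = 1.0 if rng.random() < 0.5 else -1.0
                increment = direction * spec.step_size
            target = own_prev + increment
        elif rule == "imitate_best":
            target = prescribe_imitate_best(history, self_index)
        elif rule == "match":
            target = prescribe_match(history, self_index)
        elif rule == "myopic_br":
            target = prescribe_myopic_br(history, self_index)
        else:  # stay
            target = own_prev
    else:
        target = rng.uniform(params.action_min, params.action_max)

    if target != own_prev and spec.tremble_sd > 0:
        target += rng.normal(0.0, spec.tremble_sd)
    target = float(np.clip(target, params.action_min, params.action_max))
    if action_grid is not None:
        target = float(
            np.clip(round(target / action_grid) * action_grid,
                    params.action_min, params.action_max)
        )
    return target


@dataclass
class Trajectory:
    """One pair's full play path plus (optional) ground-truth agent specs."""

    pair_id: int
    treatment: str
    actions: np.ndarray  # (horizon, 2)
    payoffs_cents: np.ndarray  # (horizon, 2)
    params: _game.ContestParams
    specs: Optional[tuple[AgentSpec, AgentSpec]] = None
    subject_ids: tuple[int, int] = (0, 1)

    @property
    def horizon(self) -> int:
        return self.actions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long subject-period table (one row per subject and period)."""
        h = self.horizon
        frames = []
        for k in range(2):
            spec = self.specs[k] if self.specs is not None else None
            frames.append(
                pd.DataFrame(
                    {
                        "treatment": self.treatment,
                        "pair_id": self.pair_id,
                        "subject_id": self.subject_ids[k],
                        "period": np.arange(1, h + 1),
                        "action": self.actions[:, k],
                        "payoff_cents": self.payoffs_cents[:, k],
                        "payoff_points": _game.cents_to_points(
                            self.payoffs_cents[:, k], self.params
                        ),
                        "true_rule": spec.rule_label() if spec is not None else "",
                        "true_switch_period": (
                            spec.switch_period
                            if spec is not None and spec.switch_period is not None
                            else np.nan
                        ),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def run_pair(
    spec_a: AgentSpec,
    spec_b: AgentSpec,
    horizon: int,
    params: _game.ContestParams | None = None,
    initial_actions: tuple[float, float] | None = None,
    rng: np.random.Generator | int | None = None,
    pair_id: int = 0,
    treatment: str = "NoInfo",
    subject_ids: tuple[int, int] = (0, 1),
    action_grid: float | None = 0.01,
) -> Trajectory:
    """Simulate one pair for ``horizon`` periods with simultaneous moves.

    In period 1 the sliders sit at ``initial_actions`` (uniform random when
    absent, mirroring random initial slider positions).  In every later
    period both agents choose given the history through the previous period
    only (one-period memory), then payoffs are computed from the realized
    profile.  Actions snap to the slider resolution ``action_grid``
    (default 0.01 action units; ``None`` for a truly continuous slider), so
    exact action ties and exactly constant payoffs can occur, as they do on
    a real interface.
    """
    if horizon < 1:
        raise ConfigError(f"horizon must be >= 1, got {horizon}")
    params = params if params is not None else _game.default_params()
    rng = np.random.default_rng(rng)
    if initial_actions is None:
        initial_actions = tuple(rng.uniform(params.action_min, params.action_max, 2))
    x_a, x_b = float(initial_actions[0]), float(initial_actions[1])
    for x in (x_a, x_b):
        if not params.action_min <= x <= params.action_max:
            raise ConfigError(f"initial action {x:g} outside bounds")
    if action_grid is not None:
        x_a = float(np.clip(round(x_a / action_grid) * action_grid,
                            params.action_min, params.action_max))
        x_b = float(np.clip(round(x_b / action_grid) * action_grid,
                            params.action_min, params.action_max))

    hist = PairHistory(params)
    hist.append(x_a, x_b)
    for t in range(2, horizon + 1):
        # simultaneous: both decisions read the history through t-1
        next_a = step_agent(spec_a, hist, 0, rng, period=t, action_grid=action_grid)
        next_b = step_agent(spec_b, hist, 1, rng, period=t, action_grid=action_grid)
        hist.append(next_a, next_b)

    return Trajectory(
        pair_id=pair_id,
        treatment=treatment,
        actions=hist.actions,
        payoffs_cents=hist.payoffs,
        params=params,
        specs=(spec_a, spec_b),
        subject_ids=subject_ids,
    )
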