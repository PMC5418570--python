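"""Synthetic behavioral experiments with ground-truth heuristic labels.

No subject-level data from the original laboratory sessions is deposited
anywhere public, so the analysis pipeline is exercised on synthetic
experiments that copy the design — two treatments (Info / NoInfo), 18
independent anonymous pairs each, 600 periods, continuous actions on
[0.1, 6], random initial slider positions — and the narrative structure the
aggregate results suggest:

* NoInfo subjects start on a naive imitate-the-best heuristic and, around
  period 25, switch to an adapted pro-cooperative heuristic (a mixture of
  match and win-continue-lose-reverse);
* Info subjects adopt myopic best reply from the start and stick with it.

Switch periods are drawn per subject from a geometric distribution centered
near the configured period (a hard common changepoint would make the
analysis-phase cut a behavioral law, which it is not).  Execution parameters
(adherence, inertia, tremble, WCLR step) are drawn per subject from uniform
ranges to emulate subject heterogeneity; the ranges are free parameters of
the generator, chosen to reproduce the ordinal treatment patterns (NoInfo
above Nash early and below Nash late, Info near Nash throughout), not any
particular published moment.

Every subject carries its ground-truth :class:`~contestlearn.heuristics.AgentSpec`
so estimator recovery can be tested against known labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import game as _game
from .heuristics import RULES, AgentSpec, Trajectory, run_pair
from .errors import ConfigError, ParseError, SchemaError

__all__ = [
    "SyntheticConfig",
    "generate_experiment",
    "write_dataset",
    "read_dataset",
    "trajectories_to_frame",
    "frame_to_trajectories",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = (
    "treatment",
    "pair_id",
    "subject_id",
    "period",
    "action",
    "payoff_cents",
    "payoff_points",
    "true_rule",
    "true_switch_period",
)


def _check_mixture(name: str, mixture: Mapping[str, float]) -> None:
    if not mixture:
        raise ConfigError(f"{name}: empty rule mixture")
    for rule, w in mixture.items():
        if rule not in RULES:
            raise ConfigError(f"{name}: unknown rule {rule!r}")
        if w < 0:
            raise ConfigError(f"{name}: negative weight {w} for {rule!r}")
    total = float(sum(mixture.values()))
    if not np.isclose(total, 1.0):
        raise ConfigError(f"{name}: mixture weights sum to {total:g}, expected 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and behavioral parameters of a synthetic experiment.

    Ranges are (low, high) uniform supports sampled once per subject.
    """

    n_pairs: int = 18
    horizon: int = 600
    noinfo_naive_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"imitate_best": 1.0}
    )
    noinfo_adapted_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"match": 0.5, "wclr": 0.5}
    )
    info_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"myopic_br": 1.0}
    )
    noinfo_switch_prob: float = 1.0
    info_switch_prob: float = 0.10
    switch_center: int = 25
    info_switch_center: int = 150
    adherence_range: tuple[float, float] = (0.90, 0.99)
    inertia_range: tuple[float, float] = (0.30, 0.60)
    step_range: tuple[float, float] = (0.20, 0.50)
    tremble_range: tuple[float, float] = (0.03, 0.12)
    action_grid: float | None = 0.01

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError(f"n_pairs must be >= 1, got {self.n_pairs}")
        if self.horizon < 2:
            raise ConfigError(f"horizon must be >= 2, got {self.horizon}")
        for name in ("switch_center", "info_switch_center"):
            if getattr(self, name) < 3:
                raise ConfigError(f"{name} must be >= 3, got {getattr(self, name)}")
        for name in ("noinfo_switch_prob", "info_switch_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        _check_mixture("noinfo_naive_mixture", self.noinfo_naive_mixture)
        _check_mixture("noinfo_adapted_mixture", self.noinfo_adapted_mixture)
        _check_mixture("info_mixture", self.info_mixture)


def _draw_rule(mixture: Mapping[str, float], rng: np.random.Generator) -> str:
    rules = sorted(mixture)
    weights = np.array([mixture[r] for r in rules], dtype=float)
    return rules[rng.choice(len(rules), p=weights / weights.sum())]


def _draw_subject_spec(
    config: SyntheticConfig, treatment: str, rng: np.random.Generator
) -> AgentSpec:
    adherence = rng.uniform(*config.adherence_range)
    inertia = rng.uniform(*config.inertia_range)
    step = rng.uniform(*config.step_range)
    tremble = rng.uniform(*config.tremble_range)
    if treatment == "Info":
        naive = _draw_rule(config.info_mixture, rng)
        switch_prob, center = config.info_switch_prob, config.info_switch_center
    else:
        naive = _draw_rule(config.noinfo_naive_mixture, rng)
        switch_prob, center = config.noinfo_switch_prob, config.switch_center
    switches = rng.random() < switch_prob
    # draw consumed either way so the stream does not depend on the outcome
    adapted = _draw_rule(config.noinfo_adapted_mixture, rng)
    # geometric around the configured center: support {3, 4, ...}, mean = center
    switch = 2 + int(rng.geometric(1.0 / (center - 2)))
    if not switches or switch >= config.horizon:
        return AgentSpec(
            rule=naive,
            adherence=adherence,
            inertia=inertia,
            step_size=step,
            tremble_sd=tremble,
        )
    return AgentSpec(
        rule=naive,
        adherence=adherence,
        inertia=inertia,
        step_size=step,
        tremble_sd=tremble,
        switch_period=int(switch),
        post_switch_rule=adapted,
    )


def generate_experiment(
    config: SyntheticConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    params: _game.ContestParams | None = None,
    treatments: Sequence[str] = ("NoInfo", "Info"),
) -> list[Trajectory]:
    """Generate ``n_pairs`` labeled trajectories per treatment, reproducibly.

    The master seed fans out to one independent child stream per pair, so a
    pair's path does not depend on how many other pairs are generated.
    """
    config = config if config is not None else SyntheticConfig()
    params = params if params is not None else _game.default_params()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_streams = len(treatments) * config.n_pairs
    children = ss.spawn(n_streams)

    out: list[Trajectory] = []
    pair_id = 0
    for treatment in treatments:
        for _ in range(config.n_pairs):
            rng = np.random.default_rng(children[pair_id])
            spec_a = _draw_subject_spec(config, treatment, rng)
            spec_b = _draw_subject_spec(config, treatment, rng)
            traj = run_pair(
                spec_a,
                spec_b,
                horizon=config.horizon,
                params=params,
                rng=rng,
                pair_id=pair_id,
                treatment=treatment,
                subject_ids=(2 * pair_id, 2 * pair_id + 1),
                action_grid=config.action_grid,
            )
            out.append(traj)
            pair_id += 1
    return out


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Concatenate pair trajectories into one long subject-period table."""
    frame = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
    return frame[list(DATASET_COLUMNS)]


def frame_to_trajectories(
    frame: pd.DataFrame, params: _game.ContestParams | None = None
) -> list[Trajectory]:
    """Rebuild per-pair trajectories (without agent specs) from a long table."""
    params = params if params is not None else _game.default_params()
    out = []
    for (treatment, pair_id), grp in frame.groupby(["treatment", "pair_id"], sort=True):
        subjects = sorted(grp["subject_id"].unique())
        if len(subjects) != 2:
            raise ParseError(
                f"pair {pair_id}: expected exactly 2 subjects, got {len(subjects)}"
            )
        wide_a = grp[grp["subject_id"] == subjects[0]].sort_values("period")
        wide_b = grp[grp["subject_id"] == subjects[1]].sort_values("period")
        if not np.array_equal(wide_a["period"].to_numpy(), wide_b["period"].to_numpy()):
            raise ParseError(f"pair {pair_id}: subjects cover different periods")
        actions = np.column_stack([wide_a["action"], wide_b["action"]])
        payoffs = np.column_stack([wide_a["payoff_cents"], wide_b["payoff_cents"]])
        out.append(
            Trajectory(
                pair_id=int(pair_id),
                treatment=str(treatment),
                actions=actions,
                payoffs_cents=payoffs,
                params=params,
                specs=None,
                subject_ids=(int(subjects[0]), int(subjects[1])),
            )
        )
    return out


def write_dataset(trajectories: Sequence[Trajectory] | pd.DataFrame, path) -> Path:
    """Write the long trajectory table as headered, UTF-8, comma-delimited text."""
    frame = (
        trajectories
        if isinstance(trajectories, pd.DataFrame)
        else trajectories_to_frame(trajectories)
    )
    path = Path(path)
    frame.to_csv(path, index=False, encoding="utf-8")
    return path


def read_dataset(path, params: _game.ContestParams | None = None) -> pd.DataFrame:
    """Read and validate a trajectory table written by :func:`write_dataset`.

    Validates the schema (all canonical columns present) and the action
    bounds; malformed rows raise :class:`ParseError` naming the offending
    line (1-based, header = line 1).
    """
    params = params if params is not None else _game.default_params()
    path = Path(path)
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    frame = frame[list(DATASET_COLUMNS)]
    for col in ("action", "payoff_cents", "payoff_points", "period"):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna()
        if bad.any():
            line = int(frame.index[bad][0]) + 2
            raise ParseError(f"{path}, line {line}: non-numeric {col!r}")
        frame[col] = values
    out_of_bounds = (frame["action"] < params.action_min) | (
        frame["action"] > params.action_max
    )
    if out_of_bounds.any():
        idx = int(frame.index[out_of_bounds][0])
        raise ParseError(
            f"{path}, line {idx + 2}: action {frame.loc[idx, 'action']:g} outside "
            f"[{params.action_min}, {params.action_max}]"
        )
    if (frame["period"] < 1).any():
        idx = int(frame.index[frame["period"] < 1][0])
        raise ParseError(f"{path}, line {idx + 2}: period must be >= 1")
    frame["true_rule"] = frame["true_rule"].fillna("")
    return frame
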