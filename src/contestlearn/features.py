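"""Subject-period dummy coding of heuristic prescriptions.

Heuristic use is measured through the *direction* of action changes: for
every subject-period in which the subject actually moved the slider, the
binary outcome CHANGE records whether the action went up (1) or down (0),
and each heuristic contributes a dummy saying whether it prescribed an
increase given the information available at that point:

``copy_up``   — opponent's previous action was strictly higher (imitation /
                matching prescribe an increase);
``copy_down`` — opponent's previous action was strictly lower;
``wclr``      — win-continue-lose-reverse prescribes an increase given the
                own adjustment from t-2 to t-1 and the own payoff change
                over the same step; constant own profit is coded 1 by
                default (variants: code 0, or drop those rows);
``br``        — the myopic best reply to the opponent's action at t-1 lies
                above the subject's own action at t-1;
``info``      — treatment dummy (1 = Info).

Rows need two lags, so periods 1-2 never emit; periods with an unchanged own
action are dropped (CHANGE has no third state).  Degenerate cases — WCLR
with no previous own adjustment, and exact best-reply ties — are coded 0 and
counted in the coding log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import game as _game
from .heuristics import Trajectory
from .errors import ConfigError, StateError

__all__ = [
    "CodingLog",
    "code_features",
    "assign_phase",
    "wclr_variant",
    "PHASE_CUTOFFS",
    "FEATURE_COLUMNS",
]

#: Default phase cut periods: naive <= first < learning <= second < longrun.
PHASE_CUTOFFS = (25, 300)
PHASES = ("naive", "learning", "longrun")

FEATURE_COLUMNS = (
    "treatment",
    "pair_id",
    "subject_id",
    "period",
    "change",
    "copy_up",
    "copy_down",
    "wclr",
    "br",
    "info",
    "phase",
    "at_boundary",
    "wclr_const_profit",
)


@dataclass
class CodingLog:
    """Row accounting and degenerate-case counts from one coding pass."""

    total_subject_periods: int = 0
    warmup_rows: int = 0
    zero_change_rows: int = 0
    emitted_rows: int = 0
    wclr_no_direction: int = 0
    wclr_const_profit: int = 0
    br_ties: int = 0

    def check(self) -> None:
        assert (
            self.emitted_rows + self.zero_change_rows + self.warmup_rows
            == self.total_subject_periods
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "total_subject_periods": self.total_subject_periods,
            "warmup_rows": self.warmup_rows,
            "zero_change_rows": self.zero_change_rows,
            "emitted_rows": self.emitted_rows,
            "wclr_no_direction": self.wclr_no_direction,
            "wclr_const_profit": self.wclr_const_profit,
            "br_ties": self.br_ties,
        }


def assign_phase(period, cutoffs: tuple[int, int] = PHASE_CUTOFFS):
    """Phase label(s) for 1-based period(s): naive / learning / longrun."""
    lo, hi = cutoffs
    if not 1 <= lo < hi:
        raise ConfigError(f"phase cutoffs must satisfy 1 <= first < second, got {cutoffs}")
    p = np.asarray(period)
    if np.any(p < 1):
        raise ConfigError("periods are 1-based")
    out = np.where(p <= lo, "naive", np.where(p <= hi, "learning", "longrun"))
    return str(out) if out.ndim == 0 else out


def _code_subject(
    actions_own: np.ndarray,
    actions_opp: np.ndarray,
    payoffs_own: np.ndarray,
    params: _game.ContestParams,
    boundary_tol: float,
    log: CodingLog,
) -> dict[str, np.ndarray]:
    """Vectorized coding for one subject; returns emitted-row columns."""
    h = actions_own.shape[0]
    t = np.arange(3, h + 1)  # candidate periods (1-based)
    own_t = actions_own[t - 1]
    own_1 = actions_own[t - 2]  # t-1
    own_2 = actions_own[t - 3]  # t-2
    opp_1 = actions_opp[t - 2]
    pi_1 = payoffs_own[t - 2]
    pi_2 = payoffs_own[t - 3]

    log.total_subject_periods += h
    log.warmup_rows += 2

    moved = own_t != own_1  # exact float comparison on stored actions
    log.zero_change_rows += int(np.sum(~moved))
    log.emitted_rows += int(np.sum(moved))

    change = (own_t > own_1).astype(int)
    copy_up = (opp_1 > own_1).astype(int)
    copy_down = (opp_1 < own_1).astype(int)

    d_prev = own_1 - own_2
    d_pi = pi_1 - pi_2
    const_profit = d_pi == 0.0
    no_direction = (d_prev == 0.0) & ~const_profit
    prescribes_up = np.where(
        d_pi >= 0, d_prev > 0, d_prev < 0
    )  # continue on win, reverse on loss
    wclr = np.where(const_profit, 1, np.where(no_direction, 0, prescribes_up)).astype(int)
    log.wclr_const_profit += int(np.sum(const_profit & moved))
    log.wclr_no_direction += int(np.sum(no_direction & moved))

    br_target = _game.best_reply(opp_1, params)
    br_tie = br_target == own_1
    br = (br_target > own_1).astype(int)  # exact ties code 0
    log.br_ties += int(np.sum(br_tie & moved))

    at_boundary = (np.abs(own_1 - params.action_min) <= boundary_tol) | (
        np.abs(own_1 - params.action_max) <= boundary_tol
    )

    return {
        "period": t[moved],
        "change": change[moved],
        "copy_up": copy_up[moved],
        "copy_down": copy_down[moved],
        "wclr": wclr[moved],
        "br": br[moved],
        "at_boundary": at_boundary[moved].astype(int),
        "wclr_const_profit": const_profit[moved].astype(int),
    }


def code_features(
    trajectories: Sequence[Trajectory],
    cutoffs: tuple[int, int] = PHASE_CUTOFFS,
    boundary_tol: float = 1e-12,
) -> tuple[pd.DataFrame, CodingLog]:
    """Code the full dummy table for a set of trajectories.

    Returns the feature table (one row per subject-period with a defined
    action change) and a :class:`CodingLog` with the dropped-row accounting.
    """
    log = CodingLog()
    parts = []
    for traj in trajectories:
        if traj.horizon < 3:
            raise StateError(
                f"pair {traj.pair_id}: horizon {traj.horizon} < 3, cannot code features"
            )
        info = 1 if traj.treatment == "Info" else 0
        for k in range(2):
            cols = _code_subject(
                traj.actions[:, k],
                traj.actions[:, 1 - k],
                traj.payoffs_cents[:, k],
                traj.params,
                boundary_tol,
                log,
            )
            part = pd.DataFrame(cols)
            part.insert(0, "treatment", traj.treatment)
            part.insert(1, "pair_id", traj.pair_id)
            part.insert(2, "subject_id", traj.subject_ids[k])
            part["info"] = info
            parts.append(part)
    table = pd.concat(parts, ignore_index=True)
    table["phase"] = assign_phase(table["period"].to_numpy(), cutoffs)
    table = table[list(FEATURE_COLUMNS)]
    log.check()
    return table, log


def wclr_variant(table: pd.DataFrame, mode: str = "const1") -> pd.DataFrame:
    """Recode or drop the constant-profit rows of the WCLR dummy.

    ``const1`` (default) keeps the code-as-1 convention; ``const0`` recodes
    those rows to 0; ``drop`` removes them.
    """
    if mode not in ("const1", "const0", "drop"):
        raise ConfigError(f"unknown wclr variant {mode!r}; use const1, const0 or drop")
    if mode == "const1":
        return table.copy()
    mask = table["wclr_const_profit"].astype(bool)
    out = table.copy()
    if mode == "const0":
        out.loc[mask, "wclr"] = 0
        return out
    return out.loc[~mask].reset_index(drop=True)
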