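"""The symmetric two-player contest game.

Each player chooses an effort-like action :math:`x` on a continuous interval
``[action_min, action_max]``.  Per-period profit (in euro cents) is an affine
contest share

.. math::

    \\pi(x_i, x_j) = g \\frac{x_i}{x_i + x_j} - c\\, x_i + b,

where ``g`` (``gain_scale``) scales the prize share, ``c`` (``cost_rate``) is
the marginal cost of the action and ``b`` (``baseline``) is an additive
constant.  A higher action always yields a higher *relative* payoff while
lowering joint profits, so the game pits competition against cooperation: the
symmetric one-period Nash action is :math:`g/(4c)` while joint profits are
maximized at the lower action bound.

Parameters are not hard coded; they are recovered by :func:`calibrate` from
symmetric payoff anchors (action, payoff) and/or the Nash first-order
condition, so alternative parameterizations of the same family can be swapped
in.  All internal payoffs are euro cents per period; lab points are cents
times ``points_per_euro / 100`` and euros are points divided by
``points_per_euro``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import BoundsError, CalibrationError

__all__ = [
    "ContestParams",
    "PayoffAnchor",
    "DEFAULT_ANCHORS",
    "calibrate",
    "default_params",
    "payoff",
    "symmetric_payoff",
    "best_reply",
    "nash_action",
    "relative_payoff",
    "points_to_euro",
    "cents_to_points",
]

#: Numerical tolerance (cents) for calibration residuals and fixed points.
CALIBRATION_TOL = 1e-9


@dataclass(frozen=True)
class ContestParams:
    """Calibrated payoff parameters, in euro cents per period.

    Attributes
    ----------
    gain_scale:
        Prize scale ``g`` multiplying the contest share ``x_i/(x_i+x_j)``.
    cost_rate:
        Marginal action cost ``c`` (cents per action unit).
    baseline:
        Additive constant ``b`` (cents per period).
    action_min, action_max:
        Hard bounds of the continuous action space.
    points_per_euro:
        Conversion divisor from lab points to euro.
    """

    gain_scale: float
    cost_rate: float
    baseline: float
    action_min: float = 0.1
    action_max: float = 6.0
    points_per_euro: float = 2000.0

    def __post_init__(self) -> None:
        if not self.gain_scale > 0:
            raise CalibrationError(f"gain_scale must be > 0, got {self.gain_scale}")
        if not self.cost_rate > 0:
            raise CalibrationError(f"cost_rate must be > 0, got {self.cost_rate}")
        if not 0 < self.action_min < self.action_max:
            raise CalibrationError(
                f"need 0 < action_min < action_max, got [{self.action_min}, {self.action_max}]"
            )
        star = self.gain_scale / (4.0 * self.cost_rate)
        if not self.action_min <= star <= self.action_max:
            raise CalibrationError(
                f"interior Nash action {star:g} outside [{self.action_min}, {self.action_max}]"
            )

    # -- unit conversions ---------------------------------------------------
    @property
    def points_per_cent(self) -> float:
        return self.points_per_euro / 100.0


@dataclass(frozen=True)
class PayoffAnchor:
    """A printed symmetric payoff: both players at ``action`` earn ``payoff`` cents."""

    action: float
    payoff: float


#: The three symmetric profiles the experiment's instructions pin down, plus
#: the interior Nash action used as an optional fourth condition.
DEFAULT_ANCHORS: tuple[PayoffAnchor, ...] = (
    PayoffAnchor(0.1, 3.45),
    PayoffAnchor(3.0, 2.0),
    PayoffAnchor(6.0, 0.5),
)
DEFAULT_NASH_ACTION = 3.0


def _check_actions(params: ContestParams, *actions: float) -> None:
    for x in actions:
        arr = np.asarray(x, dtype=float)
        if np.any(arr < params.action_min) or np.any(arr > params.action_max):
            bad = arr[(arr < params.action_min) | (arr > params.action_max)]
            raise BoundsError(
                f"action {np.atleast_1d(bad)[0]:g} outside "
                f"[{params.action_min}, {params.action_max}]"
            )


def payoff(x_own, x_opp, params: ContestParams):
    """Per-period profit (euro cents) of the player choosing ``x_own``.

    Accepts scalars or broadcastable arrays; both actions must lie inside the
    action bounds (the lower bound is strictly positive, so the contest share
    is always well defined).
    """
    _check_actions(params, x_own, x_opp)
    x_own = np.asarray(x_own, dtype=float)
    x_opp = np.asarray(x_opp, dtype=float)
    out = (
        params.gain_scale * x_own / (x_own + x_opp)
        - params.cost_rate * x_own
        + params.baseline
    )
    return float(out) if out.ndim == 0 else out


def symmetric_payoff(x, params: ContestParams):
    """Profit when both players choose ``x``: ``g/2 - c*x + b`` (affine in x)."""
    return payoff(x, x, params)


def relative_payoff(x_own, x_opp, params: ContestParams):
    """Own minus opponent profit at the profile ``(x_own, x_opp)``.

    Equals ``(x_own - x_opp) * (g/(x_own+x_opp) - c)``; with calibrated
    parameters the bracket is positive on the whole action space, so the
    higher action always earns the higher relative payoff.
    """
    out = np.asarray(payoff(x_own, x_opp, params)) - np.asarray(
        payoff(x_opp, x_own, params)
    )
    return float(out) if out.ndim == 0 else out


def best_reply(x_opp, params: ContestParams):
    """Unique payoff maximizer against ``x_opp``, clipped to the action bounds.

    The interior first-order condition ``g*x_opp/(x+x_opp)^2 = c`` gives the
    closed form ``sqrt(g*x_opp/c) - x_opp``.
    """
    _check_actions(params, x_opp)
    x_opp = np.asarray(x_opp, dtype=float)
    interior = np.sqrt(params.gain_scale * x_opp / params.cost_rate) - x_opp
    out = np.clip(interior, params.action_min, params.action_max)
    return float(out) if out.ndim == 0 else out


def nash_action(params: ContestParams) -> float:
    """Symmetric one-period Nash action ``g/(4c)``, the fixed point of best_reply."""
    star = params.gain_scale / (4.0 * params.cost_rate)
    assert abs(best_reply(star, params) - star) < CALIBRATION_TOL
    return star


def points_to_euro(points, params: ContestParams | None = None):
    """Convert lab points to euro (default divisor 2,000)."""
    divisor = params.points_per_euro if params is not None else 2000.0
    arr = np.asarray(points, dtype=float)
    if np.any(arr < 0):
        raise BoundsError(f"points must be >= 0, got {arr[arr < 0].flat[0]:g}")
    out = arr / divisor
    return float(out) if out.ndim == 0 else out


def cents_to_points(cents, params: ContestParams | None = None):
    """Convert euro cents to lab points (20 points per cent at 2,000 points/euro)."""
    factor = (params.points_per_euro if params is not None else 2000.0) / 100.0
    out = np.asarray(cents, dtype=float) * factor
    return float(out) if out.ndim == 0 else out


def calibrate(
    anchors: Sequence[PayoffAnchor | tuple[float, float]],
    nash_action: float | None = None,
    *,
    action_min: float = 0.1,
    action_max: float = 6.0,
    points_per_euro: float = 2000.0,
    tol: float = CALIBRATION_TOL,
) -> ContestParams:
    """Recover ``(gain_scale, cost_rate, baseline)`` from payoff conditions.

    Each symmetric anchor ``(x, p)`` contributes the linear condition
    ``g/2 - c*x + b = p``; an optional Nash action ``x*`` contributes the
    first-order condition ``g - 4*c*x* = 0``.  The system may be
    overdetermined; every supplied condition must then still hold to within
    ``tol`` cents, otherwise a :class:`CalibrationError` reporting the
    residuals is raised.

    Symmetric anchors alone pin down ``c`` and the sum ``g/2 + b`` but not
    the gain/baseline split (symmetric payoffs are blind to it).  When no
    Nash condition is supplied, the split is closed by the family's
    normalization ``g = 2*c*action_max``: the minimal prize scale for which
    a higher action earns a higher relative payoff on the *whole* action
    space (the bracket ``g/(x_i+x_j) - c`` stays nonnegative up to the
    maximal profile).  Equivalently, it places the interior Nash action at
    the midpoint ``action_max/2`` of the action space — the normalization
    under which the game's printed anchors are mutually consistent.
    """
    anchors = [a if isinstance(a, PayoffAnchor) else PayoffAnchor(*a) for a in anchors]
    seen: dict[float, float] = {}
    for a in anchors:
        if not action_min <= a.action <= action_max:
            raise BoundsError(
                f"anchor action {a.action:g} outside [{action_min}, {action_max}]"
            )
        if a.action in seen and not math.isclose(seen[a.action], a.payoff):
            raise CalibrationError(
                f"contradictory anchors at action {a.action:g}: "
                f"payoffs {seen[a.action]:g} and {a.payoff:g}"
            )
        seen[a.action] = a.payoff

    rows, rhs, labels = [], [], []
    for a in anchors:
        rows.append([0.5, -a.action, 1.0])
        rhs.append(a.payoff)
        labels.append(f"symmetric_payoff({a.action:g}) = {a.payoff:g}")
    if nash_action is not None:
        rows.append([1.0, -4.0 * nash_action, 0.0])
        rhs.append(0.0)
        labels.append(f"nash first-order condition at {nash_action:g}")

    A = np.array(rows, dtype=float)
    y = np.array(rhs, dtype=float)
    n_supplied = len(rows)
    if nash_action is None and np.linalg.matrix_rank(A) < 3:
        # symmetric anchors leave the gain/baseline split free; close it with
        # the minimal-gain normalization g = 2*c*action_max (Nash at the
        # midpoint of the action space)
        A = np.vstack([A, [1.0, -2.0 * action_max, 0.0]])
        y = np.append(y, 0.0)
    if np.linalg.matrix_rank(A) < 3:
        raise CalibrationError(
            f"rank-deficient condition set ({n_supplied} conditions, "
            f"rank {np.linalg.matrix_rank(A[:n_supplied])}): "
            "need 3 independent conditions (or 2 distinct symmetric anchors)"
        )
    theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    # prefer the exactly-representable solution when rounding is lossless
    # (keeps knife-edge identities, e.g. best replies hitting an action
    # exactly, detectable downstream)
    theta_snapped = np.round(theta, 12)
    if np.max(np.abs(A @ theta_snapped - y)) <= tol:
        theta = theta_snapped
    resid = (A @ theta - y)[:n_supplied]
    if np.max(np.abs(resid)) > tol:
        detail = "; ".join(
            f"{lab}: residual {r:+.3e}" for lab, r in zip(labels, resid)
        )
        raise CalibrationError(f"inconsistent calibration conditions: {detail}")
    g, c, b = (float(v) for v in theta)
    return ContestParams(
        gain_scale=g,
        cost_rate=c,
        baseline=b,
        action_min=action_min,
        action_max=action_max,
        points_per_euro=points_per_euro,
    )


def default_params() -> ContestParams:
    """Parameters calibrated from the three printed symmetric anchors."""
    return calibrate(DEFAULT_ANCHORS)
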