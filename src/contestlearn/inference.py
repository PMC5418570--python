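"""Estimation and testing: the linear probability model and phase statistics.

The core regression is a linear probability model (OLS on the binary CHANGE
outcome) of the form

    CHANGE ~ COPY_UP + COPY_DOWN + WCLR + BR + INFO
             + COPY_UP:INFO + COPY_DOWN:INFO + WCLR:INFO + BR:INFO

with standard errors clustered on pairs (the independent observational
units) using the one-way sandwich estimator and the conventional
small-sample factor G/(G-1) * (N-1)/(N-K).  Coefficients are probability
differences: e.g. the COPY_UP coefficient is the change in the probability
of an upward move when the opponent was higher in the previous period.  A
Logit estimator is available behind the same interface as a robustness
variant.

Aggregate statistics mirror the descriptive analysis of the experiment:
median actions in period bins (5-period bins up to period 25, 25-period bins
after), pooled action moments per treatment x phase, a two-sided
Mann-Whitney U test comparing treatments on pair-level statistics, a
one-sample t test of pair-level mean actions against the Nash action, and
phase earnings in euro (summed lab points divided by the points-per-euro
conversion).  Pairs, not subjects, are the default unit for tests because
only pairs are statistically independent; subject-level variants are
exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import game as _game
from .features import PHASE_CUTOFFS, assign_phase
from .heuristics import Trajectory
from .errors import EstimationError, TestError, ConfigError

__all__ = [
    "INTERACTION_REGRESSORS",
    "RegressionResult",
    "TestResult",
    "fit_lpm",
    "wald_combination",
    "median_action_bins",
    "phase_summary",
    "mann_whitney_treatments",
    "t_test_vs_nash",
    "earnings",
]

#: The full interaction design of the behavioral regression.
INTERACTION_REGRESSORS = (
    "copy_up",
    "copy_down",
    "wclr",
    "br",
    "info",
    "copy_up:info",
    "copy_down:info",
    "wclr:info",
    "br:info",
)

#: Main-effects-only design for single-treatment populations.
MAIN_EFFECT_REGRESSORS = ("copy_up", "copy_down", "wclr", "br")


@dataclass
class RegressionResult:
    """Estimates, cluster-robust covariance and fit statistics of one model."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    r_squared: float
    f_statistic: float
    nobs: int
    n_clusters: int
    df_inference: float
    estimator: str
    sm_results: object  # underlying statsmodels results (not serialized)

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def se(self, name: str) -> float:
        return float(self.bse[name])

    def pvalue(self, name: str) -> float:
        return float(np.asarray(self.sm_results.pvalues)[self.params.index.get_loc(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se_clustered": self.bse,
                "p": np.asarray(self.sm_results.pvalues),
            }
        )


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    method: str
    statistic: float
    pvalue: float
    unit: str
    n: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.pvalue <= 1.0 + 1e-12


def _interaction_columns(table: pd.DataFrame, regressors: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    for name in regressors:
        if ":" in name:
            a, b = name.split(":")
            X[name] = table[a].to_numpy() * table[b].to_numpy()
        else:
            X[name] = table[name].to_numpy()
    return X.astype(float)


def _subset_phase(
    table: pd.DataFrame,
    phases: Sequence[str] | None,
    periods: tuple[int, int] | None,
) -> pd.DataFrame:
    out = table
    if phases is not None:
        out = out[out["phase"].isin(list(phases))]
    if periods is not None:
        lo, hi = periods
        out = out[(out["period"] >= lo) & (out["period"] <= hi)]
    return out


def fit_lpm(
    features: pd.DataFrame,
    phases: Sequence[str] | None = None,
    periods: tuple[int, int] | None = None,
    regressors: Sequence[str] = INTERACTION_REGRESSORS,
    drop_boundary: bool = False,
    estimator: str = "ols",
    cluster_col: str = "pair_id",
) -> RegressionResult:
    """Fit the CHANGE regression on a phase subset with pair-clustered errors.

    Parameters
    ----------
    features:
        Coded feature table from :func:`contestlearn.features.code_features`.
    phases / periods:
        Optional row filters (phase labels, or an inclusive 1-based period
        window such as ``(1, 25)``).
    regressors:
        Design columns; colon-separated names are products of the two parts.
    drop_boundary:
        Drop rows whose previous own action sat on an action bound (there the
        direction of change is mechanically one-sided).
    estimator:
        ``"ols"`` (linear probability model) or ``"logit"`` (robustness).
    """
    if estimator not in ("ols", "logit"):
        raise ConfigError(f"unknown estimator {estimator!r}")
    table = _subset_phase(features, phases, periods)
    if drop_boundary:
        table = table[table["at_boundary"] == 0]
    if table.empty:
        raise EstimationError("empty feature subset: nothing to estimate")

    groups = table[cluster_col].to_numpy()
    n_clusters = len(np.unique(groups))
    if n_clusters < 2:
        raise EstimationError(f"need >= 2 clusters, got {n_clusters}")

    y = table["change"].to_numpy(dtype=float)
    X = _interaction_columns(table, regressors)
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns: ones whose removal restores full rank
        collinear = []
        for col in X.columns:
            if col == "const":
                continue
            sub = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(col)
        raise EstimationError(f"rank-deficient design; collinear column(s): {collinear}")

    if estimator == "ols":
        model = sm.OLS(y, X)
    else:
        model = sm.Logit(y, X)
    res = model.fit(
        cov_type="cluster", cov_kwds={"groups": groups}, use_t=True, disp=0
    ) if estimator == "logit" else model.fit(
        cov_type="cluster", cov_kwds={"groups": groups}, use_t=True
    )

    if estimator == "ols":
        r2 = float(res.rsquared)
        fstat = float(res.fvalue)
    else:
        r2 = float(res.prsquared)
        fstat = float(np.nan)
    return RegressionResult(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        bse=pd.Series(np.asarray(res.bse), index=X.columns),
        cov=pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns),
        r_squared=r2,
        f_statistic=fstat,
        nobs=int(res.nobs),
        n_clusters=int(n_clusters),
        df_inference=float(res.df_resid_inference if hasattr(res, "df_resid_inference") else res.df_resid),
        estimator=estimator,
        sm_results=res,
    )


def wald_combination(
    result: RegressionResult, weights: Mapping[str, float] | Sequence[float]
) -> TestResult:
    """Wald test of a zero linear combination of coefficients.

    ``weights`` is either a full-length vector aligned with the coefficient
    order (constant first) or a name->weight mapping; unnamed coefficients
    get weight 0.  The statistic is the squared t ratio of the combination
    under the clustered covariance; for a single coefficient it reduces to
    (coef/se)^2.
    """
    names = list(result.params.index)
    if isinstance(weights, Mapping):
        w = np.zeros(len(names))
        for key, val in weights.items():
            if key not in names:
                raise ConfigError(f"unknown coefficient {key!r}; have {names}")
            w[names.index(key)] = val
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(names),):
            raise ConfigError(
                f"weight vector length {w.shape} does not match {len(names)} coefficients"
            )
    if not np.any(w):
        raise ConfigError("zero weight vector")
    tt = result.sm_results.t_test(w)
    stat = float(np.squeeze(tt.tvalue)) ** 2
    p = float(np.squeeze(tt.pvalue))
    return TestResult(
        method="wald", statistic=stat, pvalue=p, unit="coefficient", n=result.nobs
    )


# ---------------------------------------------------------------------------
# aggregate statistics
# ---------------------------------------------------------------------------

def _long_actions(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    parts = []
    for traj in trajectories:
        for k in range(2):
            parts.append(
                pd.DataFrame(
                    {
                        "treatment": traj.treatment,
                        "pair_id": traj.pair_id,
                        "subject_id": traj.subject_ids[k],
                        "period": np.arange(1, traj.horizon + 1),
                        "action": traj.actions[:, k],
                        "payoff_points": _game.cents_to_points(
                            traj.payoffs_cents[:, k], traj.params
                        ),
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def median_action_bins(
    trajectories: Sequence[Trajectory],
    small_bin: int = 5,
    small_until: int = 25,
    large_bin: int = 25,
) -> pd.DataFrame:
    """Median action per treatment in period bins (fine early, coarse late)."""
    long = _long_actions(trajectories)
    horizon = int(long["period"].max())
    edges = list(range(0, small_until, small_bin)) + list(
        range(small_until, horizon + large_bin, large_bin)
    )
    labels = [f"{lo + 1}-{min(hi, horizon)}" for lo, hi in zip(edges[:-1], edges[1:])]
    long = long.copy()
    long["bin"] = pd.cut(long["period"], bins=edges, labels=labels)
    out = (
        long.groupby(["treatment", "bin"], observed=True)["action"]
        .median()
        .rename("median_action")
        .reset_index()
    )
    starts = {lab: int(lab.split("-")[0]) for lab in labels}
    out["bin_start"] = out["bin"].map(starts)
    return out.sort_values(["treatment", "bin_start"]).reset_index(drop=True)


def phase_summary(
    trajectories: Sequence[Trajectory],
    cutoffs: tuple[int, int] = PHASE_CUTOFFS,
    level: str = "subject_period",
) -> pd.DataFrame:
    """Mean, s.d. and median of actions per treatment x phase.

    ``subject_period`` (default) pools all subject-period actions in the
    cell; ``pair`` first averages within pairs and summarizes pair means.
    """
    if level not in ("subject_period", "pair"):
        raise ConfigError(f"unknown level {level!r}")
    long = _long_actions(trajectories)
    long["phase"] = assign_phase(long["period"].to_numpy(), cutoffs)
    if level == "pair":
        long = (
            long.groupby(["treatment", "phase", "pair_id"], observed=True)["action"]
            .mean()
            .reset_index()
        )
    out = (
        long.groupby(["treatment", "phase"], observed=True)["action"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), median="median", n="count")
        .reset_index()
    )
    order = {"naive": 0, "learning": 1, "longrun": 2}
    return out.sort_values(["treatment", "phase"], key=lambda s: s.map(order).fillna(s)).reset_index(drop=True)


def _pair_stat(
    trajectories: Sequence[Trajectory],
    phase: str,
    cutoffs: tuple[int, int],
    stat: str,
    unit: str,
) -> pd.DataFrame:
    long = _long_actions(trajectories)
    long["phase"] = assign_phase(long["period"].to_numpy(), cutoffs)
    long = long[long["phase"] == phase]
    if long.empty:
        raise TestError(f"no observations in phase {phase!r}")
    group_cols = ["treatment", "pair_id"] if unit == "pair" else [
        "treatment",
        "pair_id",
        "subject_id",
    ]
    agg = long.groupby(group_cols, observed=True)["action"]
    series = agg.median() if stat == "median" else agg.mean()
    return series.rename("value").reset_index()


def mann_whitney_treatments(
    trajectories: Sequence[Trajectory],
    phase: str,
    treatments: tuple[str, str] = ("NoInfo", "Info"),
    cutoffs: tuple[int, int] = PHASE_CUTOFFS,
    unit: str = "pair",
    stat: str = "median",
) -> TestResult:
    """Two-sided Mann-Whitney U comparing treatments on per-unit actions.

    The default unit is the pair (the independent observation) and the
    per-unit statistic is the median action within the phase.
    """
    if unit not in ("pair", "subject"):
        raise ConfigError(f"unknown unit {unit!r}")
    table = _pair_stat(trajectories, phase, cutoffs, stat, unit)
    a = table.loc[table["treatment"] == treatments[0], "value"].to_numpy()
    b = table.loc[table["treatment"] == treatments[1], "value"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise TestError(
            f"need >= 2 units per treatment, got {len(a)} and {len(b)}"
        )
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        method="mann_whitney_u",
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        unit=unit,
        n=len(a) + len(b),
    )


def t_test_vs_nash(
    trajectories: Sequence[Trajectory],
    treatment: str,
    phase: str,
    nash: float | None = None,
    cutoffs: tuple[int, int] = PHASE_CUTOFFS,
    unit: str = "pair",
) -> TestResult:
    """Two-sided one-sample t test of per-unit mean actions against Nash."""
    if unit not in ("pair", "subject"):
        raise ConfigError(f"unknown unit {unit!r}")
    if nash is None:
        nash = _game.nash_action(trajectories[0].params)
    table = _pair_stat(trajectories, phase, cutoffs, "mean", unit)
    x = table.loc[table["treatment"] == treatment, "value"].to_numpy()
    if len(x) < 2:
        raise TestError(f"need >= 2 units in treatment {treatment!r}, got {len(x)}")
    if np.allclose(x, x[0]):
        if np.isclose(x[0], nash):
            return TestResult("t_one_sample", 0.0, 1.0, unit, len(x))
        raise TestError("zero variance in per-unit means away from the null")
    res = scipy.stats.ttest_1samp(x, nash)
    return TestResult(
        method="t_one_sample",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        unit=unit,
        n=len(x),
    )


def earnings(
    trajectories: Sequence[Trajectory],
    phase: str | None = None,
    cutoffs: tuple[int, int] = PHASE_CUTOFFS,
    show_up_euro: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject euro earnings within a phase, and treatment medians.

    Earnings are summed lab points divided by the points-per-euro conversion;
    a show-up fee is added only when session payouts are reported.
    """
    long = _long_actions(trajectories)
    if phase is not None:
        long["phase"] = assign_phase(long["period"].to_numpy(), cutoffs)
        long = long[long["phase"] == phase]
    divisor = trajectories[0].params.points_per_euro
    per_subject = (
        long.groupby(["treatment", "pair_id", "subject_id"], observed=True)[
            "payoff_points"
        ]
        .sum()
        .rename("points")
        .reset_index()
    )
    per_subject["euro"] = per_subject["points"] / divisor + show_up_euro
    medians = per_subject.groupby("treatment", observed=True)["euro"].median()
    return per_subject, medians
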