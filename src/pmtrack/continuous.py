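"""Time-continuous regression of movement measures on trial predictors.

The two-stage random-effects scheme standard in mouse-tracking research:

1. per participant and per time step, an ordinary least-squares regression
   of the dependent measure (angle or speed) across that participant's
   trials on effect-coded predictors (−1/+1) plus an intercept, keeping the
   slope coefficients ("beta weights");
2. per time step, a two-sided one-sample t-test of the participants' betas
   against zero (df = n − 1);
3. reporting only maximal runs of at least ``min_run`` consecutive steps
   with p < α, signed by the group-mean beta (runs with mixed beta signs
   are split at the sign change).

Dependent series have 99 steps (differences of 100 normalized positions);
step k is the measure between positions k and k+1, so reported segment
bounds live on the 1..99 difference grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .config import COND_OT_ONLY, COND_PM_REPETITION, PHASE_FINISHED
from .kinematics import MeasureSet

__all__ = [
    "BetaSeries",
    "ContinuousResult",
    "effect_code",
    "fit_participant_betas",
    "group_level_test",
    "find_segments",
    "TimeContinuousRegression",
    "run_aftereffects_continuous",
    "run_costs_continuous",
]

#: effect codes of the two-level factors (positive level first)
TRIAL_TYPE_CODES = {"pm_repeated": 1.0, "oddball": -1.0}
CONDITION_CODES = {COND_PM_REPETITION: 1.0, COND_OT_ONLY: -1.0}


@dataclass
class BetaSeries:
    """Per-participant beta weights and group-level test for one predictor."""

    predictor: str
    per_participant_betas: np.ndarray  # (n_participants, n_steps)
    group_t: np.ndarray  # (n_steps,)
    group_p: np.ndarray  # (n_steps,)
    segments: list[tuple[int, int, str]]  # (start, end, "positive"|"negative"), 1-based

    @property
    def mean_beta(self) -> np.ndarray:
        return self.per_participant_betas.mean(axis=0)


@dataclass
class ContinuousResult:
    """All beta series of one time-continuous regression analysis."""

    dependent: str  # "angle" | "speed"
    beta_series: dict[str, BetaSeries]
    n_participants: int
    alpha: float
    min_run: int
    participants: list[str] = field(default_factory=list)

    def segments_table(self) -> pd.DataFrame:
        rows = [
            {
                "dependent": self.dependent,
                "predictor": name,
                "start": s,
                "end": e,
                "sign": sign,
            }
            for name, bs in self.beta_series.items()
            for (s, e, sign) in bs.segments
        ]
        return pd.DataFrame(rows, columns=["dependent", "predictor", "start", "end", "sign"])


def effect_code(trials: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Effect-coded (−1/+1) design columns for the requested predictors.

    Supported predictor names: ``trial_type`` (PM_REPEATED = +1, oddball =
    −1), ``condition`` (PM-task repetition = +1, ongoing-task only = −1) and
    ``interaction`` (their product).
    """
    cols = []
    for name in predictors:
        if name == "trial_type":
            cols.append(trials["trial_type"].map(TRIAL_TYPE_CODES).to_numpy(float))
        elif name == "condition":
            cols.append(trials["condition"].map(CONDITION_CODES).to_numpy(float))
        elif name == "interaction":
            tt = trials["trial_type"].map(TRIAL_TYPE_CODES).to_numpy(float)
            cc = trials["condition"].map(CONDITION_CODES).to_numpy(float)
            cols.append(tt * cc)
        else:
            raise ValueError(f"unknown predictor {name!r}")
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("trials outside the coded factor levels in the design")
    return X


def fit_participant_betas(
    y: np.ndarray, X: np.ndarray, participant: str = "?"
) -> np.ndarray:
    """Per-step OLS slopes for one participant.

    ``y`` is (n_trials, n_steps), ``X`` the (n_trials, p) effect-coded
    predictor matrix without intercept (added internally).  Returns the
    (n_steps, p) slope matrix.  Raises on rank-deficient designs.
    """
    n = X.shape[0]
    Xi = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
        raise ValueError(
            f"participant {participant!r}: rank-deficient design "
            f"(collinear or constant predictors)"
        )
    coef, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    return coef[1:].T  # drop the intercept row -> (n_steps, p)


def group_level_test(betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided one-sample t-test of per-participant betas against zero.

    ``betas`` is (n_participants, n_steps); returns (t, p) per step.  Steps
    with zero between-participant variance get p = 0 when the mean differs
    from zero and p = 1 otherwise (logged).
    """
    n = betas.shape[0]
    if n < 3:
        raise ValueError("group-level test needs >= 3 participants")
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} step(s) with zero between-participant variance",
            stacklevel=2,
        )
        t[degenerate] = np.where(mean[degenerate] != 0, np.inf, 0.0)
        p[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
    return t, p


def find_segments(
    group_p: np.ndarray,
    beta_means: np.ndarray,
    alpha: float = 0.05,
    min_run: int = 10,
) -> list[tuple[int, int, str]]:
    """Maximal runs of ≥ ``min_run`` consecutive significant steps.

    Runs are defined on ``p < alpha``; a run is signed by its mean beta, and
    runs containing a beta-sign change are split at the change (a mixed-sign
    run is uninterpretable as one effect).  Steps with mean beta ≥ 0 count
    as positive.  Returned bounds are 1-based and inclusive on the
    difference-step grid.
    """
    group_p = np.asarray(group_p)
    beta_means = np.asarray(beta_means)
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    sig = group_p < alpha
    sign = np.where(beta_means >= 0, 1, -1)
    segments: list[tuple[int, int, str]] = []
    i = 0
    k = len(sig)
    while i < k:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < k and sig[j + 1]:
            j += 1
        # split [i, j] at sign changes
        s = i
        while s <= j:
            e = s
            while e + 1 <= j and sign[e + 1] == sign[s]:
                e += 1
            if e - s + 1 >= min_run:
                segments.append((s + 1, e + 1, "positive" if sign[s] > 0 else "negative"))
            s = e + 1
        i = j + 1
    return segments


class TimeContinuousRegression(BaseEstimator):
    """Two-stage per-timestep regression with consecutive-run segments.

    Parameters
    ----------
    dependent:
        ``"angle"`` or ``"speed"``.
    predictors:
        subset of ``["trial_type", "condition", "interaction"]``.
    alpha, min_run:
        significance level and consecutive-step threshold of the segment
        rule.

    Fitted attributes
    -----------------
    results_ : dict mapping predictor name to :class:`BetaSeries`;
    n_participants_, participants_.
    """

    def __init__(
        self,
        dependent: str = "angle",
        predictors: tuple[str, ...] = ("trial_type",),
        alpha: float = 0.05,
        min_run: int = 10,
    ):
        self.dependent = dependent
        self.predictors = predictors
        self.alpha = alpha
        self.min_run = min_run

    def fit(self, trials: pd.DataFrame, measures: MeasureSet):
        """Fit on an analysis trial table and its kinematic measures."""
        if self.dependent not in ("angle", "speed"):
            raise ValueError("dependent must be 'angle' or 'speed'")
        merged = measures.merged_with(trials)
        dep_cols = [
            c for c in merged.columns if c.startswith(f"{self.dependent}_")
        ]
        dep_cols.sort()
        pids = sorted(merged["participant_id"].unique())
        betas = {name: [] for name in self.predictors}
        for pid in pids:
            g = merged[merged["participant_id"] == pid]
            X = effect_code(g, list(self.predictors))
            if any((X[:, j] == X[0, j]).all() for j in range(X.shape[1])):
                raise ValueError(
                    f"participant {pid!r}: a predictor is constant over their trials"
                )
            B = fit_participant_betas(g[dep_cols].to_numpy(float), X, participant=pid)
            for j, name in enumerate(self.predictors):
                betas[name].append(B[:, j])
        self.participants_ = pids
        self.n_participants_ = len(pids)
        self.results_ = {}
        for name in self.predictors:
            mat = np.vstack(betas[name])
            t, p = group_level_test(mat)
            segs = find_segments(p, mat.mean(axis=0), self.alpha, self.min_run)
            self.results_[name] = BetaSeries(
                predictor=name,
                per_participant_betas=mat,
                group_t=t,
                group_p=p,
                segments=segs,
            )
        return self

    def result(self) -> ContinuousResult:
        return ContinuousResult(
            dependent=self.dependent,
            beta_series=self.results_,
            n_participants=self.n_participants_,
            alpha=self.alpha,
            min_run=self.min_run,
            participants=self.participants_,
        )


AFTEREFFECT_SCOPES = (COND_OT_ONLY, COND_PM_REPETITION, "both_with_interaction")


def run_aftereffects_continuous(
    trials: pd.DataFrame,
    measures: MeasureSet,
    condition_scope: str = COND_OT_ONLY,
    alpha: float = 0.05,
    min_run: int = 10,
) -> dict[str, ContinuousResult]:
    """Aftereffects regressions (PM_REPEATED vs. oddball) on angle and speed.

    ``condition_scope`` restricts to one finished-phase condition with trial
    type as the sole predictor, or ``"both_with_interaction"`` for the full
    model with trial type, condition and their product.  ``trials`` must be
    the preprocessed aftereffects trial set.
    """
    if condition_scope not in AFTEREFFECT_SCOPES:
        raise ValueError(f"condition_scope must be one of {AFTEREFFECT_SCOPES}")
    if condition_scope == "both_with_interaction":
        subset = trials
        predictors = ("trial_type", "condition", "interaction")
    else:
        subset = trials[trials["condition"] == condition_scope]
        predictors = ("trial_type",)
    out = {}
    for dep in ("angle", "speed"):
        est = TimeContinuousRegression(dep, predictors, alpha, min_run)
        est.fit(subset, measures)
        out[dep] = est.result()
    return out


def run_costs_continuous(
    trials: pd.DataFrame,
    measures: MeasureSet,
    alpha: float = 0.05,
    min_run: int = 10,
) -> dict[str, ContinuousResult]:
    """Costs regressions (condition contrast) on finished-phase standards."""
    out = {}
    for dep in ("angle", "speed"):
        est = TimeContinuousRegression(dep, ("condition",), alpha, min_run)
        est.fit(trials, measures)
        out[dep] = est.result()
    return out
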