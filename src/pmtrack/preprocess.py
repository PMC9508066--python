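"""Trial exclusions and trajectory time-normalization.

Two analysis trial sets are defined on finished phases:

* ``aftereffects`` — PM_REPEATED vs. oddball trials;
* ``costs`` — standard trials, excluding the single standard trial
  immediately following any cue-bearing trial (those reflect post-deviant
  slowing rather than baseline ongoing-task performance).

Both sets then drop erroneous ongoing-task responses, commission errors and
timeout trials, and finally RT outliers beyond 3 SDs of the participant's
cell mean (per trial type and condition).

Raw trajectories are resampled by linear interpolation at 100 equally spaced
time points spanning the response stage, recentered so the horizontal start
coordinate is 0 (negative x = toward the ongoing-task boxes, positive x =
toward the PM box) and flipped to upward-positive y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import PHASE_FINISHED, SYMBOL_TRIAL_TYPES, ExperimentConfig
from .io import TRIAL_KEY, RawTrajectory

ANALYSES = ("aftereffects", "costs")


@dataclass
class ExclusionReport:
    """Per-participant exclusion counts for one analysis trial set."""

    table: pd.DataFrame  # one row per participant

    def overall_fraction(self, column: str) -> float:
        tab = self.table
        return float(tab[column].sum() / tab["n_total"].sum()) if len(tab) else 0.0


def mark_post_deviant(trials: pd.DataFrame) -> pd.Series:
    """True for standard trials immediately following a cue-bearing trial.

    Evaluated within each (participant, cycle, phase) block in trial order,
    so the result does not depend on the row order of the input table.
    """
    df = trials.sort_values(TRIAL_KEY + ["phase"], kind="mergesort")
    prev_type = df.groupby(["participant_id", "cycle", "phase"], sort=False)[
        "trial_type"
    ].shift(1)
    mark = (df["trial_type"] == "standard") & prev_type.isin(SYMBOL_TRIAL_TYPES)
    return mark.reindex(trials.index)


def select_analysis_trials(
    trials: pd.DataFrame,
    analysis: str,
    with_outlier_removal: bool = True,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Select the finished-phase trials entering one analysis.

    Returns the included trials and a per-participant exclusion report.
    Exclusion order follows the published pipeline: post-deviant standards
    (costs only), then ongoing-task errors, commission errors and timeouts,
    then the 3-SD RT outlier rule computed on the surviving trials.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")
    fin = trials[trials["phase"] == PHASE_FINISHED]
    if analysis == "aftereffects":
        pool = fin[fin["trial_type"].isin(["pm_repeated", "oddball"])]
        n_post = pd.Series(0, index=pool.index, dtype=bool)
    else:
        std = fin[fin["trial_type"] == "standard"]
        post = mark_post_deviant(fin).reindex(std.index).fillna(False)
        pool = std
        n_post = post

    err = ~pool["correct"] & ~pool["commission_error"] & (pool["timeout_flag"] == "none")
    com = pool["commission_error"].astype(bool)
    tmo = pool["timeout_flag"] != "none"
    keep = ~(n_post | err | com | tmo)
    included = pool[keep]

    if with_outlier_removal:
        included, outlier_mask = remove_rt_outliers(included)
    else:
        outlier_mask = pd.Series(False, index=included.index)

    per = pool.groupby("participant_id", sort=True)
    report = pd.DataFrame(
        {
            "n_total": per.size(),
            "n_post_deviant_excluded": n_post.groupby(pool["participant_id"]).sum(),
            "n_error_excluded": err.groupby(pool["participant_id"]).sum(),
            "n_commission_excluded": com.groupby(pool["participant_id"]).sum(),
            "n_timeout_excluded": tmo.groupby(pool["participant_id"]).sum(),
            "n_outlier_excluded": outlier_mask.groupby(
                pool.loc[outlier_mask.index, "participant_id"]
            ).sum(),
        }
    ).fillna(0)
    for col in report.columns:
        report[col] = report[col].astype(int)
        if col != "n_total":
            report[f"frac_{col[2:].removesuffix('_excluded')}"] = (
                report[col] / report["n_total"]
            )
    return included.reset_index(drop=True), ExclusionReport(report.reset_index())


def remove_rt_outliers(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Single-pass 3-SD RT outlier removal per (participant, type, condition).

    Cell means/SDs (sample SD) are computed over the cell before removal;
    cells with fewer than two trials are left untouched.  Returns the
    surviving trials and the boolean outlier mask over the input index.
    """
    mask = pd.Series(False, index=trials.index)
    grouped = trials.groupby(["participant_id", "trial_type", "condition"], sort=False)
    for _, g in grouped:
        rt = g["rt_ms"]
        if len(g) < 2:
            continue
        mu, sd = rt.mean(), rt.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        mask.loc[g.index] = (rt - mu).abs() > 3.0 * sd
    return trials[~mask], mask


@dataclass
class NormalizedTrajectories:
    """Time-normalized, recentered trajectories of a set of trials.

    ``xc``/``yu`` are (n_trials, n_steps) arrays: x minus the horizontal
    start coordinate (positive = PM side), and upward-positive y.  ``keys``
    aligns rows with trials.
    """

    keys: pd.DataFrame  # participant_id, cycle, trial_index
    xc: np.ndarray
    yu: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.keys) == len(self.xc) == len(self.yu)):
            raise ValueError("keys, xc, yu must align")

    @property
    def n_steps(self) -> int:
        return self.xc.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (trial, step)."""
        n, k = self.xc.shape
        rep = self.keys.loc[self.keys.index.repeat(k)].reset_index(drop=True)
        rep["step"] = np.tile(np.arange(1, k + 1), n)
        rep["x_c"] = self.xc.ravel()
        rep["y_u"] = self.yu.ravel()
        return rep

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormalizedTrajectories":
        df = df.sort_values(TRIAL_KEY + ["step"], kind="mergesort")
        n_steps = df["step"].max()
        keys = df.loc[df["step"] == 1, TRIAL_KEY].reset_index(drop=True)
        xc = df["x_c"].to_numpy().reshape(len(keys), n_steps)
        yu = df["y_u"].to_numpy().reshape(len(keys), n_steps)
        return cls(keys=keys, xc=xc, yu=yu)


def time_normalize(raw: RawTrajectory, config: ExperimentConfig) -> tuple[np.ndarray, np.ndarray]:
    """Resample one trajectory to ``n_norm_steps`` equal time steps.

    Linear interpolation of x and y at equally spaced query times spanning
    [t_first, t_last]; endpoints are preserved exactly.  Returns recentered
    ``x_c = x - start_x`` and upward-positive ``y_u = screen_h - y``.
    """
    if raw.n_samples < 2:
        raise ValueError("cannot normalize a single-sample trajectory")
    tq = np.linspace(raw.t[0], raw.t[-1], config.n_norm_steps)
    x = np.interp(tq, raw.t, raw.x)
    y = np.interp(tq, raw.t, raw.y)
    return x - config.start_x, config.screen_h - y


class TrajectoryNormalizer(TransformerMixin, BaseEstimator):
    """Transformer mapping raw trajectories to normalized, recentered paths.

    Stateless (``fit`` only validates parameters); composes with sklearn
    pipelines operating on lists of :class:`~pmtrack.io.RawTrajectory`.
    """

    def __init__(self, config: ExperimentConfig | None = None):
        self.config = config

    def fit(self, X, y=None):
        cfg = self.config or ExperimentConfig()
        if cfg.n_norm_steps < 3:
            raise ValueError("n_norm_steps must be >= 3")
        self.config_ = cfg
        self.n_steps_ = cfg.n_norm_steps
        return self

    def transform(self, X: list[RawTrajectory]) -> NormalizedTrajectories:
        if not hasattr(self, "config_"):
            self.fit(X)
        cfg = self.config_
        n = len(X)
        xc = np.empty((n, cfg.n_norm_steps))
        yu = np.empty((n, cfg.n_norm_steps))
        keys = []
        for i, raw in enumerate(X):
            xc[i], yu[i] = time_normalize(raw, cfg)
            keys.append(raw.key)
        return NormalizedTrajectories(
            keys=pd.DataFrame(keys, columns=TRIAL_KEY), xc=xc, yu=yu
        )


def normalize_trajectories(
    trajectories: list[RawTrajectory], config: ExperimentConfig | None = None
) -> NormalizedTrajectories:
    """Functional wrapper over :class:`TrajectoryNormalizer`."""
    return TrajectoryNormalizer(config=config).fit(trajectories).transform(trajectories)
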