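"""Movement measures: signed AUC curvature, movement angles, and speed.

Sign convention, shared by all measures and downstream regression betas:
rightward / PM-box-ward is positive, leftward / ongoing-task-ward negative.

* **AUC** — signed area (px²) between the normalized path and the straight
  chord from its first to its last point; deviation toward the PM side
  counts positive.  z-scored per participant over the trials of the
  compared conditions (population-SD convention).
* **Angle** — per step, the angle between the step's displacement vector
  and the vertical axis, ``atan2(Δx, Δy)``; standardized to [-1, 1] by
  clamping to ±90° and dividing by 90 (a per-participant max-|angle|
  rescaling is available as an option).  Purely upward motion gives 0.
* **Speed** — per step, the magnitude of the displacement vector, in px per
  normalized time step.

A 100-point path yields 99 step values; step k lies between positions k and
k+1 of the normalized path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import TRIAL_KEY
from .preprocess import NormalizedTrajectories

__all__ = [
    "compute_auc",
    "compute_angles",
    "compute_speed",
    "zscore_auc",
    "KinematicFeatures",
    "MeasureSet",
    "compute_measures",
]


def compute_auc(xc: np.ndarray, yu: np.ndarray) -> np.ndarray:
    """Signed area between each path and its first-to-last chord (px²).

    ``xc``/``yu`` are (n_trials, n_steps) or (n_steps,) arrays in recentered,
    upward-positive coordinates.  Computed by the shoelace formula on the
    polygon formed by the path closed with the chord; for an upward movement
    a rightward (PM-side) bulge is positive.  Degenerate paths whose first
    and last points coincide have no chord and return 0 with a warning.
    """
    xc = np.atleast_2d(np.asarray(xc, dtype=float))
    yu = np.atleast_2d(np.asarray(yu, dtype=float))
    x2 = np.roll(xc, -1, axis=1)
    y2 = np.roll(yu, -1, axis=1)
    area = 0.5 * np.sum(xc * y2 - x2 * yu, axis=1)
    degenerate = (xc[:, 0] == xc[:, -1]) & (yu[:, 0] == yu[:, -1])
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate path(s) with coinciding endpoints; "
            "AUC set to 0",
            stacklevel=2,
        )
        area[degenerate] = 0.0
    return area if area.size > 1 else area.reshape(-1)


def _step_diffs(xc: np.ndarray, yu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xc = np.atleast_2d(np.asarray(xc, dtype=float))
    yu = np.atleast_2d(np.asarray(yu, dtype=float))
    return np.diff(xc, axis=1), np.diff(yu, axis=1)


def compute_angles(xc: np.ndarray, yu: np.ndarray) -> np.ndarray:
    """Standardized per-step movement angles in [-1, 1].

    The raw angle is ``atan2(Δx, Δy)`` in degrees (0 = straight up,
    positive = toward the PM box), clamped to ±90° and divided by 90.
    Zero-length steps inherit the previous step's angle (leading zero-length
    steps take the first defined angle); a path of only zero-length steps
    raises.
    """
    dx, dy = _step_diffs(xc, yu)
    zero = (dx == 0.0) & (dy == 0.0)
    if np.any(zero.all(axis=1)):
        raise ValueError("trajectory with all zero-length steps has no angles")
    theta = np.degrees(np.arctan2(dx, dy))
    theta = np.clip(theta, -90.0, 90.0) / 90.0
    if zero.any():
        n, k = theta.shape
        idx = np.where(zero, 0, np.arange(k))
        np.maximum.accumulate(idx, axis=1, out=idx)
        theta = theta[np.arange(n)[:, None], idx]
        # leading zero-length steps: backfill from the first moving step
        lead = zero & (np.cumsum(~zero, axis=1) == 0)
        if lead.any():
            first = (~zero).argmax(axis=1)
            for i in np.flatnonzero(lead.any(axis=1)):
                theta[i, : first[i]] = theta[i, first[i]]
    return theta


def compute_speed(xc: np.ndarray, yu: np.ndarray) -> np.ndarray:
    """Per-step movement speed: |displacement| in px per normalized step."""
    dx, dy = _step_diffs(xc, yu)
    return np.hypot(dx, dy)


def zscore_auc(
    trials: pd.DataFrame, auc_column: str = "auc", ddof: int = 0
) -> pd.Series:
    """Per-participant z-scores of AUC over the supplied comparison set.

    The input frame should already be restricted to the union of the
    compared cells (PM_REPEATED ∪ oddball for aftereffects; standard trials
    of both conditions for costs).  Population-SD convention by default
    (``ddof=0``); a participant with zero AUC variance raises.
    """
    out = pd.Series(np.nan, index=trials.index, dtype=float)
    for pid, g in trials.groupby("participant_id"):
        sd = g[auc_column].std(ddof=ddof)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"participant {pid!r}: zero AUC variance, cannot z-score")
        out.loc[g.index] = (g[auc_column] - g[auc_column].mean()) / sd
    return out


@dataclass
class MeasureSet:
    """Per-trial movement measures aligned with a trial key table."""

    keys: pd.DataFrame  # participant_id, cycle, trial_index
    auc: np.ndarray  # (n_trials,)
    angle: np.ndarray  # (n_trials, n_steps - 1)
    speed: np.ndarray  # (n_trials, n_steps - 1)

    @property
    def n_steps(self) -> int:
        return self.angle.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: auc plus angle_01..k and speed_01..k columns."""
        k = self.n_steps
        cols = {"auc": self.auc}
        cols.update({f"angle_{j + 1:02d}": self.angle[:, j] for j in range(k)})
        cols.update({f"speed_{j + 1:02d}": self.speed[:, j] for j in range(k)})
        return pd.concat(
            [self.keys.reset_index(drop=True), pd.DataFrame(cols)], axis=1
        )

    def merged_with(self, trials: pd.DataFrame) -> pd.DataFrame:
        """Inner-join trial metadata onto the measures (key-aligned)."""
        return trials.merge(self.to_frame(), on=TRIAL_KEY, how="inner", validate="1:1")


class KinematicFeatures(TransformerMixin, BaseEstimator):
    """Transformer computing AUC, angle and speed from normalized paths.

    Parameters
    ----------
    angle_standardization:
        ``"fixed"`` (default) clamps angles to ±90° and divides by 90;
        ``"participant_max"`` divides each participant's clamped angles by
        that participant's maximum absolute clamped angle, an alternative
        reading of per-participant standardization.
    """

    def __init__(self, angle_standardization: str = "fixed"):
        self.angle_standardization = angle_standardization

    def fit(self, X, y=None):
        if self.angle_standardization not in ("fixed", "participant_max"):
            raise ValueError("angle_standardization must be 'fixed' or 'participant_max'")
        return self

    def transform(self, X: NormalizedTrajectories) -> MeasureSet:
        self.fit(X)
        angle = compute_angles(X.xc, X.yu)
        if self.angle_standardization == "participant_max":
            pid = X.keys["participant_id"].to_numpy()
            for p in np.unique(pid):
                rows = pid == p
                peak = np.abs(angle[rows]).max()
                if peak > 0:
                    angle[rows] = angle[rows] / peak
        return MeasureSet(
            keys=X.keys.copy(),
            auc=compute_auc(X.xc, X.yu),
            angle=angle,
            speed=compute_speed(X.xc, X.yu),
        )


def compute_measures(
    normalized: NormalizedTrajectories, angle_standardization: str = "fixed"
) -> MeasureSet:
    """Functional wrapper over :class:`KinematicFeatures`."""
    return KinematicFeatures(angle_standardization).fit(normalized).transform(normalized)
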