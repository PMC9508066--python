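"""Reading, writing and validating the package's on-disk tables.

Two CSV layouts are used throughout:

``trials.csv``
    one row per behavioral trial with columns ``participant_id, cycle, phase,
    condition, trial_index, trial_type, digit, symbol_id, chosen_box,
    correct, commission_error, rt_ms, timeout_flag``.

``trajectories.csv``
    long format, one cursor sample per row, columns ``participant_id, cycle,
    trial_index, t_ms, x_px, y_px``; only response-stage samples are stored,
    in raw screen coordinates (origin top-left, y downward).

A trial is keyed by ``(participant_id, cycle, trial_index)`` with
``trial_index`` 1-based within its phase block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    BOX_IDS,
    CONDITIONS,
    PHASES,
    TIMEOUT_FLAGS,
    TRIAL_TYPES,
    COND_OT_ONLY,
    PHASE_FINISHED,
    ExperimentConfig,
)

TRIAL_COLUMNS = [
    "participant_id",
    "cycle",
    "phase",
    "condition",
    "trial_index",
    "trial_type",
    "digit",
    "symbol_id",
    "chosen_box",
    "correct",
    "commission_error",
    "rt_ms",
    "timeout_flag",
]

TRAJECTORY_COLUMNS = ["participant_id", "cycle", "trial_index", "t_ms", "x_px", "y_px"]

TRIAL_KEY = ["participant_id", "cycle", "trial_index"]


@dataclass
class RawTrajectory:
    """Timestamped cursor samples of one trial's response stage."""

    participant_id: str
    cycle: int
    trial_index: int
    t: np.ndarray  # ms, strictly increasing
    x: np.ndarray  # px, screen convention
    y: np.ndarray  # px, screen convention (downward)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError(
                f"trajectory {self.key} needs >= 2 samples, got {len(self.t)}"
            )
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError(f"non-monotone or duplicate timestamps in trial {self.key}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.participant_id, self.cycle, self.trial_index)

    @property
    def n_samples(self) -> int:
        return len(self.t)


def _validate_trial_frame(df: pd.DataFrame, config: ExperimentConfig | None) -> None:
    for col, allowed in [
        ("phase", PHASES),
        ("condition", CONDITIONS),
        ("trial_type", TRIAL_TYPES),
        ("timeout_flag", TIMEOUT_FLAGS),
        ("chosen_box", BOX_IDS + ("none",)),
    ]:
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"row {row + 2}: invalid {col} {df[col].iloc[row]!r}"
            )  # +2: header line + 1-based
    bad_digit = ~df["digit"].between(2, 9)
    if bad_digit.any():
        row = int(np.flatnonzero(bad_digit.to_numpy())[0])
        raise ValueError(f"row {row + 2}: digit outside 2..9")
    # a commission error is, by definition, a PM-box entry on a trial showing
    # a no-longer-relevant or control cue
    com = df["commission_error"]
    bad_com = com & (
        ~df["trial_type"].isin(["pm_repeated", "oddball"]) | (df["chosen_box"] != "pm")
    )
    if bad_com.any():
        row = int(np.flatnonzero(bad_com.to_numpy())[0])
        raise ValueError(
            f"row {row + 2}: commission_error only valid for pm_repeated/oddball "
            "trials ending in the pm box"
        )
    bad_pm = (
        (df["phase"] == PHASE_FINISHED)
        & (df["condition"] == COND_OT_ONLY)
        & df["trial_type"].isin(["pm", "new_pm"])
    )
    if bad_pm.any():
        row = int(np.flatnonzero(bad_pm.to_numpy())[0])
        raise ValueError(
            f"row {row + 2}: pm/new_pm trials cannot occur in "
            "ongoing_task_only finished phases"
        )
    if config is not None:
        timed = df["timeout_flag"] == "none"
        bad_rt = timed & df["rt_ms"].notna() & (df["rt_ms"] > config.stage_timeout)
        if bad_rt.any():
            row = int(np.flatnonzero(bad_rt.to_numpy())[0])
            raise ValueError(
                f"row {row + 2}: rt_ms {df['rt_ms'].iloc[row]} exceeds "
                f"stage_timeout {config.stage_timeout} without a timeout flag"
            )


def read_trial_log(path, config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Returns a DataFrame with one row per trial (the package's TrialRecord
    container).  Raises ``ValueError`` naming the offending file line on
    malformed or inconsistent rows.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "symbol_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} lacks columns {missing}")
    df = df[TRIAL_COLUMNS].copy()
    if df.empty:
        return df
    for col in ("cycle", "trial_index", "digit"):
        df[col] = df[col].astype(int)
    for col in ("correct", "commission_error"):
        df[col] = df[col].astype(bool)
    df["rt_ms"] = df["rt_ms"].astype(float)
    df["symbol_id"] = df["symbol_id"].fillna("none")
    df["chosen_box"] = df["chosen_box"].fillna("none")
    _validate_trial_frame(df, config)
    return df


def write_trial_log(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def trajectories_to_frame(trajectories: list[RawTrajectory]) -> pd.DataFrame:
    """Stack RawTrajectory objects into the long CSV layout."""
    parts = []
    for tr in trajectories:
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "cycle": tr.cycle,
                    "trial_index": tr.trial_index,
                    "t_ms": tr.t,
                    "x_px": tr.x,
                    "y_px": tr.y,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[RawTrajectory]:
    """Group a long-format sample table into per-trial trajectories.

    Samples are sorted by time within each trial; duplicate timestamps raise.
    """
    out: list[RawTrajectory] = []
    for (pid, cyc, idx), g in df.groupby(TRIAL_KEY, sort=True):
        g = g.sort_values("t_ms")
        out.append(
            RawTrajectory(
                participant_id=str(pid),
                cycle=int(cyc),
                trial_index=int(idx),
                t=g["t_ms"].to_numpy(),
                x=g["x_px"].to_numpy(),
                y=g["y_px"].to_numpy(),
            )
        )
    return out


def read_trajectories(path) -> list[RawTrajectory]:
    """Read a long-format trajectory CSV into per-trial trajectories."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} lacks columns {missing}")
    return frame_to_trajectories(df)


def write_trajectories(trajectories: list[RawTrajectory], path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Report-only consistency check of a trial table + trajectory set."""

    missing_trajectory: list[tuple] = field(default_factory=list)
    orphan_trajectory: list[tuple] = field(default_factory=list)
    count_mismatch: list[str] = field(default_factory=list)
    endpoint_outside_box: list[tuple] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.missing_trajectory
            or self.orphan_trajectory
            or self.count_mismatch
            or self.endpoint_outside_box
        )

    def summary(self) -> str:
        if self.ok:
            return "dataset consistent"
        lines = []
        for name in (
            "missing_trajectory",
            "orphan_trajectory",
            "count_mismatch",
            "endpoint_outside_box",
        ):
            entries = getattr(self, name)
            if entries:
                lines.append(f"{name}: {len(entries)}")
                lines.extend(f"  {e}" for e in entries[:10])
        return "\n".join(lines)


def validate_dataset(
    trials: pd.DataFrame,
    trajectories: list[RawTrajectory],
    config: ExperimentConfig,
) -> ValidationReport:
    """Cross-check trials against trajectories and configured block counts."""
    report = ValidationReport()
    traj_keys = {tr.key: tr for tr in trajectories}
    trial_keys = set(map(tuple, trials[TRIAL_KEY].itertuples(index=False)))

    responded = trials[(trials["timeout_flag"] == "none") & (trials["chosen_box"] != "none")]
    for row in responded.itertuples(index=False):
        key = (row.participant_id, row.cycle, row.trial_index)
        tr = traj_keys.get(key)
        if tr is None:
            report.missing_trajectory.append(key)
        elif not config.in_box(row.chosen_box, tr.x[-1], tr.y[-1]):
            report.endpoint_outside_box.append(key + (row.chosen_box,))
    report.orphan_trajectory = sorted(set(traj_keys) - trial_keys)

    counts = (
        trials.groupby(["participant_id", "cycle", "phase", "condition", "trial_type"])
        .size()
        .reset_index(name="n")
    )
    for (pid, cyc, phase, cond), g in counts.groupby(
        ["participant_id", "cycle", "phase", "condition"]
    ):
        expected = config.block_counts(phase, cond)
        observed = dict(zip(g["trial_type"], g["n"]))
        if observed != expected:
            report.count_mismatch.append(
                f"{pid} cycle {cyc} {phase}/{cond}: expected {expected}, got {observed}"
            )
    return report
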