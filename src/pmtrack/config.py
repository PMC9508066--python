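"""Experiment configuration for the dynamic-start mouse-tracking paradigm.

The paradigm pairs a digit parity judgement (the ongoing task) with an
event-based prospective-memory (PM) task: on trials where a specific cue
symbol surrounds the digit, the cursor must be moved into a dedicated PM
response box instead of the parity boxes.  Each experimental cycle consists
of an *active* phase (PM task in force) and a *finished* phase (intention
declared complete), the latter run under one of two conditions:

* ``pm_task_repetition`` — a new PM task is active during the finished phase;
* ``ongoing_task_only`` — only the parity task is performed.

All geometry is expressed in screen pixels.  Raw cursor logs use the screen
convention (origin top-left, y growing downward); ``start_y`` and
``response_trigger_dy`` are distances from the *bottom* screen edge, matching
how the start procedure is described to participants.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import yaml

PHASE_ACTIVE = "active"
PHASE_FINISHED = "finished"
PHASES = (PHASE_ACTIVE, PHASE_FINISHED)

COND_PM_REPETITION = "pm_task_repetition"
COND_OT_ONLY = "ongoing_task_only"
CONDITIONS = (COND_PM_REPETITION, COND_OT_ONLY)

TRIAL_TYPES = ("standard", "pm", "oddball", "pm_repeated", "new_pm")
#: trial types in which a cue symbol surrounds the digit
SYMBOL_TRIAL_TYPES = ("pm", "oddball", "pm_repeated", "new_pm")
#: trial types whose correct response is the PM box
PM_RESPONSE_TRIAL_TYPES = ("pm", "new_pm")

BOX_IDS = ("ot_odd", "ot_even", "pm")
TIMEOUT_FLAGS = ("none", "start", "response", "reset")

_DEFAULT_TRIAL_COUNTS: dict[str, dict[str, int]] = {
    # active phases are identical in both conditions
    "active": {"standard": 40, "pm": 4, "oddball": 4},
    "finished/pm_task_repetition": {
        "standard": 40,
        "pm_repeated": 4,
        "oddball": 4,
        "new_pm": 4,
    },
    # two distinct oddball cues, four presentations each, keep the number of
    # deviant stimuli equal across conditions
    "finished/ongoing_task_only": {"standard": 40, "pm_repeated": 4, "oddball": 8},
}

# Response-box centroids in raw screen coordinates (y downward).  The parity
# boxes sit in the upper-left corner (upper box = odd, lower box = even), the
# PM box in the upper-right corner.
_DEFAULT_BOX_TARGETS: dict[str, tuple[float, float]] = {
    "ot_odd": (110.0, 90.0),
    "ot_even": (110.0, 260.0),
    "pm": (1170.0, 90.0),
}


@dataclass
class ExperimentConfig:
    """Geometry, timing and per-block trial counts of the paradigm."""

    screen_w: int = 1280
    screen_h: int = 1024
    start_x: int = 640
    start_y: int = 10  # distance of the start point from the bottom edge
    response_trigger_dy: int = 160  # upward travel that triggers the response stage
    stage_timeout: float = 1500.0  # ms per stage
    n_cycles: int = 12
    trial_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_TRIAL_COUNTS)
    )
    sample_rate: float = 100.0  # Hz
    n_norm_steps: int = 100
    box_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_BOX_TARGETS)
    )
    box_radius: float = 110.0  # containment radius around a box centroid, px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_norm_steps < 3:
            raise ValueError("n_norm_steps must be >= 3")
        if self.start_x != self.screen_w // 2:
            raise ValueError("start_x must equal screen_w / 2")
        if self.sample_rate <= 0 or self.stage_timeout <= 0:
            raise ValueError("sample_rate and stage_timeout must be positive")
        for block, counts in self.trial_counts.items():
            for ttype, n in counts.items():
                if ttype not in TRIAL_TYPES:
                    raise ValueError(f"unknown trial type {ttype!r} in block {block!r}")
                if n <= 0:
                    raise ValueError(f"count for {ttype!r} in block {block!r} must be > 0")
        missing = set(BOX_IDS) - set(self.box_targets)
        if missing:
            raise ValueError(f"box_targets missing entries for {sorted(missing)}")

    # -- derived geometry ---------------------------------------------------
    @property
    def dt_ms(self) -> float:
        """Sampling interval of the cursor stream in milliseconds."""
        return 1000.0 / self.sample_rate

    @property
    def response_start_raw(self) -> tuple[float, float]:
        """Raw-screen coordinates of the response-stage start point."""
        return (
            float(self.start_x),
            float(self.screen_h - self.start_y - self.response_trigger_dy),
        )

    def block_counts(self, phase: str, condition: str) -> dict[str, int]:
        """Trial counts for one phase block of a cycle in ``condition``."""
        key = "active" if phase == PHASE_ACTIVE else f"finished/{condition}"
        return dict(self.trial_counts[key])

    def block_length(self, phase: str, condition: str) -> int:
        return sum(self.block_counts(phase, condition).values())

    def in_box(self, box: str, x: float, y: float) -> bool:
        bx, by = self.box_targets[box]
        return (x - bx) ** 2 + (y - by) ** 2 <= self.box_radius**2

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "screen_w": self.screen_w,
            "screen_h": self.screen_h,
            "start_x": self.start_x,
            "start_y": self.start_y,
            "response_trigger_dy": self.response_trigger_dy,
            "stage_timeout": self.stage_timeout,
            "n_cycles": self.n_cycles,
            "trial_counts": copy.deepcopy(self.trial_counts),
            "sample_rate": self.sample_rate,
            "n_norm_steps": self.n_norm_steps,
            "box_targets": {k: list(v) for k, v in self.box_targets.items()},
            "box_radius": self.box_radius,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        if "box_targets" in d:
            d["box_targets"] = {k: tuple(v) for k, v in d["box_targets"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def correct_box(trial_type: str, digit: int) -> str:
    """The response box a correct response must reach for this stimulus."""
    if trial_type in PM_RESPONSE_TRIAL_TYPES:
        return "pm"
    return "ot_odd" if digit % 2 == 1 else "ot_even"
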