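"""Synthetic experiment generator for the dynamic-start PM paradigm.

Produces complete experiments — per-participant design schedules honoring the
paradigm's sequencing constraints, plus 100-Hz response-stage cursor
trajectories — with controllable, cell-specific effects so every downstream
analysis stage can be checked against known ground truth.

The generative model of a single response-stage movement:

* a minimum-jerk position profile from the response-stage start point to the
  (possibly erroneous) target box, the standard smooth-reach null model;
* a transient lateral velocity bias toward the PM box, shaped as a raised
  cosine over a normalized-time window, emulating partial intention
  retrieval (and, optionally, a compensatory bias of opposite sign later in
  the movement);
* a multiplicative slowing of movement progress over a late window,
  emulating a response-verification process;
* isotropic Gaussian positional noise per sample;
* log-normal response times truncated at the stage timeout;
* full capture into the PM box with probability ``p_commission`` on trials
  showing a deviant cue (a commission error / false alarm).

Between-participant heterogeneity is a shared log-normal multiplier on all
deflection and slowing amplitudes, which links a participant's deflection to
their subsequent slowing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import (
    COND_OT_ONLY,
    COND_PM_REPETITION,
    CONDITIONS,
    PHASE_ACTIVE,
    PHASE_FINISHED,
    SYMBOL_TRIAL_TYPES,
    ExperimentConfig,
    correct_box,
)
from .io import RawTrajectory

__all__ = [
    "EffectSpec",
    "ConditionEffects",
    "DesignError",
    "build_design",
    "simulate_trajectory",
    "simulate_experiment",
    "paper_like_effects",
    "null_effects",
]


class DesignError(ValueError):
    """Raised when the requested trial counts admit no valid sequence."""


def _lognormal_mu(mean_ms: float, sigma: float) -> float:
    """Log-scale location giving a log-normal with the requested mean."""
    return math.log(mean_ms) - sigma**2 / 2.0


@dataclass
class EffectSpec:
    """Trajectory and outcome effects for one design cell.

    Amplitudes are in pixels per normalized step (1/100 of the movement) for
    velocity biases, and dimensionless fractions for the slowing.  Windows
    are (start, end) fractions of normalized movement time.
    """

    deflect_amp: float = 0.0  # peak lateral velocity bias toward the PM box
    deflect_window: tuple[float, float] = (0.30, 0.60)
    return_amp: float = 0.0  # compensatory bias away from the PM box
    return_window: tuple[float, float] = (0.65, 0.95)
    slow_amp: float = 0.0  # 0 <= s < 1, multiplicative progress reduction
    slow_window: tuple[float, float] = (0.65, 0.95)
    rt_mu: float = _lognormal_mu(700.0, 0.22)  # log-scale ms
    rt_sigma: float = 0.22
    base_noise_sd: float = 4.0  # px, isotropic per sample
    p_commission: float = 0.0
    p_ongoing_error: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_commission, self.p_ongoing_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.deflect_amp < 0 or self.return_amp < 0:
            raise ValueError("velocity-bias amplitudes must be >= 0")
        if not 0.0 <= self.slow_amp < 1.0:
            raise ValueError("slow_amp must lie in [0, 1)")
        for a, b in (self.deflect_window, self.return_window, self.slow_window):
            if not (0.0 <= a < b <= 1.0):
                raise ValueError("windows must satisfy 0 <= start < end <= 1")

    @classmethod
    def from_mean_rt(cls, mean_rt_ms: float, rt_sigma: float = 0.22, **kw) -> "EffectSpec":
        return cls(rt_mu=_lognormal_mu(mean_rt_ms, rt_sigma), rt_sigma=rt_sigma, **kw)


@dataclass
class ConditionEffects:
    """Map from (phase, condition, trial_type) to an :class:`EffectSpec`."""

    specs: dict[tuple[str, str, str], EffectSpec]
    participant_sd: float = 0.4  # log-normal sigma of the shared amplitude multiplier
    rt_participant_sd: float = 0.12  # log-normal sigma of the RT multiplier

    def spec_for(self, phase: str, condition: str, trial_type: str) -> EffectSpec:
        try:
            return self.specs[(phase, condition, trial_type)]
        except KeyError:
            raise KeyError(
                f"no EffectSpec for cell (phase={phase!r}, condition={condition!r}, "
                f"trial_type={trial_type!r})"
            ) from None

    def validate_covers(self, config: ExperimentConfig) -> None:
        for cond in CONDITIONS:
            for phase in (PHASE_ACTIVE, PHASE_FINISHED):
                for ttype in config.block_counts(phase, cond):
                    self.spec_for(phase, cond, ttype)

    def zeroed(self) -> "ConditionEffects":
        """Copy with all trajectory effects removed (null data generator)."""
        return ConditionEffects(
            specs={
                k: replace(s, deflect_amp=0.0, return_amp=0.0, slow_amp=0.0)
                for k, s in self.specs.items()
            },
            participant_sd=self.participant_sd,
            rt_participant_sd=self.rt_participant_sd,
        )


def paper_like_effects() -> ConditionEffects:
    """Default effect preset emulating the published paradigm.

    Cell mean RTs follow the reported condition/trial-type means; commission
    and error probabilities follow the reported rates; deflection windows sit
    mid-movement (0.30-0.60) and slowing windows late (0.65-0.95), where the
    aftereffect signatures appear.  The finished-phase standard trials of the
    PM-task-repetition condition carry an early central-channel bias with a
    late compensatory return plus early slowing, emulating delayed, more
    careful responding under a new PM task (ongoing-task costs).
    """
    A, F = PHASE_ACTIVE, PHASE_FINISHED
    R, O = COND_PM_REPETITION, COND_OT_ONLY
    mk = EffectSpec.from_mean_rt
    specs: dict[tuple[str, str, str], EffectSpec] = {}
    # active phases (identical effects in both conditions)
    for cond in (R, O):
        specs[(A, cond, "standard")] = mk(676, p_ongoing_error=0.0303)
        specs[(A, cond, "pm")] = mk(828, p_ongoing_error=0.0556)
        specs[(A, cond, "oddball")] = mk(
            915, deflect_amp=0.6, slow_amp=0.08, p_ongoing_error=0.0987
        )
    # finished phase, PM-task-repetition condition
    specs[(F, R, "standard")] = mk(
        684,
        deflect_amp=0.9,
        deflect_window=(0.02, 0.40),
        return_amp=0.9,
        return_window=(0.60, 0.98),
        slow_amp=0.15,
        slow_window=(0.02, 0.55),
        p_ongoing_error=0.0268,
    )
    specs[(F, R, "pm_repeated")] = mk(
        1010, deflect_amp=2.6, slow_amp=0.30, p_commission=0.026, p_ongoing_error=0.0268
    )
    specs[(F, R, "oddball")] = mk(
        932, deflect_amp=0.6, slow_amp=0.08, p_commission=0.0105, p_ongoing_error=0.06
    )
    specs[(F, R, "new_pm")] = mk(850, p_ongoing_error=0.0556)
    # finished phase, ongoing-task-only condition
    specs[(F, O, "standard")] = mk(657, p_ongoing_error=0.0337)
    specs[(F, O, "pm_repeated")] = mk(
        762, deflect_amp=2.2, slow_amp=0.25, p_commission=0.004, p_ongoing_error=0.0337
    )
    specs[(F, O, "oddball")] = mk(
        734, deflect_amp=0.6, slow_amp=0.08, p_commission=0.0005, p_ongoing_error=0.06
    )
    return ConditionEffects(specs=specs)


def null_effects() -> ConditionEffects:
    """Paper-like RTs and error rates but no trajectory effects at all."""
    return paper_like_effects().zeroed()


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------

def _block_sequence(
    counts: dict[str, int],
    symbol_assignment: dict[str, list[str]],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """One block's trial sequence as (trial_type, symbol_id) pairs.

    Constraints: the block opens with two standard trials and every
    symbol trial is followed by at least two standard trials.  The sequence
    is built from shuffled units of [symbol, standard, standard] plus
    leftover single standards, which guarantees both constraints.
    """
    n_std = counts.get("standard", 0)
    symbols: list[tuple[str, str]] = []
    for ttype, n in counts.items():
        if ttype == "standard":
            continue
        ids = list(symbol_assignment[ttype])
        if len(ids) == 1:
            ids = ids * n
        elif len(ids) != n:
            # several cues for this type: spread them evenly, then shuffle
            reps = n // len(ids)
            if reps * len(ids) != n:
                raise DesignError(f"{n} {ttype} trials not divisible over {len(ids)} cues")
            ids = ids * reps
        symbols.extend(("%s" % ttype, sid) for sid in ids)
    k = len(symbols)
    if n_std < 2 + 2 * k:
        raise DesignError(
            f"{k} symbol trials need >= {2 + 2 * k} standard trials "
            f"(2 leading + 2 after each), got {n_std}"
        )
    rng.shuffle(symbols)
    units: list[list[tuple[str, str]]] = [
        [s, ("standard", "none"), ("standard", "none")] for s in symbols
    ]
    units += [[("standard", "none")]] * (n_std - 2 - 2 * k)
    order = rng.permutation(len(units))
    seq = [("standard", "none"), ("standard", "none")]
    for i in order:
        seq.extend(units[i])
    return seq


def build_design(
    config: ExperimentConfig,
    n_participants: int,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Generate trial stubs (no outcomes) for a full simulated experiment.

    Each participant runs ``config.n_cycles`` cycles of an active phase
    followed by a finished phase; finished-phase conditions alternate across
    cycles, and participants with even/odd position start with the
    PM-task-repetition / ongoing-task-only condition respectively (start
    condition counterbalancing).  Digits are drawn uniformly from 2-9; cue
    symbols are assigned to trial types and cycles at random per participant,
    with the PM_REPEATED cue of a finished phase equal to the PM cue of the
    preceding active phase.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rows: list[tuple] = []
    width = max(2, len(str(n_participants)))
    for p in range(n_participants):
        pid = f"p{p + 1:0{width}d}"
        start_cond = COND_PM_REPETITION if p % 2 == 0 else COND_OT_ONLY
        pool = [f"sym{i:02d}" for i in rng.permutation(60)]
        pool_iter = iter(pool)
        for cycle in range(1, config.n_cycles + 1):
            cond = (
                start_cond
                if cycle % 2 == 1
                else (COND_OT_ONLY if start_cond == COND_PM_REPETITION else COND_PM_REPETITION)
            )
            pm_cue = next(pool_iter)
            odd_cue = next(pool_iter)
            assign_active = {"pm": [pm_cue], "oddball": [odd_cue]}
            if cond == COND_PM_REPETITION:
                assign_fin = {
                    "pm_repeated": [pm_cue],
                    "new_pm": [next(pool_iter)],
                    "oddball": [next(pool_iter)],
                }
            else:
                assign_fin = {
                    "pm_repeated": [pm_cue],
                    "oddball": [next(pool_iter), next(pool_iter)],
                }
            # trial_index runs continuously through the cycle (active block
            # first) so that (participant, cycle, trial_index) is unique
            idx = 0
            for phase, assign in ((PHASE_ACTIVE, assign_active), (PHASE_FINISHED, assign_fin)):
                counts = config.block_counts(phase, cond)
                seq = _block_sequence(counts, assign, rng)
                digits = rng.integers(2, 10, size=len(seq))
                for (ttype, sid), digit in zip(seq, digits):
                    idx += 1
                    rows.append((pid, cycle, phase, cond, idx, ttype, int(digit), sid))
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "cycle",
            "phase",
            "condition",
            "trial_index",
            "trial_type",
            "digit",
            "symbol_id",
        ],
    )


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _bump(tau: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Raised-cosine bump: 0 outside ``window``, peak 1 at its midpoint."""
    a, b = window
    out = np.zeros_like(tau)
    inside = (tau >= a) & (tau <= b)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (tau[inside] - a) / (b - a)))
    return out


def _min_jerk(u: np.ndarray) -> np.ndarray:
    return 10.0 * u**3 - 15.0 * u**4 + 6.0 * u**5


_MJ_GRID = np.linspace(0.0, 1.0, 513)
_MJ_VALUES = _min_jerk(_MJ_GRID)


def _min_jerk_inverse(s: float) -> float:
    """Movement-time fraction at which min-jerk progress reaches ``s``."""
    return float(np.interp(s, _MJ_VALUES, _MJ_GRID))


_OT_BOXES = ("ot_odd", "ot_even")


def simulate_trajectory(
    stub,
    spec: EffectSpec,
    config: ExperimentConfig,
    rng: np.random.Generator,
    amp_multiplier: float = 1.0,
    rt_multiplier: float = 1.0,
) -> tuple[dict, RawTrajectory | None]:
    """Simulate one trial's outcome and response-stage trajectory.

    ``stub`` needs attributes participant_id, cycle, trial_index, trial_type,
    digit.  Returns the outcome fields (chosen_box, correct,
    commission_error, rt_ms, timeout_flag) and the trajectory, or ``None``
    for response-stage timeouts, which have no completed movement.
    """
    ttype = stub.trial_type
    intended = correct_box(ttype, stub.digit)
    commission = False
    correct = True
    chosen = intended
    if ttype in ("pm_repeated", "oddball") and rng.random() < spec.p_commission:
        # full capture by the no-longer-relevant (or control) cue
        chosen, commission, correct = "pm", True, False
    elif rng.random() < spec.p_ongoing_error:
        if intended in _OT_BOXES:
            chosen = "ot_even" if intended == "ot_odd" else "ot_odd"
        else:  # PM miss: parity response given instead of the PM response
            chosen = "ot_odd" if stub.digit % 2 == 1 else "ot_even"
        correct = False

    rt = float(rng.lognormal(spec.rt_mu + math.log(rt_multiplier), spec.rt_sigma))
    if rt > config.stage_timeout:
        if commission:
            rt = config.stage_timeout - config.dt_ms  # captured movements complete
        else:
            outcome = {
                "chosen_box": "none",
                "correct": False,
                "commission_error": False,
                "rt_ms": np.nan,
                "timeout_flag": "response",
            }
            return outcome, None

    dt = config.dt_ms
    n = max(2, int(rt // dt) + 1)
    t = np.arange(n) * dt
    rt = float(t[-1])
    # fraction of the observed response stage; the trial ends at box ENTRY,
    # while the reach still carries speed, so the observed stage covers only
    # the pre-entry part of the full minimum-jerk movement
    frac = t / t[-1]

    m = amp_multiplier
    deflect = None
    if not commission and chosen != "pm":
        # transient lateral velocity bias toward the PM box (+x on screen),
        # optionally compensated later in the movement; px per normalized
        # step of the 100-step grid -> cumulative px
        vel = spec.deflect_amp * m * _bump(frac, spec.deflect_window)
        vel -= spec.return_amp * m * _bump(frac, spec.return_window)
        deflect = np.concatenate(
            ([0.0], np.cumsum((vel[1:] + vel[:-1]) * 0.5 * np.diff(frac) * 100.0))
        )

    x0, y0 = config.response_start_raw
    bx, by = config.box_targets[chosen]
    tx = bx + rng.normal(0.0, 12.0)
    ty = by + rng.normal(0.0, 12.0)
    dist = float(np.hypot(tx - x0, ty - y0))
    entry_depth = 25.0  # px past the containment boundary at stage end
    jitter = float(np.hypot(tx - bx, ty - by))
    margin = max(config.box_radius - entry_depth - jitter, 10.0)
    # the reach aims past the box centroid (participants target the box area
    # and the stage cuts off at entry), so the boundary is crossed at speed
    overshoot = 220.0
    dist_v = dist + overshoot
    s_entry = max(0.4, 1.0 - (margin + overshoot) / dist_v)
    tau_entry = _min_jerk_inverse(s_entry)

    # late slowing: warp progress within the observed stage, keeping entry at
    # the drawn RT; windows are fractions of the observed movement
    rate = 1.0 - np.minimum(spec.slow_amp * m, 0.95) * _bump(frac, spec.slow_window)
    v = np.concatenate(([0.0], np.cumsum((rate[1:] + rate[:-1]) * 0.5 * np.diff(frac))))
    v *= tau_entry / v[-1]
    s = _min_jerk(v)

    # virtual (overshot) aim point; the baseline also absorbs the bias' net
    # displacement so the movement still terminates inside the chosen box
    scale_v = dist_v / dist
    tx_v = x0 + (tx - x0) * scale_v
    ty_v = y0 + (ty - y0) * scale_v
    if deflect is not None:
        tx_v -= deflect[-1] / s_entry
    x = x0 + s * (tx_v - x0)
    y = y0 + s * (ty_v - y0)
    if deflect is not None:
        x = x + deflect

    if spec.base_noise_sd > 0:
        x = x + rng.normal(0.0, spec.base_noise_sd, n)
        y = y + rng.normal(0.0, spec.base_noise_sd, n)
        x[0], y[0] = x0, y0  # response-stage onset is logged exactly

    traj = RawTrajectory(
        participant_id=stub.participant_id,
        cycle=stub.cycle,
        trial_index=stub.trial_index,
        t=t,
        x=x,
        y=y,
    )
    outcome = {
        "chosen_box": chosen,
        "correct": correct,
        "commission_error": commission,
        "rt_ms": rt,
        "timeout_flag": "none",
    }
    return outcome, traj


def simulate_experiment(
    config: ExperimentConfig,
    effects: ConditionEffects,
    n_participants: int,
    seed: int | np.random.SeedSequence = 0,
    trial_filter=None,
) -> tuple[pd.DataFrame, list[RawTrajectory], pd.DataFrame]:
    """Simulate a full experiment.

    Returns ``(trials, trajectories, ground_truth)``: the trial table with
    outcomes, the response-stage trajectories of all completed trials, and a
    per-participant, per-cell record of the effect amplitudes actually used
    (after participant heterogeneity), for parameter-recovery checks.

    ``trial_filter`` may be a callable mapping the stub DataFrame to a
    boolean mask, restricting which design stubs are instantiated (e.g. only
    the finished-phase trials one analysis consumes); filtered-out stubs are
    omitted from the output.
    """
    if n_participants % 2 != 0:
        raise ValueError("n_participants must be even for start-condition counterbalancing")
    effects.validate_covers(config)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    design_ss, sim_ss, part_ss = ss.spawn(3)
    stubs = build_design(config, n_participants, design_ss)
    rng = np.random.default_rng(sim_ss)
    part_rng = np.random.default_rng(part_ss)

    pids = sorted(stubs["participant_id"].unique())
    amp_mult = {
        pid: float(part_rng.lognormal(-effects.participant_sd**2 / 2, effects.participant_sd))
        for pid in pids
    }
    rt_mult = {
        pid: float(
            part_rng.lognormal(-effects.rt_participant_sd**2 / 2, effects.rt_participant_sd)
        )
        for pid in pids
    }

    if trial_filter is not None:
        stubs = stubs[np.asarray(trial_filter(stubs))].reset_index(drop=True)

    outcomes: list[dict] = []
    trajectories: list[RawTrajectory] = []
    for stub in stubs.itertuples(index=False):
        spec = effects.spec_for(stub.phase, stub.condition, stub.trial_type)
        out, traj = simulate_trajectory(
            stub, spec, config, rng, amp_mult[stub.participant_id], rt_mult[stub.participant_id]
        )
        outcomes.append(out)
        if traj is not None:
            trajectories.append(traj)

    trials = pd.concat([stubs, pd.DataFrame(outcomes)], axis=1)

    gt_rows = []
    for pid in pids:
        for (phase, cond, ttype), spec in effects.specs.items():
            gt_rows.append(
                {
                    "participant_id": pid,
                    "phase": phase,
                    "condition": cond,
                    "trial_type": ttype,
                    "amp_multiplier": amp_mult[pid],
                    "deflect_amp_eff": spec.deflect_amp * amp_mult[pid],
                    "slow_amp_eff": min(spec.slow_amp * amp_mult[pid], 0.95),
                    "deflect_start": spec.deflect_window[0],
                    "deflect_end": spec.deflect_window[1],
                    "slow_start": spec.slow_window[0],
                    "slow_end": spec.slow_window[1],
                }
            )
    ground_truth = pd.DataFrame(gt_rows)
    return trials, trajectories, ground_truth
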