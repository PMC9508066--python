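"""End-to-end orchestration: simulate → preprocess → measures → analyses.

``run_all`` executes the whole pipeline on simulated (or supplied) data and
writes CSV outputs, a plain-text report and a manifest with input/output
digests so a run can be reproduced and verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import COND_OT_ONLY, COND_PM_REPETITION, PHASE_FINISHED, ExperimentConfig
from .continuous import run_aftereffects_continuous, run_costs_continuous
from .discrete import StatResult, run_discrete_suite
from .io import (
    read_trajectories,
    read_trial_log,
    validate_dataset,
    write_trajectories,
    write_trial_log,
)
from .kinematics import compute_measures
from .preprocess import normalize_trajectories, select_analysis_trials
from .simulate import ConditionEffects, paper_like_effects, simulate_experiment

FIXTURE_SEED = 947_160_21  # pinned; < 2**31


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt_segments(results: dict) -> list[str]:
    lines = []
    for dep, res in results.items():
        for name, bs in res.beta_series.items():
            segs = (
                "; ".join(f"[{s}, {e}], {sign}" for s, e, sign in bs.segments) or "none"
            )
            lines.append(f"  {dep} ~ {name}: {segs}")
    return lines


def run_all(
    config: ExperimentConfig,
    effects: ConditionEffects | None = None,
    n_participants: int = 42,
    seed: int = 0,
    out_dir: str | Path = "pmtrack_run",
    trials_path: str | Path | None = None,
    trajectories_path: str | Path | None = None,
) -> dict:
    """Run the full pipeline and write outputs under ``out_dir``.

    When ``trials_path``/``trajectories_path`` are given, simulation is
    skipped and the analysis runs on the supplied data.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()

    if trials_path is not None:
        trials = read_trial_log(trials_path, config)
        trajectories = read_trajectories(trajectories_path)
        source = {"trials": str(trials_path), "trajectories": str(trajectories_path)}
    else:
        effects = effects or paper_like_effects()
        trials, trajectories, ground_truth = simulate_experiment(
            config, effects, n_participants, seed
        )
        write_trial_log(trials, out / "trials.csv")
        write_trajectories(trajectories, out / "trajectories.csv")
        ground_truth.to_csv(out / "ground_truth.csv", index=False)
        source = {"simulated": True, "n_participants": n_participants}

    report_lines = [f"pmtrack {__version__} run report", ""]
    validation = validate_dataset(trials, trajectories, config)
    report_lines += ["dataset validation:", "  " + validation.summary().replace("\n", "\n  "), ""]

    normalized = normalize_trajectories(trajectories, config)
    measures = compute_measures(normalized)

    discrete = run_discrete_suite(trials, measures)
    report_lines.append("discrete statistics:")
    for key, val in discrete.items():
        if isinstance(val, StatResult):
            report_lines.append(f"  {key}: {val}")
        elif isinstance(val, dict):
            for eff, sr in val.items():
                report_lines.append(f"  {key}[{eff}]: {sr}")
        elif isinstance(val, float):
            report_lines.append(f"  {key}: {val:.4f}")
    report_lines.append("")

    after, after_report = select_analysis_trials(trials, "aftereffects")
    costs, costs_report = select_analysis_trials(trials, "costs")
    after_report.table.to_csv(out / "exclusions_aftereffects.csv", index=False)
    costs_report.table.to_csv(out / "exclusions_costs.csv", index=False)

    seg_frames = []
    for scope in (COND_OT_ONLY, COND_PM_REPETITION, "both_with_interaction"):
        res = run_aftereffects_continuous(after, measures, scope)
        report_lines.append(f"aftereffects segments ({scope}):")
        report_lines += _fmt_segments(res)
        for dep, r in res.items():
            tab = r.segments_table()
            tab.insert(0, "analysis", f"aftereffects/{scope}")
            seg_frames.append(tab)
    res = run_costs_continuous(costs, measures)
    report_lines.append("costs segments:")
    report_lines += _fmt_segments(res)
    for dep, r in res.items():
        tab = r.segments_table()
        tab.insert(0, "analysis", "costs")
        seg_frames.append(tab)
    pd.concat(seg_frames, ignore_index=True).to_csv(out / "segments.csv", index=False)

    (out / "report.txt").write_text("\n".join(report_lines) + "\n", encoding="utf-8")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "source": source,
        "config": config.to_dict(),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv")) if p.is_file()
        },
        "report_digest": _sha256(out / "report.txt"),
        "elapsed_s": round(time.time() - started, 2),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def make_fixtures(out_dir: str | Path, n_participants: int = 4, n_cycles: int = 2) -> dict:
    """Write small, seed-pinned datasets for tests and examples.

    Defaults: 4 participants × 2 cycles × 100 trials = 800 trials.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = ExperimentConfig(n_cycles=n_cycles, seed=FIXTURE_SEED)
    trials, trajectories, ground_truth = simulate_experiment(
        config, paper_like_effects(), n_participants, FIXTURE_SEED
    )
    write_trial_log(trials, out / "trials.csv")
    write_trajectories(trajectories, out / "trajectories.csv")
    ground_truth.to_csv(out / "ground_truth.csv", index=False)
    config.to_yaml(out / "config.yaml")
    return {
        "n_trials": len(trials),
        "n_trajectories": len(trajectories),
        "config": str(out / "config.yaml"),
    }
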