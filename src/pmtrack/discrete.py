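"""Discrete analyses: repeated-measures ANOVAs, paired t-tests, effect
sizes with noncentral-t confidence intervals, commission-error rates, the
minimal-detectable-effect power computation, and the exploratory
peak-deflection/speed-trough correlation.

Effect-size conventions (one-df within-subject designs):

* Cohen's d for paired data: ``d = mean(diff) / SD(diff) = t / sqrt(n)``,
  with a 95% CI from inverting the noncentral-t distribution;
* partial eta squared: ``η_p² = SS_effect / (SS_effect + SS_error)``, which
  for a one-numerator-df effect equals ``F / (F + df_error)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import COND_OT_ONLY, COND_PM_REPETITION, PHASE_ACTIVE, PHASE_FINISHED
from .kinematics import MeasureSet, zscore_auc
from .preprocess import select_analysis_trials

__all__ = [
    "StatResult",
    "rm_anova_2x2",
    "paired_t",
    "cohen_d_from_t",
    "cohen_d_ci",
    "partial_eta_from_F",
    "commission_rates",
    "min_detectable_d",
    "peak_trough_correlation",
    "run_discrete_suite",
]


@dataclass
class StatResult:
    """A single test statistic with df, p, effect size and optional CI."""

    statistic: float
    statistic_name: str  # "F" | "t" | "r"
    df: tuple[float, float] | float
    p: float
    effect_size: float
    effect_size_name: str  # "partial_eta_sq" | "cohen_d" | "pearson_r"
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.statistic_name == "F" and self.statistic < 0:
            raise ValueError("F statistics are non-negative")

    def __str__(self) -> str:
        df = (
            f"({self.df[0]:g}, {self.df[1]:g})"
            if isinstance(self.df, tuple)
            else f"({self.df:g})"
        )
        s = (
            f"{self.statistic_name}{df} = {self.statistic:.2f}, p = {self.p:.4g}, "
            f"{self.effect_size_name} = {self.effect_size:.2f}"
        )
        if self.ci_low is not None:
            s += f", 95% CI [{self.ci_low:.2f}, {self.ci_high:.2f}]"
        return s


# ---------------------------------------------------------------------------
# effect-size conversions
# ---------------------------------------------------------------------------

def cohen_d_from_t(t: float, n: int) -> float:
    """Paired-design Cohen's d from a t statistic with n pairs: t / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return t / np.sqrt(n)


def partial_eta_from_F(F: float, df_err: float) -> float:
    """Partial eta squared from a one-numerator-df F: F / (F + df_err)."""
    if F < 0 or df_err <= 0:
        raise ValueError("need F >= 0 and df_err > 0")
    return F / (F + df_err)


def cohen_d_ci(t: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """CI for paired Cohen's d by noncentral-t inversion.

    Finds the noncentrality parameters whose distributions place the
    observed t at the upper/lower tail probabilities, then rescales by
    sqrt(n).
    """
    df = n - 1
    alpha = 1.0 - confidence
    scale = np.sqrt(n)

    def cdf_safe(nc: float) -> float:
        # the scipy nct cdf underflows to NaN far from the noncentrality
        val = stats.nct.cdf(t, df, nc)
        if np.isnan(val):
            return 0.0 if nc > t else 1.0
        return float(val)

    def nc_for(prob: float) -> float:
        # nc such that P(T_{df,nc} <= t) = prob; the cdf decreases in nc.
        # Low df gives heavy tails, so expand the bracket until it straddles.
        span = 4.0 * (abs(t) + 1.0)
        lo, hi = t - span, t + span
        while cdf_safe(lo) < prob:
            lo -= span
        while cdf_safe(hi) > prob:
            hi += span
        return optimize.brentq(lambda nc: cdf_safe(nc) - prob, lo, hi, xtol=1e-10)

    return nc_for(1.0 - alpha / 2.0) / scale, nc_for(alpha / 2.0) / scale


def paired_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Classical paired t-test with Cohen's d and a noncentral-t d CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    diff = x - y
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    lo, hi = cohen_d_ci(t, n)
    return StatResult(
        statistic=float(t),
        statistic_name="t",
        df=float(n - 1),
        p=float(p),
        effect_size=float(cohen_d_from_t(t, n)),
        effect_size_name="cohen_d",
        ci_low=float(lo),
        ci_high=float(hi),
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_2x2(cells: pd.DataFrame) -> dict[str, StatResult]:
    """2×2 fully within-subject ANOVA from a per-participant cell table.

    ``cells`` has columns ``participant_id, A, B, value`` with exactly one
    value per participant per (A, B) cell; A and B each have two levels.
    Returns StatResults keyed ``"A"``, ``"B"``, ``"AxB"``, each tested
    against its own participant-interaction error term with df (1, n − 1),
    and partial η² = SS_effect / (SS_effect + SS_error_effect).
    """
    for col in ("participant_id", "A", "B", "value"):
        if col not in cells.columns:
            raise ValueError(f"cells table lacks column {col!r}")
    a_levels = sorted(cells["A"].unique())
    b_levels = sorted(cells["B"].unique())
    pids = sorted(cells["participant_id"].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("both factors must have exactly two levels")
    wide = cells.pivot_table(
        index="participant_id", columns=["A", "B"], values="value", aggfunc="mean"
    )
    expected = [(a, b) for a in a_levels for b in b_levels]
    missing = [
        (p, ab) for ab in expected for p in pids if pd.isna(wide.get(ab, pd.Series()).get(p))
    ]
    if missing:
        raise ValueError(f"missing cells for participants: {sorted({p for p, _ in missing})}")
    data = np.stack(
        [wide[(a, b)].loc[pids].to_numpy() for a in a_levels for b in b_levels], axis=1
    ).reshape(len(pids), 2, 2)  # (subject, A, B)

    n = len(pids)
    grand = data.mean()
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_s = data.mean(axis=(1, 2))
    m_as = data.mean(axis=2)
    m_bs = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    ss_a = 2 * n * np.sum((m_a - grand) ** 2)
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((m_as - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        data
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    out: dict[str, StatResult] = {}
    for name, ss_eff, ss_err in [
        ("A", ss_a, ss_as),
        ("B", ss_b, ss_bs),
        ("AxB", ss_ab, ss_abs),
    ]:
        df_err = n - 1
        if ss_err == 0:
            F = np.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
        else:
            F = (ss_eff / 1.0) / (ss_err / df_err)
            p = stats.f.sf(F, 1, df_err)
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out[name] = StatResult(
            statistic=float(F),
            statistic_name="F",
            df=(1.0, float(df_err)),
            p=float(p),
            effect_size=float(eta),
            effect_size_name="partial_eta_sq",
        )
    return out


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def paired_t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of a two-tailed paired t-test at effect size d with n pairs."""
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    # the opposite-tail term underflows to NaN for large |nc|; it is 0 there
    upper = np.nan_to_num(stats.nct.sf(tcrit, df, nc), nan=1.0 if nc > tcrit else 0.0)
    lower = np.nan_to_num(stats.nct.cdf(-tcrit, df, nc), nan=1.0 if nc < -tcrit else 0.0)
    return float(upper + lower)


def min_detectable_d(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest d a two-tailed paired t-test detects at the target power.

    Solved numerically on the noncentral-t power function.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    f = lambda d: paired_t_power(d, n, alpha) - power
    if f(10.0) < 0:
        raise ValueError("no solution for d in (0, 10)")
    return float(optimize.brentq(f, 1e-9, 10.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# commission rates and correlation
# ---------------------------------------------------------------------------

def commission_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Percentage of PM-box responses per participant, condition, trial type.

    Computed on all finished-phase PM_REPEATED and oddball trials (including
    timeouts in the denominator, which never end in the PM box).  The
    oddball rate is the false-alarm baseline of the commission ANOVA.
    """
    fin = trials[
        (trials["phase"] == PHASE_FINISHED)
        & trials["trial_type"].isin(["pm_repeated", "oddball"])
    ]
    if fin.empty:
        raise ValueError("no finished-phase pm_repeated/oddball trials")
    grp = fin.groupby(["participant_id", "condition", "trial_type"])
    out = grp.apply(
        lambda g: 100.0 * (g["chosen_box"] == "pm").sum() / len(g),
        include_groups=False,
    ).reset_index(name="rate_pct")
    return out


def peak_trough_correlation(
    trials: pd.DataFrame,
    measures: MeasureSet,
    condition: str,
    deflection_window: tuple[int, int] = (34, 66),
    trough_window: tuple[int, int] = (67, 99),
) -> StatResult:
    """Pearson correlation of peak deflection with the late speed trough.

    Per participant, the mean angle and speed series over PM_REPEATED trials
    of ``condition`` are reduced to the maximum angle within the
    second-third window and the minimum speed within the last-third window
    (1-based difference-step bounds, inclusive); the correlation is computed
    across participants with df = n − 2.
    """
    for w in (deflection_window, trough_window):
        if not (1 <= w[0] <= w[1] <= measures.n_steps):
            raise ValueError("windows must lie within the difference-step grid")
    sub = trials[
        (trials["trial_type"] == "pm_repeated") & (trials["condition"] == condition)
    ]
    merged = measures.merged_with(sub)
    if merged["participant_id"].nunique() < 3:
        raise ValueError("need >= 3 participants with pm_repeated trials")
    angle_cols = sorted(c for c in merged.columns if c.startswith("angle_"))
    speed_cols = sorted(c for c in merged.columns if c.startswith("speed_"))
    peaks, troughs = [], []
    for _, g in merged.groupby("participant_id"):
        ang = g[angle_cols].to_numpy(float).mean(axis=0)
        spd = g[speed_cols].to_numpy(float).mean(axis=0)
        a, b = deflection_window
        peaks.append(ang[a - 1 : b].max())
        a, b = trough_window
        troughs.append(spd[a - 1 : b].min())
    r, p = stats.pearsonr(peaks, troughs)
    n = len(peaks)
    return StatResult(
        statistic=float(r),
        statistic_name="r",
        df=float(n - 2),
        p=float(p),
        effect_size=float(r),
        effect_size_name="pearson_r",
    )


# ---------------------------------------------------------------------------
# full discrete suite
# ---------------------------------------------------------------------------

def _cell_means(trials: pd.DataFrame, value: str) -> pd.DataFrame:
    out = (
        trials.groupby(["participant_id", "trial_type", "condition"])[value]
        .mean()
        .reset_index()
        .rename(columns={"trial_type": "A", "condition": "B", value: "value"})
    )
    return out


def run_discrete_suite(
    trials: pd.DataFrame, measures: MeasureSet | None = None
) -> dict[str, object]:
    """All discrete analyses of a (simulated or real) experiment.

    Returns a dict with RT and commission 2×2 ANOVAs, per-condition
    aftereffect t-tests, costs t-tests on RT and error rates, the AUC
    analyses (when ``measures`` are supplied), and active-phase
    descriptives.
    """
    report: dict[str, object] = {}

    after, _ = select_analysis_trials(trials, "aftereffects")
    rt_cells = _cell_means(after, "rt_ms")
    report["rt_aftereffects_anova"] = rm_anova_2x2(rt_cells)

    wide = rt_cells.pivot_table(index="participant_id", columns=["A", "B"], values="value")
    for cond, label in [
        (COND_PM_REPETITION, "rt_aftereffect_t_pm_task_repetition"),
        (COND_OT_ONLY, "rt_aftereffect_t_ongoing_task_only"),
    ]:
        report[label] = paired_t(
            wide[("pm_repeated", cond)].to_numpy(), wide[("oddball", cond)].to_numpy()
        )

    rates = commission_rates(trials)
    com_cells = rates.rename(
        columns={"trial_type": "A", "condition": "B", "rate_pct": "value"}
    )
    report["commission_anova"] = rm_anova_2x2(com_cells)
    report["commission_rates"] = rates

    costs, _ = select_analysis_trials(trials, "costs")
    cost_rt = costs.groupby(["participant_id", "condition"])["rt_ms"].mean().unstack()
    report["costs_rt_t"] = paired_t(
        cost_rt[COND_PM_REPETITION].to_numpy(), cost_rt[COND_OT_ONLY].to_numpy()
    )

    # ongoing-task error rates on finished-phase standards (pre error exclusion)
    fin_std = trials[
        (trials["phase"] == PHASE_FINISHED)
        & (trials["trial_type"] == "standard")
        & (trials["timeout_flag"] == "none")
    ]
    err = (
        fin_std.assign(err=~fin_std["correct"])
        .groupby(["participant_id", "condition"])["err"]
        .mean()
        .mul(100.0)
        .unstack()
    )
    report["costs_error_t"] = paired_t(
        err[COND_PM_REPETITION].to_numpy(), err[COND_OT_ONLY].to_numpy()
    )

    if measures is not None:
        m_after = measures.merged_with(after)
        m_after["auc_z"] = zscore_auc(m_after)
        auc_cells = _cell_means(m_after, "auc_z")
        report["auc_aftereffects_anova"] = rm_anova_2x2(auc_cells)
        auc_wide = auc_cells.pivot_table(
            index="participant_id", columns=["A", "B"], values="value"
        )
        report["auc_aftereffect_t_ongoing_task_only"] = paired_t(
            auc_wide[("pm_repeated", COND_OT_ONLY)].to_numpy(),
            auc_wide[("oddball", COND_OT_ONLY)].to_numpy(),
        )
        m_costs = measures.merged_with(costs)
        m_costs["auc_z"] = zscore_auc(m_costs)
        auc_cost = m_costs.groupby(["participant_id", "condition"])["auc_z"].mean().unstack()
        report["costs_auc_t"] = paired_t(
            auc_cost[COND_PM_REPETITION].to_numpy(), auc_cost[COND_OT_ONLY].to_numpy()
        )
        for cond in (COND_OT_ONLY, COND_PM_REPETITION):
            report[f"peak_trough_correlation_{cond}"] = peak_trough_correlation(
                after, measures, cond
            )

    act = trials[
        (trials["phase"] == PHASE_ACTIVE) & (trials["timeout_flag"] == "none")
    ]
    desc = []
    for ttype, g in act.groupby("trial_type"):
        per = g[g["correct"]].groupby("participant_id")["rt_ms"].mean()
        errp = g.groupby("participant_id").apply(
            lambda h: 100.0 * (~h["correct"]).mean(), include_groups=False
        )
        desc.append(
            {
                "trial_type": ttype,
                "rt_mean_ms": per.mean(),
                "rt_sd_ms": per.std(ddof=1),
                "error_mean_pct": errp.mean(),
                "error_sd_pct": errp.std(ddof=1),
            }
        )
    report["active_phase_descriptives"] = pd.DataFrame(desc)
    report["min_detectable_d_n42"] = min_detectable_d(42, 0.05, 0.80)
    return report
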