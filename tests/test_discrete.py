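"""ANOVAs, t-tests, effect sizes, power, commission rates, correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pmtrack as pm
from pmtrack.discrete import cohen_d_ci, paired_t_power


def anova_table(values, pids=None):
    """values: (n, 2, 2) array -> long cell table."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    pids = pids or [f"p{i:02d}" for i in range(n)]
    rows = []
    for i, pid in enumerate(pids):
        for a, alev in enumerate(["a1", "a2"]):
            for b, blev in enumerate(["b1", "b2"]):
                rows.append((pid, alev, blev, values[i, a, b]))
    return pd.DataFrame(rows, columns=["participant_id", "A", "B", "value"])


def ss_oracle_2x2(values):
    """From-definition within-subject SS decomposition with explicit loops."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    grand = v.mean()
    out = {}
    m_a = [v[:, a, :].mean() for a in range(2)]
    m_b = [v[:, :, b].mean() for b in range(2)]
    m_s = [v[s].mean() for s in range(n)]
    ss_a = sum(2 * n * (m - grand) ** 2 for m in m_a)
    ss_b = sum(2 * n * (m - grand) ** 2 for m in m_b)
    ss_ab = 0.0
    for a in range(2):
        for b in range(2):
            ss_ab += n * (v[:, a, b].mean() - m_a[a] - m_b[b] + grand) ** 2
    ss_as = ss_bs = ss_abs = 0.0
    for s in range(n):
        for a in range(2):
            ss_as += 2 * (v[s, a, :].mean() - m_s[s] - m_a[a] + grand) ** 2
        for b in range(2):
            ss_bs += 2 * (v[s, :, b].mean() - m_s[s] - m_b[b] + grand) ** 2
        for a in range(2):
            for b in range(2):
                ss_abs += (
                    v[s, a, b]
                    - v[:, a, b].mean()
                    - v[s, a, :].mean()
                    - v[s, :, b].mean()
                    + m_a[a]
                    + m_b[b]
                    + m_s[s]
                    - grand
                ) ** 2
    df = n - 1
    for name, se, serr in [("A", ss_a, ss_as), ("B", ss_b, ss_bs), ("AxB", ss_ab, ss_abs)]:
        out[name] = (se / (serr / df), se / (se + serr))
    return out


class TestRmAnova:
    def test_identical_cells_give_zero_F(self):
        tab = anova_table(np.full((6, 2, 2), 5.0))
        res = pm.rm_anova_2x2(tab)
        for eff in ("A", "B", "AxB"):
            assert res[eff].statistic == 0.0
            assert res[eff].p == 1.0

    def test_matches_definitional_ss_oracle(self, rng):
        v = rng.normal(10, 2, (10, 2, 2))
        res = pm.rm_anova_2x2(anova_table(v))
        oracle = ss_oracle_2x2(v)
        for eff in ("A", "B", "AxB"):
            F, eta = oracle[eff]
            assert res[eff].statistic == pytest.approx(F, rel=1e-10)
            assert res[eff].effect_size == pytest.approx(eta, rel=1e-10)
            assert res[eff].df == (1.0, 9.0)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        v = rng.normal(0, 1, (12, 2, 2)) + np.array([[0.5, 0], [0, 0]])
        tab = anova_table(v)
        res = pm.rm_anova_2x2(tab)
        long = tab.rename(columns={"participant_id": "subj"})
        pg = pingouin.rm_anova(
            data=long, dv="value", within=["A", "B"], subject="subj", detailed=True
        )
        pcol = "p_unc" if "p_unc" in pg.columns else "p-unc"
        for eff, label in [("A", "A"), ("B", "B"), ("AxB", "A * B")]:
            row = pg[pg["Source"] == label].iloc[0]
            assert res[eff].statistic == pytest.approx(row["F"], rel=1e-8)
            assert res[eff].p == pytest.approx(row[pcol], rel=1e-6, abs=1e-12)

    def test_missing_cell_rejected(self):
        tab = anova_table(np.ones((4, 2, 2)) + np.arange(4)[:, None, None])
        tab = tab.drop(tab.index[1])
        with pytest.raises(ValueError, match="missing cells"):
            pm.rm_anova_2x2(tab)

    def test_invariance_under_shift_and_scale(self, rng):
        v = rng.normal(0, 1, (8, 2, 2)) + np.array([[0.4, 0], [0.1, -0.2]])
        base = pm.rm_anova_2x2(anova_table(v))
        moved = pm.rm_anova_2x2(anova_table(3.5 * v + 100.0))
        for eff in ("A", "B", "AxB"):
            assert moved[eff].statistic == pytest.approx(base[eff].statistic, rel=1e-9)


class TestPairedT:
    def test_known_differences(self):
        res = pm.paired_t(np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0]))
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.effect_size == pytest.approx(2.0)
        assert res.df == 2.0

    def test_zero_variance_rejected(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            pm.paired_t(x, x - 5.0)

    def test_agrees_with_scipy(self, rng):
        x, y = rng.normal(0, 1, (2, 30))
        res = pm.paired_t(x, y)
        t, p = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_d_consistency_with_conversion(self, rng):
        x, y = rng.normal(0, 1, (2, 25))
        res = pm.paired_t(x, y)
        assert res.effect_size == pytest.approx(
            pm.cohen_d_from_t(res.statistic, 25)
        )

    def test_d_ci_brackets_point_estimate_and_inverts(self, rng):
        x = rng.normal(0.5, 1, 40)
        y = rng.normal(0.0, 1, 40)
        res = pm.paired_t(x, y)
        assert res.ci_low < res.effect_size < res.ci_high
        # inversion property: at the CI bound, the observed t sits at the tail
        lo_nc = res.ci_low * np.sqrt(40)
        assert stats.nct.cdf(res.statistic, 39, lo_nc) == pytest.approx(0.975, abs=1e-6)

    def test_invariance_under_common_shift(self, rng):
        x, y = rng.normal(0, 1, (2, 20))
        a = pm.paired_t(x, y)
        b = pm.paired_t(x + 42.0, y + 42.0)
        assert a.statistic == pytest.approx(b.statistic)


class TestPower:
    def test_monotone_in_n(self):
        assert pm.min_detectable_d(84) < pm.min_detectable_d(42)

    def test_power_at_solution_equals_target(self):
        d = pm.min_detectable_d(42, 0.05, 0.80)
        assert paired_t_power(d, 42, 0.05) == pytest.approx(0.80, abs=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pm.min_detectable_d(1)
        with pytest.raises(ValueError):
            pm.min_detectable_d(42, alpha=1.5)


class TestCommissionRates:
    def test_simple_arithmetic(self):
        trials = pd.DataFrame(
            {
                "participant_id": "a",
                "condition": "ongoing_task_only",
                "phase": "finished",
                "trial_type": ["pm_repeated"] * 24,
                "chosen_box": ["pm"] + ["ot_odd"] * 23,
            }
        )
        out = pm.commission_rates(trials)
        assert out["rate_pct"].iloc[0] == pytest.approx(100.0 / 24.0)

    def test_no_commissions_zero_rate(self, small_experiment):
        trials, _, _ = small_experiment
        clean = trials.copy()
        clean.loc[clean["chosen_box"] == "pm", "chosen_box"] = "ot_odd"
        out = pm.commission_rates(clean)
        assert (out["rate_pct"] == 0.0).all()

    def test_simulated_rate_matches_generator_probability(self, config):
        """Large-sample commission rate approaches p_commission (binomial)."""
        spec = pm.EffectSpec(p_commission=0.05, rt_sigma=0.0, rt_mu=np.log(700))
        rng = np.random.default_rng(11)
        stub = pd.Series(
            {
                "participant_id": "p01",
                "cycle": 1,
                "trial_index": 1,
                "trial_type": "pm_repeated",
                "digit": 4,
            }
        )
        hits = sum(
            pm.simulate_trajectory(stub, spec, config, rng)[0]["commission_error"]
            for _ in range(2000)
        )
        assert stats.binomtest(hits, 2000, 0.05).pvalue > 0.001


class TestCorrelation:
    def _measures_from_pairs(self, peaks, troughs):
        rows, angles, speeds = [], [], []
        for i, (pk, tr) in enumerate(zip(peaks, troughs)):
            pid = f"p{i:02d}"
            for t in range(3):
                rows.append((pid, 1, i * 3 + t + 1, "finished", "ongoing_task_only",
                             "pm_repeated", True, False, "none", 700.0))
                ang = np.zeros(99)
                ang[45] = pk
                spd = np.full(99, 10.0)
                spd[80] = tr
                angles.append(ang)
                speeds.append(spd)
        trials = pd.DataFrame(
            rows,
            columns=["participant_id", "cycle", "trial_index", "phase", "condition",
                     "trial_type", "correct", "commission_error", "timeout_flag", "rt_ms"],
        )
        keys = trials[["participant_id", "cycle", "trial_index"]].copy()
        meas = pm.MeasureSet(
            keys=keys, auc=np.zeros(len(keys)),
            angle=np.vstack(angles), speed=np.vstack(speeds),
        )
        return trials, meas

    def test_perfect_negative_line(self):
        peaks = np.linspace(0.1, 0.9, 8)
        troughs = 5.0 - 4.0 * peaks
        trials, meas = self._measures_from_pairs(peaks, troughs)
        res = pm.peak_trough_correlation(trials, meas, "ongoing_task_only")
        assert res.statistic == pytest.approx(-1.0)
        assert res.df == 6.0

    def test_null_linkage_near_zero(self, rng):
        peaks = rng.uniform(0.1, 0.9, 40)
        troughs = rng.uniform(2.0, 8.0, 40)
        trials, meas = self._measures_from_pairs(peaks, troughs)
        res = pm.peak_trough_correlation(trials, meas, "ongoing_task_only")
        assert abs(res.statistic) < 0.35

    def test_too_few_participants_rejected(self):
        trials, meas = self._measures_from_pairs([0.5, 0.6], [3.0, 2.0])
        with pytest.raises(ValueError, match="participants"):
            pm.peak_trough_correlation(trials, meas, "ongoing_task_only")


class TestDiscreteSuite:
    def test_full_suite_on_paper_like_simulation(self, small_experiment, small_measures):
        trials, _, _ = small_experiment
        report = pm.run_discrete_suite(trials, small_measures)
        for key in (
            "rt_aftereffects_anova",
            "commission_anova",
            "costs_rt_t",
            "costs_error_t",
            "auc_aftereffects_anova",
            "active_phase_descriptives",
        ):
            assert key in report
        # aftereffects present in both conditions at this (small) sample
        d_rep = report["rt_aftereffect_t_pm_task_repetition"]
        d_only = report["rt_aftereffect_t_ongoing_task_only"]
        assert d_rep.statistic > 0 and d_only.statistic > 0
        # ongoing-task costs: slower standards under the new PM task
        assert report["costs_rt_t"].statistic > 0

    def test_injected_rt_aftereffect_ordering(self, config):
        """With enough trials, the RT aftereffect (PM_REPEATED - oddball) is
        positive in both conditions and larger while a new PM task is
        pursued, recovering the injected ordering."""
        trials, _, _ = pm.simulate_experiment(
            config, pm.paper_like_effects(), 20, seed=31,
            trial_filter=lambda df: (df["phase"] == "finished")
            & df["trial_type"].isin(["pm_repeated", "oddball"]),
        )
        after, _ = pm.select_analysis_trials(trials, "aftereffects")
        cells = after.groupby(["participant_id", "condition", "trial_type"])[
            "rt_ms"
        ].mean().unstack(["condition", "trial_type"])
        diffs = {
            cond: (
                cells[(cond, "pm_repeated")] - cells[(cond, "oddball")]
            ).mean()
            for cond in ("pm_task_repetition", "ongoing_task_only")
        }
        assert diffs["ongoing_task_only"] > 0
        assert diffs["pm_task_repetition"] > diffs["ongoing_task_only"]

    def test_eta_identity_between_anova_and_conversion(self, rng):
        v = rng.normal(0, 1, (9, 2, 2)) + np.array([[0.8, 0], [0, 0]])
        res = pm.rm_anova_2x2(anova_table(v))["A"]
        assert res.effect_size == pytest.approx(
            pm.partial_eta_from_F(res.statistic, 8), rel=1e-10
        )

    def test_shared_amplitude_links_deflection_and_slowing(self, config):
        """Participants with larger deflection amplitudes also slow more,
        producing a negative peak-deflection/speed-trough correlation."""
        trials, trajs, _ = pm.simulate_experiment(
            config, pm.paper_like_effects(), 20, seed=77,
            trial_filter=lambda df: (df["phase"] == "finished")
            & (df["trial_type"] == "pm_repeated")
            & (df["condition"] == "ongoing_task_only"),
        )
        meas = pm.compute_measures(pm.normalize_trajectories(trajs, config))
        ok = trials[trials["timeout_flag"] == "none"]
        res = pm.peak_trough_correlation(ok, meas, "ongoing_task_only")
        assert res.statistic < 0
        assert res.p < 0.05
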