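"""Group statistics: outlier fences, t tests, mixed-design ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from calnet.stats import (
    compare_groups_ttest,
    group_summary,
    mixed_anova_posthoc,
    remove_outliers_quartile,
)


class TestOutliers:
    def test_regular_range_keeps_everything(self):
        kept, excluded = remove_outliers_quartile(np.arange(1, 11, dtype=float))
        assert kept.size == 10 and excluded.size == 0

    def test_far_point_is_excluded(self):
        values = np.array([*range(1, 11), 100.0])
        # Q1 = 3.5, Q3 = 8.5 (linear interpolation), fence = 8.5 + 1.5*5 = 16
        kept, excluded = remove_outliers_quartile(values)
        assert list(excluded) == [100.0]
        assert kept.size == 10

    def test_constant_group_keeps_everything(self):
        kept, excluded = remove_outliers_quartile(np.full(6, 4.2))
        assert kept.size == 6 and excluded.size == 0

    def test_small_groups_untouched(self):
        kept, excluded = remove_outliers_quartile(np.array([1.0, 2.0, 99.0]))
        assert kept.size == 3 and excluded.size == 0

    def test_idempotent_on_clear_outliers(self):
        values = np.array([*range(1, 11), 100.0, -80.0])
        once, excluded1 = remove_outliers_quartile(values)
        twice, excluded2 = remove_outliers_quartile(once)
        assert sorted(excluded1) == [-80.0, 100.0]
        assert excluded2.size == 0
        assert np.array_equal(np.sort(once), np.sort(twice))


class TestTTest:
    def test_identical_groups(self):
        res = compare_groups_ttest([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_shifted_group_matches_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10.0
        res = compare_groups_ttest(a, b, exclude_outliers=False)
        # pooled SD = 1, t = -10 / sqrt(2/3), df = 4
        t_expected = -10.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2.0 * sps.t.sf(abs(t_expected), df=4)
        assert res.statistic == pytest.approx(t_expected, abs=1e-12)
        assert res.p_value == pytest.approx(p_expected, rel=1e-12)
        assert res.df == (4,)

    def test_group_stats_match_direct_formulas(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 15)
        res = compare_groups_ttest(a, b, exclude_outliers=False)
        assert res.group_stats["a"]["mean"] == pytest.approx(a.mean())
        assert res.group_stats["a"]["sd"] == pytest.approx(a.std(ddof=1))
        assert res.group_stats["b"]["sem"] == pytest.approx(
            b.std(ddof=1) / np.sqrt(b.size)
        )


def mixed_anova_ss_oracle(wide):
    """Hand decomposition of a balanced 2 (group) x 2 (phase) mixed design.

    ``wide``: DataFrame with columns group, y1, y2 (one row per subject).
    Returns F statistics for group, phase and interaction.
    """
    groups = sorted(wide["group"].unique())
    n = len(wide) // len(groups)
    y = np.stack([wide[["y1", "y2"]].to_numpy()[wide["group"] == g]
                  for g in groups])  # (g, n, p)
    grand = y.mean()
    g_means = y.mean(axis=(1, 2))
    p_means = y.mean(axis=(0, 1))
    gp_means = y.mean(axis=1)
    subj_means = y.mean(axis=2)

    n_p = y.shape[2]
    ss_group = n * n_p * ((g_means - grand) ** 2).sum()
    ss_subj_within = n_p * ((subj_means - g_means[:, None]) ** 2).sum()
    ss_phase = n * len(groups) * ((p_means - grand) ** 2).sum()
    ss_inter = n * (
        (gp_means - g_means[:, None] - p_means[None, :] + grand) ** 2
    ).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_phase - ss_inter

    df_g, df_sw = len(groups) - 1, len(groups) * (n - 1)
    df_p = n_p - 1
    df_i = df_g * df_p
    df_e = df_sw * df_p
    f_group = (ss_group / df_g) / (ss_subj_within / df_sw)
    f_phase = (ss_phase / df_p) / (ss_err_within / df_e)
    f_inter = (ss_inter / df_i) / (ss_err_within / df_e)
    return f_group, f_phase, f_inter


def _long_table(wide):
    rows = []
    for i, row in wide.iterrows():
        rows.append({"culture": i, "genotype": row["group"], "phase": "basal",
                     "value": row["y1"]})
        rows.append({"culture": i, "genotype": row["group"], "phase": "treated",
                     "value": row["y2"]})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def _toy(self, rng, effect=0.0, interaction=0.0, n=8):
        rows = []
        for g, gname in enumerate(["WT", "HD"]):
            base = rng.normal(10 + g, 1.0, n)
            y1 = base + rng.normal(0, 0.5, n)
            y2 = base + effect + interaction * g + rng.normal(0, 0.5, n)
            for i in range(n):
                rows.append({"group": gname, "y1": y1[i], "y2": y2[i]})
        return pd.DataFrame(rows)

    def test_matches_hand_ss_decomposition(self, rng):
        wide = self._toy(rng, effect=1.0, interaction=0.6)
        f_group, f_phase, f_inter = mixed_anova_ss_oracle(wide)
        res = mixed_anova_posthoc(_long_table(wide), dv="value")
        aov = res.anova_table.set_index("Source")
        assert aov.loc["genotype", "F"] == pytest.approx(f_group, rel=1e-6)
        assert aov.loc["phase", "F"] == pytest.approx(f_phase, rel=1e-6)
        assert aov.loc["Interaction", "F"] == pytest.approx(f_inter, rel=1e-6)

    def test_null_data_gives_small_f(self):
        # no phase effect planted: subject variation plus exchangeable noise
        rng = np.random.default_rng(8)
        rows = []
        for g in ["WT", "HD"]:
            for i in range(8):
                v = 10 + rng.normal(0, 1)
                rows.append({"group": g, "y1": v + rng.normal(0, 1),
                             "y2": v + rng.normal(0, 1)})
        wide = pd.DataFrame(rows)
        res = mixed_anova_posthoc(_long_table(wide), dv="value")
        aov = res.anova_table.set_index("Source")
        assert aov.loc["phase", "p_unc"] > 0.05

    def test_incomplete_subjects_are_dropped_listwise(self, rng):
        wide = self._toy(rng, effect=1.0)
        table = _long_table(wide)
        table = table.drop(table[(table["culture"] == 0)
                                 & (table["phase"] == "treated")].index)
        res = mixed_anova_posthoc(table, dv="value")
        assert 0 in res.excluded

    def test_bonferroni_posthoc_properties(self, rng):
        wide = self._toy(rng, effect=1.5)
        res = mixed_anova_posthoc(_long_table(wide), dv="value")
        ph = res.posthoc
        assert "p_corr" in ph.columns
        both = ph.dropna(subset=["p_corr"])
        # Bonferroni-adjusted p >= raw p, capped at 1
        assert (both["p_corr"] >= both["p_unc"] - 1e-12).all()
        assert (both["p_corr"] <= 1.0 + 1e-12).all()

    def test_power_for_planted_treatment_effect(self):
        """Within-subject effect d = 1.5 at n = 8/group: the treatment factor
        should reach p < 0.05 while the interaction stays quiet."""
        hits_effect = 0
        hits_inter = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            wide = self._toy(rng, effect=0.75)  # 1.5 x within-subject sd 0.5
            res = mixed_anova_posthoc(_long_table(wide), dv="value")
            aov = res.anova_table.set_index("Source")
            hits_effect += aov.loc["phase", "p_unc"] < 0.05
            hits_inter += aov.loc["Interaction", "p_unc"] > 0.05
        assert hits_effect / reps >= 0.90
        assert hits_inter / reps >= 0.80


class TestGroupSummary:
    def test_mean_sem_sd_columns(self, rng):
        df = pd.DataFrame({
            "genotype": ["WT"] * 5 + ["HD"] * 5,
            "x": np.r_[rng.normal(0, 1, 5), rng.normal(2, 1, 5)],
        })
        out = group_summary(df, ["x"], ["genotype"])
        wt = out[out["genotype"] == "WT"].iloc[0]
        vals = df[df["genotype"] == "WT"]["x"]
        assert wt["x_mean"] == pytest.approx(vals.mean())
        assert wt["x_sd"] == pytest.approx(vals.std(ddof=1))
        assert wt["x_n"] == 5
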