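"""CC probability tables, slope inference, free-motion binning, mixed ANOVA."""

import numpy as np
import pandas as pd
import pytest

import ccmotion as cm


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["participant", "frequency",
                                       "peak_velocity", "is_cc"])


class TestCCProbability:
    def test_all_cc_gives_one_everywhere(self):
        rows = [(1, f, 20.0, True) for f in cm.DESIGN_FREQUENCIES]
        tab = cm.cc_probability(seg_frame(rows), axis="frequency")
        assert (tab["probability"] == 1.0).all()

    def test_empty_bin_is_nan_not_zero(self):
        rows = [(1, 0.25, 20.0, False), (1, 0.5, 20.0, True)]
        tab = cm.cc_probability(seg_frame(rows), axis="frequency")
        empty = tab[tab["bin"] == 0.875].iloc[0]
        assert np.isnan(empty["probability"]) and empty["n_segments"] == 0

    def test_pooled_is_count_weighted_mean_of_participants(self):
        rng = np.random.default_rng(0)
        rows = []
        for p in (1, 2, 3):
            for f in cm.DESIGN_FREQUENCIES:
                for _ in range(rng.integers(2, 8)):
                    rows.append((p, f, 20.0, bool(rng.integers(0, 2))))
        df = seg_frame(rows)
        pooled = cm.cc_probability(df, axis="frequency")
        per = cm.cc_probability(df, axis="frequency", by_participant=True)
        for _, row in pooled.iterrows():
            sub = per[per["bin"] == row["bin"]]
            weighted = (sub["probability"] * sub["n_segments"]).sum() / \
                sub["n_segments"].sum()
            assert np.isclose(row["probability"], weighted)


class TestParticipantSlopes:
    def test_identical_slopes_degenerate(self):
        rows = []
        for p in (1, 2, 3, 4):
            for f in cm.DESIGN_FREQUENCIES:
                # deterministic linear-in-f CC pattern, same for everyone
                n_cc = int(round(10 * (f - 0.25) / 0.625))
                rows += [(p, f, 20.0, True)] * n_cc
                rows += [(p, f, 20.0, False)] * (10 - n_cc)
        with pytest.warns(UserWarning, match="degenerate"):
            inf = cm.participant_slopes(seg_frame(rows))
        assert inf.degenerate
        assert np.isinf(inf.t_statistic) and inf.t_statistic > 0

    def test_symmetric_slopes_give_p_half(self):
        rows = []
        for p, sign in [(1, 1), (2, -1), (3, 1), (4, -1)]:
            for f in cm.DESIGN_FREQUENCIES:
                frac = 0.5 + sign * (f - 0.5625)
                n_cc = int(round(20 * np.clip(frac, 0, 1)))
                rows += [(p, f, 20.0, True)] * n_cc
                rows += [(p, f, 20.0, False)] * (20 - n_cc)
        inf = cm.participant_slopes(seg_frame(rows))
        assert abs(inf.p_value - 0.5) < 0.2
        assert abs(np.mean(inf.slopes)) < 0.2


class TestBinFreeMotion:
    def test_edge_rules(self):
        df = pd.DataFrame({
            "frequency": [0.5 / 2.0, 0.5 / 0.571, 1.5, 0.05],
            "is_cc": [True, False, True, False],
        })
        tab = cm.bin_free_motion(df)
        by_bin = tab.set_index("bin")["n_segments"]
        assert by_bin[0.25] == 2          # 0.25 Hz and the 0.05 Hz outlier
        assert by_bin[0.875] == 2         # 0.875 Hz and the 1.5 Hz outlier
        assert by_bin[[0.375, 0.5, 0.625, 0.75]].sum() == 0

    def test_degenerate_range_lands_in_one_bin(self):
        df = pd.DataFrame({"frequency": [0.5] * 7, "is_cc": [True] * 7})
        tab = cm.bin_free_motion(df)
        assert tab.set_index("bin").loc[0.5, "n_segments"] == 7

    def test_wide_dyad_ranges_fill_all_bins(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            leader, follower, anns = cm.simulate_free_dyad(duration=180.0,
                                                           seed=12)
            res = cm.analyze_trial(follower, leader, anns)
        df = cm.segments_to_frame(res.segments)
        df = df[df["is_cc"].notna()].copy()
        df["frequency"] = 0.5 / df["duration"]
        tab = cm.bin_free_motion(df)
        assert (tab["n_segments"] > 0).all()


def split_plot_oracle(df):
    """Definitional sums-of-squares for a balanced split-plot design."""
    grand = df["y"].mean()
    n_w = df["w"].nunique()
    n_per_g = df.groupby("g")["s"].nunique().iloc[0]
    ss_total = ((df["y"] - grand) ** 2).sum()
    subj_means = df.groupby("s")["y"].mean()
    ss_subj = n_w * ((subj_means - grand) ** 2).sum()
    g_means = df.groupby("g")["y"].mean()
    ss_g = n_w * n_per_g * ((g_means - grand) ** 2).sum()
    ss_err_between = ss_subj - ss_g
    w_means = df.groupby("w")["y"].mean()
    n_subj = df["s"].nunique()
    ss_w = n_subj * ((w_means - grand) ** 2).sum()
    cell = df.groupby(["g", "w"])["y"].mean()
    ss_gw = n_per_g * sum(
        (cell[g, w] - g_means[g] - w_means[w] + grand) ** 2
        for g, w in cell.index)
    ss_err_within = ss_total - ss_subj - ss_w - ss_gw
    n_g = df["g"].nunique()
    df_g, df_w = n_g - 1, n_w - 1
    df_eb = n_subj - n_g
    df_ew = df_eb * df_w
    return {
        "g": (ss_g / df_g) / (ss_err_between / df_eb),
        "w": (ss_w / df_w) / (ss_err_within / df_ew),
        "gw": (ss_gw / (df_g * df_w)) / (ss_err_within / df_ew),
    }


class TestMixedAnova:
    @staticmethod
    def balanced_data(seed=0, effects=(0.2, 0.1, 0.05)):
        rng = np.random.default_rng(seed)
        ge, we, ie = effects
        rows = []
        for gi, g in enumerate(("A", "B", "C")):
            for s in range(4):
                subj_off = rng.normal(0, 0.05)
                for wi, w in enumerate((0.25, 0.5, 0.75)):
                    y = (0.3 + ge * gi + we * wi + ie * gi * wi + subj_off
                         + rng.normal(0, 0.03))
                    rows.append({"participant": f"{g}{s}", "experiment": g,
                                 "frequency": w, "probability": y,
                                 "g": g, "s": f"{g}{s}", "w": w, "y": y})
        return pd.DataFrame(rows)

    def test_matches_sums_of_squares_oracle(self):
        df = self.balanced_data()
        res = cm.mixed_anova(df)
        oracle = split_plot_oracle(df)
        assert np.isclose(res.effect("experiment")["F"], oracle["g"], rtol=1e-6)
        assert np.isclose(res.effect("frequency")["F"], oracle["w"], rtol=1e-6)
        assert np.isclose(res.effect("Interaction")["F"], oracle["gw"], rtol=1e-6)

    def test_all_cells_equal_gives_zero_f(self):
        df = self.balanced_data()
        df["probability"] = 0.4
        res = cm.mixed_anova(df)
        assert (res.anova["F"] == 0).all()

    def test_two_groups_one_level_equals_squared_t(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        rows = []
        for g, off in (("A", 0.0), ("B", 0.15)):
            for s in range(8):
                rows.append({"participant": f"{g}{s}", "experiment": g,
                             "frequency": 0.5,
                             "probability": 0.3 + off + rng.normal(0, 0.05)})
        df = pd.DataFrame(rows)
        res = cm.mixed_anova(df)
        a = df[df["experiment"] == "A"]["probability"]
        b = df[df["experiment"] == "B"]["probability"]
        t = stats.ttest_ind(a, b).statistic
        assert np.isclose(res.effect("experiment")["F"], t ** 2, rtol=1e-9)

    def test_incomplete_subject_excluded_with_warning(self):
        df = self.balanced_data()
        df = df[~((df["participant"] == "A0") & (df["frequency"] == 0.5))]
        with pytest.warns(UserWarning, match="missing"):
            res = cm.mixed_anova(df)
        assert res.effect("experiment")["DF2"] == 8  # 11 subjects - 3 groups

    def test_tukey_separates_distinct_groups(self):
        df = self.balanced_data(effects=(0.3, 0.0, 0.0))
        res = cm.mixed_anova(df)
        assert not res.tukey.empty
        assert res.tukey["reject"].any()
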