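"""Mixed ANOVA, sphericity, LSD contrasts, JZS and BIC Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import asrtlearn as al
from asrtlearn.stats import _orthonormal_contrasts


def _one_within(n, k, rng, effect=0.0):
    rows = []
    for s in range(n):
        base = rng.normal(400, 30)
        for j in range(k):
            rows.append({"subject": s, "w": j,
                         "y": base + effect * j + rng.normal(0, 15)})
    return pd.DataFrame(rows)


def _mixed(n_per_group, k, rng, within_effect=0.0, group_effect=0.0):
    rows = []
    for g, gname in enumerate(("A", "B")):
        for s in range(n_per_group):
            base = rng.normal(400 + group_effect * g, 30)
            for j in range(k):
                rows.append({"subject": f"{gname}{s}", "group": gname, "w": j,
                             "y": base + within_effect * j + rng.normal(0, 15)})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_dv_gives_zero_F(self):
        df = pd.DataFrame({"subject": np.repeat(np.arange(6), 2),
                           "w": [0, 1] * 6, "y": 7.0})
        res = al.mixed_anova(df, "y", within="w", subject="subject")
        assert res["F"].iloc[0] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_level_within_equals_squared_paired_t(self, seed):
        rng = np.random.default_rng(seed)
        df = _one_within(13, 2, rng, effect=12.0)
        res = al.mixed_anova(df, "y", within="w", subject="subject")
        wide = df.pivot(index="subject", columns="w", values="y")
        t, p = sps.ttest_rel(wide[0], wide[1])
        assert res["F"].iloc[0] == pytest.approx(t * t, rel=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p, rel=1e-10)
        assert res["gg_epsilon"].iloc[0] == 1.0

    def test_split_plot_ss_match_cell_means_oracle(self):
        # brute-force textbook sums of squares for a balanced 2 x 4
        # within x 2 group split-plot design
        rng = np.random.default_rng(5)
        n, ka, kc = 6, 2, 4
        y = {}
        rows = []
        for g in range(2):
            for s in range(n):
                sid = f"g{g}s{s}"
                for a in range(ka):
                    for c in range(kc):
                        val = rng.normal(10 * a + 3 * c + 4 * g + 2 * a * c, 5)
                        y[(g, sid, a, c)] = val
                        rows.append({"subject": sid, "group": g, "A": a, "C": c,
                                     "y": val})
        df = pd.DataFrame(rows)
        res = al.mixed_anova(df, "y", within=["A", "C"], subject="subject",
                             between="group").set_index("effect")

        arr = np.array([[[[y[(g, f"g{g}s{s}", a, c)] for c in range(kc)]
                          for a in range(ka)] for s in range(n)] for g in range(2)])
        grand = arr.mean()
        # balanced design: classic unweighted marginal-mean formulas
        m_a = arr.mean(axis=(0, 1, 3))
        m_c = arr.mean(axis=(0, 1, 2))
        m_g = arr.mean(axis=(1, 2, 3))
        m_ag = arr.mean(axis=(1, 3))
        m_ac = arr.mean(axis=(0, 1))
        ss_a = 2 * n * kc * ((m_a - grand) ** 2).sum()
        ss_c = 2 * n * ka * ((m_c - grand) ** 2).sum()
        ss_g = n * ka * kc * ((m_g - grand) ** 2).sum()
        ss_ag = n * kc * ((m_ag - m_a[None, :] - m_g[:, None] + grand) ** 2).sum()
        ss_ac = 2 * n * ((m_ac - m_a[:, None] - m_c[None, :] + grand) ** 2).sum()

        assert res.loc["A", "ss_effect"] == pytest.approx(ss_a)
        assert res.loc["C", "ss_effect"] == pytest.approx(ss_c)
        assert res.loc["group", "ss_effect"] == pytest.approx(ss_g)
        assert res.loc["A * group", "ss_effect"] == pytest.approx(ss_ag)
        assert res.loc["A * C", "ss_effect"] == pytest.approx(ss_ac)

    def test_matches_statsmodels_anovarm_two_within(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(11)
        rows = []
        for s in range(10):
            base = rng.normal(0, 20)
            for a in range(2):
                for c in range(5):
                    rows.append({"subject": s, "trip": a, "epoch": c,
                                 "y": base + 8 * a + 2 * c + rng.normal(0, 10)})
        df = pd.DataFrame(rows)
        mine = al.mixed_anova(df, "y", within=["trip", "epoch"],
                              subject="subject").set_index("effect")
        ref = AnovaRM(df, "y", "subject", within=["trip", "epoch"]).fit().anova_table
        assert mine.loc["trip", "F"] == pytest.approx(ref.loc["trip", "F Value"])
        assert mine.loc["epoch", "F"] == pytest.approx(ref.loc["epoch", "F Value"])
        assert mine.loc["trip * epoch", "F"] == pytest.approx(
            ref.loc["trip:epoch", "F Value"])

    def test_matches_pingouin_mixed_anova_balanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        df = _mixed(9, 4, rng, within_effect=6.0, group_effect=15.0)
        mine = al.mixed_anova(df, "y", within="w", subject="subject",
                              between="group").set_index("effect")
        ref = pg.mixed_anova(df, dv="y", within="w", subject="subject",
                             between="group").set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
        assert mine.loc["w", "F"] == pytest.approx(ref.loc["w", "F"])
        assert mine.loc["w * group", "F"] == pytest.approx(ref.loc["Interaction", "F"])
        assert mine.loc["w", "partial_eta_sq"] == pytest.approx(ref.loc["w", "np2"])

    def test_missing_cell_names_the_subject(self):
        rng = np.random.default_rng(0)
        df = _one_within(6, 3, rng)
        df = df.drop(df[(df["subject"] == 4) & (df["w"] == 2)].index)
        with pytest.raises(ValueError, match="4"):
            al.mixed_anova(df, "y", within="w", subject="subject")

    def test_single_subject_group_rejected(self):
        rng = np.random.default_rng(0)
        df = _mixed(4, 3, rng)
        df = df[df["subject"] != "B1"]
        df = df[~df["subject"].isin(["B2", "B3"])]
        with pytest.raises(ValueError, match="2 subjects"):
            al.mixed_anova(df, "y", within="w", subject="subject", between="group")


class TestGGEpsilon:
    def test_two_levels_trivially_one(self):
        cov = np.array([[4.0, 1.0], [1.0, 9.0]])
        assert al.gg_epsilon(cov) == 1.0

    def test_compound_symmetry_gives_one(self):
        k = 5
        cov = np.full((k, k), 3.0) + np.eye(k) * 2.0
        assert al.gg_epsilon(cov) == pytest.approx(1.0)

    def test_rank_one_covariance_hits_lower_bound(self):
        # maximal non-sphericity: all variance on one contrast direction
        k = 4
        c = _orthonormal_contrasts(k)
        cov = np.outer(c[0], c[0]) * 10.0
        assert al.gg_epsilon(cov) == pytest.approx(1.0 / (k - 1))

    def test_matches_pingouin_on_random_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n, k = 15, 4
        Y = rng.normal(0, 1, (n, k)) @ np.diag([1.0, 2.0, 3.0, 1.5])
        long = pd.DataFrame({"subject": np.repeat(np.arange(n), k),
                             "w": np.tile(np.arange(k), n), "y": Y.ravel()})
        mine = al.mixed_anova(long, "y", within="w", subject="subject")
        assert mine["gg_epsilon"].iloc[0] == pytest.approx(
            pg.epsilon(long, dv="y", subject="subject", within="w"), rel=1e-9)
        # corrected p agrees with pingouin's GG-corrected p
        ref = pg.rm_anova(long, dv="y", subject="subject", within="w",
                          correction=True)
        if mine["correction_applied"].iloc[0]:
            assert mine["p"].iloc[0] == pytest.approx(
                float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_mauchly_close_to_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n, k = 18, 4
        Y = rng.normal(0, 1, (n, k)) @ np.diag([1.0, 2.5, 0.7, 1.2])
        long = pd.DataFrame({"subject": np.repeat(np.arange(n), k),
                             "w": np.tile(np.arange(k), n), "y": Y.ravel()})
        mine = al.mixed_anova(long, "y", within="w", subject="subject")
        ref = pg.sphericity(long, dv="y", subject="subject", within="w")
        assert mine["mauchly_p"].iloc[0] == pytest.approx(ref.pval, rel=0.15)


class TestLSD:
    def test_identical_cells_give_t_zero(self):
        df = pd.DataFrame({"subject": list(range(6)) * 2,
                           "w": [0] * 6 + [1] * 6,
                           "y": [1.0, 2, 3, 4, 5, 6] * 2})
        res = al.lsd_pairwise(df, "y", "w", subject="subject")
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_three_levels_give_three_contrasts(self):
        rng = np.random.default_rng(0)
        df = _one_within(8, 3, rng)
        res = al.lsd_pairwise(df, "y", "w", subject="subject")
        assert len(res) == 3
        assert set(map(tuple, res[["A", "B"]].values)) == {(0, 1), (0, 2), (1, 2)}

    def test_contrast_matches_hand_computed_paired_t(self):
        rng = np.random.default_rng(3)
        df = _one_within(10, 3, rng, effect=5.0)
        res = al.lsd_pairwise(df, "y", "w", subject="subject").set_index(["A", "B"])
        wide = df.pivot(index="subject", columns="w", values="y")
        d = wide[0] - wide[2]
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.loc[(0, 2), "t"] == pytest.approx(t_hand)

    def test_independent_contrasts_for_between_factor(self):
        rng = np.random.default_rng(4)
        df = _mixed(8, 2, rng, group_effect=30.0)
        subj = df.groupby("subject", observed=True).agg(
            y=("y", "mean"), group=("group", "first")).reset_index()
        res = al.lsd_pairwise(subj, "y", "group", paired=False)
        t, p = sps.ttest_ind(subj.loc[subj.group == "A", "y"],
                             subj.loc[subj.group == "B", "y"])
        assert res["t"].iloc[0] == pytest.approx(t)

    def test_single_level_rejected(self):
        df = pd.DataFrame({"subject": [0, 1], "w": [0, 0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="2 levels"):
            al.lsd_pairwise(df, "y", "w", subject="subject")


class TestJZSBayesFactors:
    # printed t statistics with their reference BF01 values; the
    # tolerance covers the reference values having been computed from
    # unrounded t while we start from t printed to two decimals
    @pytest.mark.parametrize("t, bf01", [
        (0.48, 4.67), (1.08, 3.04), (0.41, 4.82),
        (0.80, 3.87), (1.09, 3.02), (0.21, 5.08),
    ])
    def test_two_sample_reproduces_reference_values(self, t, bf01):
        res = al.jzs_bf_two_sample(t, 31, 30, r=1.0)
        assert res.bf01 == pytest.approx(bf01, abs=0.03)

    @pytest.mark.parametrize("t, n, bf01, tol", [
        (2.07, 28, 0.99, 0.02), (4.82, 29, 0.002, 0.005),
        (4.04, 29, 0.01, 0.01), (3.58, 28, 0.04, 0.01),
    ])
    def test_one_sample_reproduces_reference_values(self, t, n, bf01, tol):
        res = al.jzs_bf_one_sample(t, n, r=1.0)
        assert res.bf01 == pytest.approx(bf01, abs=tol)

    def test_null_support_maximized_at_t_zero(self):
        bf_at_zero = al.jzs_bf_one_sample(0.0, 25).bf01
        for t in (-3.0, -1.0, -0.2, 0.2, 1.0, 3.0):
            assert al.jzs_bf_one_sample(t, 25).bf01 < bf_at_zero

    def test_bf01_strictly_decreasing_in_abs_t(self):
        ts = np.linspace(0, 6, 25)
        bfs = [al.jzs_bf_one_sample(t, 28).bf01 for t in ts]
        assert all(a > b for a, b in zip(bfs, bfs[1:]))

    def test_matches_fine_grid_quadrature_oracle(self):
        # independent trapezoid-rule integration on a dense grid, with
        # the substitution g = u/(1-u) to cover the whole half-line
        def oracle_bf01(t, n_eff, df, r=1.0):
            u = np.linspace(1e-9, 1 - 1e-9, 2_000_001)
            g = u / (1 - u)
            shrink = 1 + n_eff * g
            integ = (shrink ** -0.5
                     * (1 + t * t / (shrink * df)) ** (-(df + 1) / 2)
                     * r / np.sqrt(2 * np.pi) * g ** -1.5
                     * np.exp(-r * r / (2 * g))) / (1 - u) ** 2
            num = np.trapezoid(integ, u)
            return (1 + t * t / df) ** (-(df + 1) / 2) / num

        for t in (-5.0, -2.0, -0.5, 0.0, 1.0, 3.0, 5.0):
            mine = al.jzs_bf_one_sample(t, 20).bf01
            assert mine == pytest.approx(oracle_bf01(t, 20, 19), rel=2e-4)

    def test_reciprocal_relation(self):
        res = al.jzs_bf_two_sample(1.5, 12, 14)
        assert res.bf10 == pytest.approx(1.0 / res.bf01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            al.jzs_bf_one_sample(np.nan, 10)
        with pytest.raises(ValueError, match="n >= 2"):
            al.jzs_bf_one_sample(1.0, 1)


class TestBICInclusion:
    def test_strong_within_effect_favors_inclusion(self):
        rng = np.random.default_rng(5)
        rows = []
        for g in ("A", "B"):
            for s in range(12):
                base = rng.normal(0, 5)
                for j in range(4):
                    rows.append({"subject": f"{g}{s}", "group": g, "epoch": j,
                                 "y": 10 + base + 6 * j + rng.normal(0, 4)})
        res = al.anova_bf_inclusion_approx(pd.DataFrame(rows), "y",
                                           subject="subject", within="epoch",
                                           between="group").set_index("effect")
        assert res.loc["epoch", "inv_bf_inclusion"] < 1.0
        assert res.loc["group", "inv_bf_inclusion"] > 1.0
        assert (res["method"] == "bic_anova_approx").all()
        assert res["note"].str.contains("approximation").all()

    def test_prior_inclusion_probabilities(self):
        rng = np.random.default_rng(1)
        rows = [{"subject": f"{g}{s}", "group": g, "epoch": j,
                 "y": rng.normal()} for g in "AB" for s in range(5)
                for j in range(3)]
        res = al.anova_bf_inclusion_approx(pd.DataFrame(rows), "y",
                                           subject="subject", within="epoch",
                                           between="group").set_index("effect")
        # 5-model space respecting marginality: mains in 3/5, interaction 1/5
        assert res.loc["epoch", "p_incl_prior"] == pytest.approx(0.6)
        assert res.loc["group", "p_incl_prior"] == pytest.approx(0.6)
        assert res.loc["epoch:group", "p_incl_prior"] == pytest.approx(0.2)

    def test_pure_noise_favors_exclusion_on_average(self):
        rng = np.random.default_rng(17)
        above_one = 0
        reps = 60
        for _ in range(reps):
            rows = [{"subject": s, "epoch": j, "y": rng.normal()}
                    for s in range(10) for j in range(4)]
            res = al.anova_bf_inclusion_approx(pd.DataFrame(rows), "y",
                                               subject="subject", within="epoch")
            above_one += res["inv_bf_inclusion"].iloc[0] > 1.0
        assert above_one > reps / 2

    def test_two_model_space_matches_direct_bic_identity(self):
        # with a single effect the inclusion BF must equal exp(dBIC/2)
        rng = np.random.default_rng(2)
        rows = [{"subject": s, "epoch": j, "y": 3.0 * j + rng.normal()}
                for s in range(8) for j in range(3)]
        df = pd.DataFrame(rows)
        res = al.anova_bf_inclusion_approx(df, "y", subject="subject",
                                           within="epoch")
        from asrtlearn.stats import _cs_loglik
        import statsmodels.formula.api as smf

        bics = {}
        for rhs, k_fixed in (("1", 1), ("C(epoch)", 3)):
            fit = smf.ols(f"y ~ {rhs}", data=df).fit()
            ll = _cs_loglik(fit.resid.to_numpy(), df["subject"].to_numpy(), 3)
            bics[rhs] = -2 * ll + (k_fixed + 2) * np.log(len(df))
        expected = np.exp((bics["1"] - bics["C(epoch)"]) / 2)
        assert res["bf_inclusion"].iloc[0] == pytest.approx(expected, rel=1e-9)
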