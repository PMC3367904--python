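"""Within-subject statistics against brute-force hand computations."""

import numpy as np
import pandas as pd
import pytest

from serialorder.stats import (
    correlations,
    linreg_session,
    paired_t,
    rm_anova_2way,
    within_subject_se,
)

# 4 subjects x 2 x 2 fixture; all sums of squares verified by exact
# fraction arithmetic on the cell means (SS_A=81, SS_B=36, SS_AB=4,
# SS_AxS=2, SS_BxS=1, SS_ABxS=5)
FIXTURE = pd.DataFrame(
    [
        (1, 1, 1, 10), (1, 1, 2, 12), (1, 2, 1, 13), (1, 2, 2, 18),
        (2, 1, 1, 8), (2, 1, 2, 11), (2, 2, 1, 12), (2, 2, 2, 14),
        (3, 1, 1, 11), (3, 1, 2, 13), (3, 2, 1, 16), (3, 2, 2, 19),
        (4, 1, 1, 9), (4, 1, 2, 10), (4, 2, 1, 11), (4, 2, 2, 17),
    ],
    columns=["participant", "A", "B", "y"],
)


class TestRMAnova:
    def test_hand_computed_fixture(self):
        res = rm_anova_2way(FIXTURE, dv="y", within=("A", "B"))
        a = res.effect("A")
        b = res.effect("B")
        ab = res.effect("A:B")
        assert (a.df1, a.df2) == (1, 3)
        assert a.F == pytest.approx(121.5)  # (81/1)/(2/3)
        assert b.F == pytest.approx(108.0)  # (36/1)/(1/3)
        assert ab.F == pytest.approx(2.4)   # (4/1)/(5/3)

    def test_constant_data_gives_zero_F(self):
        flat = FIXTURE.assign(y=7.0)
        res = rm_anova_2way(flat, dv="y", within=("A", "B"))
        assert (res.table.F == 0).all()

    def test_paper_scale_degrees_of_freedom(self):
        """45 blocks x 2 sequence types x 21 subjects: df = (44, 880)."""
        rng = np.random.default_rng(0)
        rows = [
            (s, b, c, rng.normal())
            for s in range(21)
            for b in range(45)
            for c in range(2)
        ]
        df = pd.DataFrame(rows, columns=["participant", "A", "B", "y"])
        res = rm_anova_2way(df, dv="y", within=("A", "B"))
        a = res.effect("A")
        assert (a.df1, a.df2) == (44, 880)
        assert (res.effect("B").df1, res.effect("B").df2) == (1, 20)

    def test_F_equals_t_squared_on_two_level_factor(self):
        rng = np.random.default_rng(1)
        n = 12
        x = rng.normal(500, 40, n)
        y = x + rng.normal(20, 15, n)
        df = pd.DataFrame(
            {
                "participant": np.repeat(np.arange(n), 2),
                "A": np.tile([1, 2], n),
                "B": 1,
                "y": np.ravel(np.column_stack([x, y])),
            }
        )
        # second factor needs >= 2 levels; duplicate with an offset
        df2 = df.assign(B=2, y=df.y + rng.normal(0, 1, 2 * n))
        res = rm_anova_2way(pd.concat([df, df2]), dv="y", within=("A", "B"))
        # the A test aggregates over B, equivalent to a paired t on B-means
        means = (
            pd.concat([df, df2])
            .groupby(["participant", "A"])
            .y.mean()
            .unstack()
        )
        t, dof, _ = paired_t(means[1], means[2])
        assert res.effect("A").F == pytest.approx(t**2)
        assert res.effect("A").df2 == dof

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_2way(FIXTURE.iloc[:-1], dv="y", within=("A", "B"))

    def test_against_pingouin(self):
        """Independent cross-check of F statistics on noisy data."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        rows = [
            (s, a, b, rng.normal(500 + 10 * a + 5 * b + 3 * a * b, 20))
            for s in range(9)
            for a in range(3)
            for b in range(2)
        ]
        df = pd.DataFrame(rows, columns=["participant", "A", "B", "y"])
        ours = rm_anova_2way(df, dv="y", within=("A", "B"))
        theirs = pg.rm_anova(
            data=df, dv="y", within=["A", "B"], subject="participant", detailed=True
        ).set_index("Source")
        assert ours.effect("A").F == pytest.approx(theirs.loc["A", "F"])
        assert ours.effect("B").F == pytest.approx(theirs.loc["B", "F"])
        assert ours.effect("A:B").F == pytest.approx(theirs.loc["A * B", "F"])


class TestPairedT:
    def test_textbook_fixture(self):
        x = [312.0, 295.0, 340.0, 368.0, 301.0]
        y = [290.0, 300.0, 311.0, 350.0, 280.0]
        t, dof, p = paired_t(x, y)
        assert t == pytest.approx(2.9371526469766245)
        assert dof == 4
        assert p == pytest.approx(0.04250955147560154)

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=21)
        _, dof, _ = paired_t(x, x + rng.normal(1, 0.5, 21))
        assert dof == 20

    def test_mean_zero_noise_gives_small_t(self):
        rng = np.random.default_rng(3)
        x = rng.normal(500, 30, 200)
        d = rng.normal(0, 10, 200)
        t, _, p = paired_t(x, x + d - d.mean())
        assert abs(t) < 1e-9 and p > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_one_tailed_halves_p(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 15)
        y = x - np.abs(rng.normal(1, 0.3, 15))
        t2, _, p2 = paired_t(x, y)
        t1, _, p1 = paired_t(x, y, tail="greater")
        assert t1 == t2 and p1 == pytest.approx(p2 / 2)


class TestCorrelations:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        r, t, p = correlations(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p < 1e-12
        r, _, _ = correlations(x, -x)
        assert r == pytest.approx(-1.0)

    def test_df_in_t_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=21)
        y = 0.5 * x + rng.normal(size=21)
        r, t, p = correlations(x, y)
        assert t == pytest.approx(r * np.sqrt(19 / (1 - r**2)))
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.t.sf(abs(t), 19))

    def test_spearman_is_rank_based(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.exp(x)  # monotone, nonlinear
        r, _, _ = correlations(x, y, method="spearman")
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRegression:
    def test_perfectly_linear(self):
        df = pd.DataFrame(
            {"session": [1, 1, 2, 2, 3, 3], "value_ms": [10.0, 10, 20, 20, 30, 30]}
        )
        res = linreg_session(df)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_df_matches_observation_count(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "session": np.repeat([1, 2, 3], 63),
                "value_ms": rng.normal(size=189),
            }
        )
        res = linreg_session(df)
        assert res.df == 187

    def test_null_slope_p_uniform(self):
        """Under no session effect the regression p-value is uniform."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(400):
            df = pd.DataFrame(
                {
                    "session": np.repeat([1, 2, 3], 21),
                    "value_ms": rng.normal(size=63),
                }
            )
            ps.append(linreg_session(df).p)
        ps = np.array(ps)
        # coarse uniformity: rejection rate near alpha at two thresholds
        assert abs((ps < 0.05).mean() - 0.05) < 0.04
        assert abs((ps < 0.5).mean() - 0.5) < 0.08

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"session": [1, 1, 1], "value_ms": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            linreg_session(df)

    def test_r_squared_matches_correlation(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "session": np.repeat([1, 2, 3], 20),
                "value_ms": rng.normal(size=60) + np.repeat([0, 1, 2], 20),
            }
        )
        res = linreg_session(df)
        r, _, _ = correlations(df.session, df.value_ms)
        assert res.r_squared == pytest.approx(r**2)


class TestWithinSubjectSE:
    def test_hand_computed_fixture(self):
        # subject x condition means of FIXTURE collapsed over B; the
        # interaction SS is 1/3 by fraction arithmetic -> SE = 1/(2 sqrt(3))
        means = FIXTURE.groupby(["participant", "A"]).y.mean().reset_index()
        res = within_subject_se(means, dv="y", condition="A")
        assert res.se == pytest.approx(1 / (2 * np.sqrt(3)))
        assert res.n_participants == 4

    def test_additive_data_gives_zero(self):
        df = pd.DataFrame(
            {
                "participant": np.repeat([1, 2, 3], 2),
                "cell": ["a", "b"] * 3,
                "median_rt_ms": [10.0, 15, 20, 25, 30, 35],  # constant offset
            }
        )
        assert within_subject_se(df).se == pytest.approx(0.0)

    def test_scaling(self):
        means = FIXTURE.groupby(["participant", "A"]).y.mean().reset_index()
        a = within_subject_se(means, dv="y", condition="A").se
        means2 = means.assign(y=means.y * 3.5)
        b = within_subject_se(means2, dv="y", condition="A").se
        assert b == pytest.approx(3.5 * a)

    def test_unbalanced_rejected(self):
        df = pd.DataFrame(
            {
                "participant": [1, 1, 2],
                "cell": ["a", "b", "a"],
                "median_rt_ms": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError):
            within_subject_se(df)
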