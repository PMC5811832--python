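"""Split-plot / repeated-measures ANOVA and correlation inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wavegraph.stats import (
    mixed_anova,
    nodal_group_comparison,
    one_way_rm_anova,
    partial_pearson,
    pearson,
)

from oracles import bf_rm_anova, bf_split_plot


def long_table(y: np.ndarray, group_idx, sessions=("placebo", "naltrexone")):
    rows = []
    for i in range(y.shape[0]):
        for k, s in enumerate(sessions):
            rows.append(
                {
                    "subject": f"s{i:03d}",
                    "group": f"g{group_idx[i]}",
                    "session": s,
                    "value": y[i, k],
                }
            )
    return pd.DataFrame(rows)


def random_design(rng, n_groups=None, n_sessions=2):
    n_groups = n_groups or int(rng.integers(2, 4))
    sizes = rng.integers(3, 9, n_groups)
    group_idx = np.repeat(np.arange(n_groups), sizes)
    n = group_idx.size
    y = rng.standard_normal((n, n_sessions)) + rng.standard_normal((n, 1))
    y += rng.standard_normal((n_groups, n_sessions))[group_idx] * 0.5
    return y, group_idx


class TestMixedAnova:
    def test_all_equal_values_give_zero_f(self):
        y = np.full((9, 2), 3.3)
        tab = mixed_anova(long_table(y, [0, 0, 0, 1, 1, 1, 2, 2, 2]))
        assert (tab["F"] == 0).all()
        assert (tab["p"] == 1.0).all()

    def test_matches_projection_oracle_on_random_designs(self):
        """Closed-form sums of squares agree with explicit projection fits,
        including unbalanced group sizes."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y, gi = random_design(rng)
            tab = mixed_anova(long_table(y, gi)).set_index("effect")
            oracle = bf_split_plot(y, gi)
            for eff in ("group", "drug", "group:drug"):
                assert tab.loc[eff, "F"] == pytest.approx(oracle[eff]["F"], rel=1e-8)
                assert tab.loc[eff, "df1"] == oracle[eff]["df1"]
                assert tab.loc[eff, "df2"] == oracle[eff]["df2"]

    def test_matches_pingouin_on_balanced_design(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        y = rng.standard_normal((12, 2))
        gi = [0] * 6 + [1] * 6
        df = long_table(y, gi)
        ours = mixed_anova(df).set_index("effect")
        theirs = pg.mixed_anova(
            data=df, dv="value", within="session", between="group", subject="subject"
        ).set_index("Source")
        assert ours.loc["group", "F"] == pytest.approx(theirs.loc["group", "F"], rel=1e-6)
        assert ours.loc["drug", "F"] == pytest.approx(theirs.loc["session", "F"], rel=1e-6)
        assert ours.loc["group:drug", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-6
        )

    def test_subject_missing_a_session_excluded(self):
        rng = np.random.default_rng(6)
        y, gi = random_design(rng, n_groups=2)
        df = long_table(y, gi)
        df = df.drop(df[(df.subject == "s000") & (df.session == "naltrexone")].index)
        tab = mixed_anova(df)
        # one subject dropped: df2 for the between stratum shrinks by one
        assert tab.set_index("effect").loc["group", "df2"] == y.shape[0] - 1 - 2

    def test_stratum_sums_of_squares_add_up(self):
        """Between-stratum SS (group + subjects) and within-stratum SS
        (drug + interaction + error) each reconstruct their stratum total."""
        rng = np.random.default_rng(7)
        y, gi = random_design(rng)
        oracle = bf_split_plot(y, gi)
        n, s = y.shape
        subj_means = y.mean(axis=1)
        ss_between = s * ((subj_means - y.mean()) ** 2).sum()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert oracle["group"]["SS"] + oracle["_ss_subj"] == pytest.approx(
            ss_between, rel=1e-8
        )
        within = oracle["drug"]["SS"] + oracle["group:drug"]["SS"] + oracle["_ss_err"]
        assert within == pytest.approx(ss_total - ss_between, rel=1e-8)

    def test_empirical_power_matches_noncentral_f(self):
        """Planted group x drug interaction (only group A shifts between
        sessions): rejection rate tracks the noncentral-F prediction."""
        n_g = np.array([20, 20, 12])
        delta = 1.0
        mu = np.zeros((3, 2))
        mu[0, 1] = delta
        n = n_g.sum()
        mg = mu.mean(axis=1)
        ms = (n_g[:, None] * mu).sum(axis=0) / n
        ab = mu - mg[:, None] - ms[None, :] + (n_g[:, None] * mu).sum() / (2 * n)
        lam = float((n_g[:, None] * ab**2).sum())
        fcrit = sps.f.isf(0.05, 2, (n - 3))
        predicted = 1 - sps.ncf.cdf(fcrit, 2, n - 3, lam)

        gi = np.repeat([0, 1, 2], n_g)
        hits = 0
        n_rep = 150
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            base = rng.standard_normal((n, 1))
            y = base + rng.standard_normal((n, 2))
            y[gi == 0, 1] += delta
            tab = mixed_anova(long_table(y, gi)).set_index("effect")
            hits += tab.loc["group:drug", "p"] < 0.05
        se = np.sqrt(predicted * (1 - predicted) / n_rep)
        assert abs(hits / n_rep - predicted) < 3.5 * se + 0.01


class TestRmAnova:
    def test_identical_sessions_give_zero_f(self):
        y = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        tab = one_way_rm_anova(
            long_table(y, [0] * 6, sessions=("baseline", "placebo", "naltrexone"))
        )
        assert tab["F"].iloc[0] == 0.0

    def test_matches_projection_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal((8, 3)) + rng.standard_normal((8, 1))
            tab = one_way_rm_anova(
                long_table(y, [0] * 8, sessions=("baseline", "placebo", "naltrexone"))
            )
            oracle = bf_rm_anova(y)
            assert tab["F"].iloc[0] == pytest.approx(oracle["F"], rel=1e-8)
            assert tab["df1"].iloc[0] == oracle["df1"]
            assert tab["df2"].iloc[0] == oracle["df2"]

    def test_session_effect_power_matches_noncentral_f(self):
        """1 within-SD shift in one of three sessions at n=12: the rejection
        rate tracks the noncentral-F prediction (lambda = 8, F(2,22) at
        alpha=0.05 gives power 0.653)."""
        lam = 12 * ((2.0 / 3.0) ** 2 + 2 * (1.0 / 3.0) ** 2)
        predicted = 1 - sps.ncf.cdf(sps.f.isf(0.05, 2, 22), 2, 22, lam)
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal((12, 1)) + rng.standard_normal((12, 3))
            y[:, 2] += 1.0
            tab = one_way_rm_anova(
                long_table(y, [0] * 12, sessions=("baseline", "placebo", "naltrexone"))
            )
            hits += tab["p"].iloc[0] < 0.05
        se = np.sqrt(predicted * (1 - predicted) / n_rep)
        assert abs(hits / n_rep - predicted) < 3.5 * se + 0.01

    def test_gg_epsilon_bounds(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal((10, 3))
        tab = one_way_rm_anova(
            long_table(y, [0] * 10, sessions=("baseline", "placebo", "naltrexone"))
        )
        eps = tab["gg_epsilon"].iloc[0]
        assert 0.5 <= eps <= 1.0  # lower bound 1/(s-1) with s=3


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.R == pytest.approx(1.0)

    def test_hand_computed_five_point_table(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # textbook formula: r = cov / (sd_x sd_y) = 8 / sqrt(10 * 10)
        assert pearson(x, y).R == pytest.approx(0.8)

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        x, y = rng.standard_normal((2, 30))
        assert pearson(x, y).R == pytest.approx(pearson(y, x).R, abs=1e-15)

    def test_partial_with_no_covariates_equals_plain(self):
        rng = np.random.default_rng(13)
        x, y = rng.standard_normal((2, 25))
        plain = pearson(x, y)
        part = partial_pearson(x, y, None)
        assert part.R == plain.R and part.p == plain.p

    def test_partial_correlation_removes_age_confound(self):
        """y = x + age with age as covariate: partialling out age recovers
        the direct x-y dependence; the raw correlation is inflated."""
        rng = np.random.default_rng(14)
        age = rng.standard_normal(100) * 3
        x = rng.standard_normal(100) + age
        y = x * 0.0 + age + rng.standard_normal(100)  # y depends only on age
        raw = pearson(x, y)
        part = partial_pearson(x, y, age, names=("age",))
        assert abs(part.R) < abs(raw.R)
        assert part.p > 0.01  # no direct dependence left
        assert part.controlled_for == ("age",)

    def test_partial_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.standard_normal((40, 3)), columns=["x", "y", "z"])
        ours = partial_pearson(df.x.to_numpy(), df.y.to_numpy(), df.z.to_numpy())
        theirs = pg.partial_corr(df, x="x", y="y", covar="z")
        assert ours.R == pytest.approx(theirs["r"].iloc[0], abs=1e-10)
        assert ours.p == pytest.approx(theirs["p_val"].iloc[0], abs=1e-10)

    def test_pearson_p_uniform_under_null(self):
        """Two-sided p-values are uniform under independence (KS at alpha=0.01)."""
        rng = np.random.default_rng(16)
        ps = []
        for _ in range(500):
            x, y = rng.standard_normal((2, 20))
            ps.append(pearson(x, y).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))


class TestNodalComparison:
    def _nodal_frame(self, a, b):
        rows = []
        for g, arr in (("A", a), ("B", b)):
            for s in range(arr.shape[0]):
                for r in range(arr.shape[1]):
                    rows.append(
                        {"subject": f"{g}{s}", "group": g, "roi": f"ROI_{r:03d}", "value": arr[s, r]}
                    )
        return pd.DataFrame(rows)

    def test_bonferroni_is_raw_times_n_nodes_capped(self):
        rng = np.random.default_rng(17)
        tab = nodal_group_comparison(
            self._nodal_frame(rng.standard_normal((8, 6)), rng.standard_normal((8, 6))),
            ("A", "B"),
            n_comparisons=90,
        )
        np.testing.assert_allclose(
            tab["p_bonferroni"], np.minimum(1.0, tab["p"] * 90), atol=1e-15
        )

    def test_null_familywise_error_controlled(self):
        """After Bonferroni over 90 nodes, any-node false positives at
        alpha=0.05 stay within the binomial envelope of 0.05 over 200 reps."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            tab = nodal_group_comparison(
                self._nodal_frame(rng.standard_normal((10, 90)), rng.standard_normal((10, 90))),
                ("A", "B"),
            )
            hits += (tab["p_bonferroni"] < 0.05).any()
        assert hits / 200 <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / 200)

    def test_planted_node_effect_has_minimal_adjusted_p(self):
        """d=2 effect at one node, n=20/group: that node attains the
        minimal adjusted p in >= 90% of seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((20, 10))
            b = rng.standard_normal((20, 10))
            a[:, 3] += 2.0
            tab = nodal_group_comparison(self._nodal_frame(a, b), ("A", "B"))
            wins += tab.loc[tab["p_bonferroni"].idxmin(), "roi"] == "ROI_003"
        assert wins >= 18
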