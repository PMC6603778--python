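"""Factorial-analysis contracts: frequency binning, ANOVA against closed-form
sums of squares, permutation invariance, degenerate handling, and Tukey HSD
identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fmgsampling.factors import (
    FREQ_GROUPS,
    bin_frequencies,
    n_way_anova,
    tukey_hsd,
)


def _records(freqs):
    return pd.DataFrame({"sub_frequency": freqs, "rmse": np.arange(len(freqs), dtype=float)})


class TestBinning:
    def test_interval_membership(self):
        out = bin_frequencies(_records([65.0]))
        assert out["freq_group"].iloc[0] == "60-70"

    def test_top_edge_closed(self):
        out = bin_frequencies(_records([100.0]))
        assert out["freq_group"].iloc[0] == "90-100"

    def test_left_closed_right_open(self):
        out = bin_frequencies(_records([20.0, 19.999]))
        assert list(out["freq_group"]) == ["20-30", "10-20"]

    def test_step_enumeration_at_1khz(self):
        """Steps 10..100 all resolve into [10, 100] Hz; step 9 (111.1 Hz) is
        excluded by the band filter."""
        steps = np.arange(9, 101)
        out = bin_frequencies(_records(1000.0 / steps))
        assert len(out) == 91
        assert out["sub_frequency"].max() == pytest.approx(100.0)
        assert set(out["freq_group"].cat.categories) == set(FREQ_GROUPS)

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="sub_frequency"):
            bin_frequencies(_records([5.0, 500.0]))


def brute_force_anova(table, response, factors):
    """Direct cell-means sums-of-squares for balanced designs (main effects)."""
    y = table[response].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    out = {}
    ss_model = 0.0
    df_model = 0
    for f in factors:
        ss = 0.0
        for _, grp in table.groupby(f, observed=True):
            ss += len(grp) * (grp[response].mean() - grand) ** 2
        out[f] = (ss, table[f].nunique() - 1)
        ss_model += ss
        df_model += table[f].nunique() - 1
    ss_resid = ss_total - ss_model
    df_resid = len(y) - 1 - df_model
    return {
        f: (ss / df, (ss_resid / df_resid), df, df_resid)
        for f, (ss, df) in out.items()
    }


class TestAnova:
    def test_one_way_closed_form(self):
        """Groups {1,2,3} and {2,3,4}: F = 1.5 with df (1, 4)."""
        table = pd.DataFrame(
            {"rmse": [1.0, 2, 3, 2, 3, 4], "g": ["a"] * 3 + ["b"] * 3}
        )
        rep = n_way_anova(table, factors=["g"], interactions=[])
        row = rep.loc["C(g)"]
        assert row.F == pytest.approx(1.5)
        assert (row.df, row.df_resid) == (1, 4)
        assert row.p == pytest.approx(stats.f.sf(1.5, 1, 4))

    def test_matches_brute_force_on_balanced_designs(self):
        rng = np.random.default_rng(11)
        levels = {"a": 3, "b": 2, "c": 3}
        rows = []
        for i in range(levels["a"]):
            for j in range(levels["b"]):
                for k in range(levels["c"]):
                    for _ in range(4):
                        rows.append(
                            {"a": f"a{i}", "b": f"b{j}", "c": f"c{k}",
                             "rmse": rng.normal(i * 0.5 + j - 0.2 * k, 1.0)}
                        )
        table = pd.DataFrame(rows)
        rep = n_way_anova(table, factors=["a", "b", "c"], interactions=[])
        oracle = brute_force_anova(table, "rmse", ["a", "b", "c"])
        for f in ("a", "b", "c"):
            ms_term, ms_resid, df, df_resid = oracle[f]
            assert rep.loc[f"C({f})", "F"] == pytest.approx(ms_term / ms_resid, rel=1e-8)
            assert rep.loc[f"C({f})", "df"] == df
            assert rep.loc[f"C({f})", "df_resid"] == df_resid

    def test_sums_of_squares_decomposition(self):
        """Balanced design: term SS + residual SS = total SS."""
        rng = np.random.default_rng(12)
        table = pd.DataFrame(
            {
                "a": np.repeat(["x", "y"], 12),
                "b": np.tile(np.repeat(["u", "v", "w"], 4), 2),
                "rmse": rng.normal(size=24),
            }
        )
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        fit = smf.ols("rmse ~ C(a) + C(b)", data=table).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        total = ((table.rmse - table.rmse.mean()) ** 2).sum()
        assert anova["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame(
            {
                "a": rng.choice(["x", "y", "z"], 60),
                "b": rng.choice(["u", "v"], 60),
                "rmse": rng.normal(size=60),
            }
        )
        rep1 = n_way_anova(table, factors=["a", "b"], interactions=[("a", "b")])
        rep2 = n_way_anova(
            table.sample(frac=1.0, random_state=0), factors=["a", "b"],
            interactions=[("a", "b")],
        )
        pd.testing.assert_frame_equal(rep1, rep2)

    def test_constant_response_flagged_degenerate(self):
        table = pd.DataFrame({"rmse": np.ones(12), "g": ["a", "b"] * 6})
        rep = n_way_anova(table, factors=["g"], interactions=[])
        assert rep.attrs["degenerate"] is True
        assert (rep["F"] == 0).all()

    def test_single_level_factor_rejected(self):
        table = pd.DataFrame({"rmse": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError, match="fewer than 2"):
            n_way_anova(table, factors=["g"], interactions=[])

    def test_aliased_design_rejected(self):
        # b is a copy of a: fully aliased
        table = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"],
             "rmse": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            n_way_anova(table, factors=["a", "b"], interactions=[])


class TestTukey:
    def test_identical_groups_not_significant(self):
        table = pd.DataFrame(
            {"rmse": [1.0, 2, 3, 1, 2, 3], "g": ["a"] * 3 + ["b"] * 3}
        )
        rep = tukey_hsd(table, factor="g")
        assert not rep["significant"].iloc[0]
        assert rep["mean_diff"].iloc[0] == pytest.approx(0.0)
        assert rep["ci_lower"].iloc[0] < 0 < rep["ci_upper"].iloc[0]

    def test_extreme_separation_significant(self):
        rng = np.random.default_rng(14)
        table = pd.DataFrame(
            {
                "rmse": np.r_[rng.normal(0, 0.1, 20), rng.normal(50, 0.1, 20)],
                "g": ["a"] * 20 + ["b"] * 20,
            }
        )
        rep = tukey_hsd(table, factor="g")
        assert rep["significant"].iloc[0]
        assert not (rep.ci_lower.iloc[0] < 0 < rep.ci_upper.iloc[0])

    def test_two_group_q_squared_equals_2f(self):
        """Balanced two-group case: the studentized-range statistic satisfies
        q^2 = 2F for the one-way F on the same data."""
        rng = np.random.default_rng(15)
        y = np.r_[rng.normal(0, 1, 15), rng.normal(0.8, 1, 15)]
        table = pd.DataFrame({"rmse": y, "g": ["a"] * 15 + ["b"] * 15})
        rep = n_way_anova(table, factors=["g"], interactions=[])
        f_stat = rep.loc["C(g)", "F"]
        a, b = y[:15], y[15:]
        s2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        q = abs(a.mean() - b.mean()) / np.sqrt(s2 / 15)
        assert q**2 == pytest.approx(2 * f_stat, rel=1e-10)

    def test_single_group_errors(self):
        table = pd.DataFrame({"rmse": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError, match="at least 2"):
            tukey_hsd(table, factor="g")

    def test_interval_contains_mean_diff(self):
        rng = np.random.default_rng(16)
        table = pd.DataFrame(
            {
                "rmse": rng.normal(size=60) + np.repeat([0.0, 0.5, 1.0], 20),
                "g": np.repeat(["a", "b", "c"], 20),
            }
        )
        rep = tukey_hsd(table, factor="g")
        assert ((rep.ci_lower <= rep.mean_diff) & (rep.mean_diff <= rep.ci_upper)).all()
        assert (rep.significant == ~((rep.ci_lower < 0) & (rep.ci_upper > 0))).all()
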