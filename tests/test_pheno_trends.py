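import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoscales import pheno_trends as pt


def make_table(years, values, **extra):
    df = pd.DataFrame({"year": years, "bill_mm": values})
    df["id"] = [f"b{i}" for i in range(len(df))]
    df["tarsus_mm"] = extra.get("tarsus", np.full(len(df), 20.0))
    for k, v in extra.items():
        if k != "tarsus":
            df[k] = v
    return df


class TestAnnualSummaries:
    def test_hand_arithmetic(self):
        df = make_table([2000, 2000, 2001], [10.0, 12.0, 5.0])
        s = pt.annual_summaries(df, "bill")
        assert s.loc[s.year == 2000, "mean"].item() == 11.0
        assert s.loc[s.year == 2000, "se"].item() == pytest.approx(1.0)

    def test_single_observation_year_flagged_with_zero_se(self):
        df = make_table([2000, 2001, 2001], [10.0, 1.0, 2.0])
        s = pt.annual_summaries(df, "bill")
        row = s[s.year == 2000].iloc[0]
        assert row["se"] == 0.0 and row["single_obs"] and row["n"] == 1

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError, match="trait"):
            pt.annual_summaries(make_table([2000], [1.0]), "wing")


class TestWelchT:
    def test_identical_samples(self):
        r = pt.welch_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert r.t == pytest.approx(0) and r.p == pytest.approx(1)

    def test_worked_example(self):
        r = pt.welch_t_test([1.0, 2, 3], [4.0, 5, 6])
        assert r.t == pytest.approx(-3.674, abs=5e-4)
        assert r.df == pytest.approx(4.0)

    def test_degenerate_zero_variance(self):
        same = pt.welch_t_test([2.0, 2], [2.0, 2])
        assert same.t == 0 and same.p == 1 and same.degenerate
        diff = pt.welch_t_test([2.0, 2], [3.0, 3])
        assert diff.p == 0 and diff.degenerate

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_brute_force_formula(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        if x.var(ddof=1) == 0 or y.var(ddof=1) == 0:
            return
        r = pt.welch_t_test(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        assert r.t == pytest.approx(t, rel=1e-12)
        assert r.df == pytest.approx(df, rel=1e-12)


class TestBreakpoint:
    def test_constant_series_is_null(self):
        years = np.repeat(np.arange(2000, 2012), 5)
        df = make_table(years, np.full(years.size, 7.0))
        r = pt.max_sel_breakpoint(df, "bill", n_perm=50)
        assert r.maxT == 0 and r.p == 1

    def test_exhaustive_per_cut_oracle(self):
        """Statistics match a direct standardized two-sample evaluation."""
        rng = np.random.default_rng(2)
        years = np.repeat(np.arange(2000, 2010), 8)
        vals = rng.normal(10, 1, years.size) + 0.8 * (years >= 2005)
        df = make_table(years, vals)
        r = pt.max_sel_breakpoint(df, "bill", n_perm=200, seed=1)
        n = vals.size
        m, s2 = vals.mean(), np.mean((vals - vals.mean()) ** 2)
        for _, row in r.per_cut.iterrows():
            left = vals[years <= row.cut_after_year]
            n1 = left.size
            expected = (left.sum() - n1 * m) / np.sqrt(n1 * (n - n1) * s2 / (n - 1))
            assert row.statistic == pytest.approx(expected, rel=1e-12)
        assert r.maxT == pytest.approx(np.abs(r.per_cut.statistic).max())
        assert r.best_cut == (2004, 2005)

    def test_minprop_restricts_candidate_cuts(self):
        years = np.repeat(np.arange(2000, 2010), 10)
        df = make_table(years, np.random.default_rng(0).normal(size=100))
        r = pt.max_sel_breakpoint(df, "bill", minprop=0.25, maxprop=0.75, n_perm=10)
        assert r.per_cut.n_left.min() >= 25
        assert r.per_cut.n_left.max() <= 75

    def test_location_scale_invariance_of_maxT(self):
        rng = np.random.default_rng(7)
        years = np.repeat(np.arange(2000, 2015), 6)
        vals = rng.normal(size=years.size)
        a = pt.max_sel_breakpoint(make_table(years, vals), "bill", n_perm=20, seed=0)
        b = pt.max_sel_breakpoint(
            make_table(years, 3.7 * vals + 11.0), "bill", n_perm=20, seed=0
        )
        assert a.maxT == pytest.approx(b.maxT, rel=1e-10)
        assert a.best_cut == b.best_cut

    def test_too_few_cuts_rejected(self):
        df = make_table([2000, 2001], [1.0, 2.0])
        with pytest.raises(ValueError, match="cutpoints"):
            pt.max_sel_breakpoint(df, "bill")


class TestLinearTrend:
    def test_perfect_linear_fit(self):
        years = np.repeat(np.arange(2000, 2010), 3)
        df = make_table(years, 5.0 + 0.01 * (years - 2000))
        r = pt.fit_linear_trend(df, "bill")
        assert r.slope == pytest.approx(0.01, rel=1e-9)
        assert r.residual_ss == pytest.approx(0, abs=1e-18)

    def test_partial_f_matches_two_model_ss_oracle(self):
        """F for the year term equals the residual-SS ratio of nested models."""
        years = np.array([2000, 2000, 2001, 2001, 2002, 2002])
        bill = np.array([10.0, 10.4, 10.3, 10.9, 10.8, 11.4])
        tarsus = np.array([20.0, 20.5, 20.1, 20.8, 20.2, 21.0])
        df = make_table(years, bill, tarsus=tarsus)
        r = pt.fit_linear_trend(df, "bill", covariate="tarsus")
        X_full = np.column_stack([np.ones(6), years, tarsus])
        X_null = np.column_stack([np.ones(6), tarsus])
        rss = lambda X: np.sum(
            (bill - X @ np.linalg.lstsq(X, bill, rcond=None)[0]) ** 2
        )
        f_oracle = (rss(X_null) - rss(X_full)) / (rss(X_full) / (6 - 3))
        assert r.F == pytest.approx(f_oracle, rel=1e-9)
        assert r.covariate_used and r.df_num == 1 and r.df_den == 3

    def test_constant_covariate_matches_no_covariate_f(self):
        rng = np.random.default_rng(3)
        years = np.repeat(np.arange(2000, 2008), 4)
        df = make_table(years, rng.normal(10, 1, years.size))
        with pytest.raises(ValueError, match="collinear|degenerate"):
            # constant tarsus column is collinear with the intercept
            pt.fit_linear_trend(df, "bill", covariate="tarsus")
        no_cov = pt.fit_linear_trend(df, "bill")
        assert no_cov.F >= 0

    def test_range_too_short_rejected(self):
        df = make_table([2000, 2001], [1.0, 2.0])
        with pytest.raises(ValueError, match="3 distinct years"):
            pt.fit_linear_trend(df, "bill")


class TestSlopeScan:
    def test_window_count_matches_closed_form(self):
        years = np.repeat(np.arange(1982, 2008), 2)  # 26 years
        df = make_table(years, np.random.default_rng(1).normal(size=years.size))
        r = pt.slope_scan(df, "bill", min_len=10, max_len=25)
        assert len(r.windows) == sum(27 - l for l in range(10, 26)) == 152

    @pytest.mark.parametrize("n_years,min_len,max_len", [(15, 5, 12), (30, 10, 25)])
    def test_window_count_general(self, n_years, min_len, max_len):
        years = np.arange(2000, 2000 + n_years)
        df = make_table(np.repeat(years, 2), np.random.default_rng(0).normal(size=2 * n_years))
        r = pt.slope_scan(df, "bill", min_len=min_len, max_len=max_len)
        expected = sum(
            n_years - l + 1 for l in range(min_len, min(max_len, n_years) + 1)
        )
        assert len(r.windows) == expected

    def test_monotone_series_gives_single_sign(self):
        years = np.repeat(np.arange(1982, 2008), 2)
        df = make_table(years, 1.0 + 0.02 * (years - 1982))
        r = pt.slope_scan(df, "bill")
        assert (r.windows.slope > 0).all()

    def test_early_plateau_then_decline_pattern(self, pheno_series):
        """Windows with early years lean positive; without, negative."""
        r = pt.slope_scan(pheno_series, "bill")
        w = r.windows
        with_early = w[w.contains_early_years]
        without = w[~w.contains_early_years]
        assert (with_early.slope > 0).mean() >= 0.8
        assert (without.slope < 0).mean() >= 0.8


class TestAnovaTukey:
    @staticmethod
    def museum_table(seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for site, shift in [("UK", 0.6), ("FR", 0.0), ("IT", 0.05), ("NL", -0.05)]:
            for sex in ("F", "M"):
                vals = rng.normal(13.2 + shift, 0.4, 30)
                rows += [
                    {"bill_mm": v, "tarsus_mm": 20.0, "site": site, "sex": sex,
                     "year": 1950, "id": f"{site}{sex}{i}"}
                    for i, v in enumerate(vals)
                ]
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_f(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        df = pd.DataFrame(
            {
                "bill_mm": vals,
                "tarsus_mm": 20.0,
                "site": ["A"] * 4 + ["B"] * 4,
                "sex": ["F", "M"] * 4,
                "year": 1900,
                "id": [str(i) for i in range(8)],
            }
        )
        r = pt.anova_tukey(df, "bill", factors=("site", "sex"))
        f_site = r.table.loc[r.table.factor == "site", "F"].item()
        assert f_site == pytest.approx(0, abs=1e-12)

    def test_f_matches_hand_sums_of_squares(self):
        """One-factor-at-a-time check against explicit between/within SS."""
        df = pd.DataFrame(
            {
                "bill_mm": [1.0, 2, 3, 2, 3, 4, 6, 7, 8],
                "tarsus_mm": 20.0,
                "site": ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                "sex": ["F", "M", "F"] * 3,
                "year": 1900,
                "id": [str(i) for i in range(9)],
            }
        )
        import statsmodels.formula.api as smf
        import statsmodels.api as sm

        fit = smf.ols("bill_mm ~ C(site)", data=df).fit()
        y = df["bill_mm"].to_numpy()
        grand = y.mean()
        between = sum(
            3 * (y[i : i + 3].mean() - grand) ** 2 for i in (0, 3, 6)
        )
        within = sum(((y[i : i + 3] - y[i : i + 3].mean()) ** 2).sum() for i in (0, 3, 6))
        f_hand = (between / 2) / (within / 6)
        f_lib = sm.stats.anova_lm(fit).loc["C(site)", "F"]
        assert f_lib == pytest.approx(f_hand, rel=1e-10)

    def test_country_significant_sex_not_with_letter_groups(self):
        df = self.museum_table()
        r = pt.anova_tukey(df, "bill", factors=("site", "sex"))
        p_site = r.table.loc[r.table.factor == "site", "p"].item()
        p_sex = r.table.loc[r.table.factor == "sex", "p"].item()
        assert p_site < 1e-4 and p_sex > 0.05
        assert r.tukey_factor == "site"
        # the shifted site gets its own letter, disjoint from the others
        uk = set(r.letters["UK"])
        for other in ("FR", "IT", "NL"):
            assert uk.isdisjoint(set(r.letters[other]))

    def test_single_level_factor_rejected(self):
        df = self.museum_table()
        df["sex"] = "F"
        with pytest.raises(ValueError, match="2 levels"):
            pt.anova_tukey(df, "bill", factors=("site", "sex"))
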