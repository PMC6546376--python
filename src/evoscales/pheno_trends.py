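"""Time-scale-sensitive analysis of an individual-level phenotype series.

Designed for long-term morphometric monitoring data (one record per bird per
year, e.g. bill and tarsus length in mm): detection of an abrupt level shift
by a maximally selected two-sample statistic with a permutation null,
Welch's t contrast across the detected cut, partial-F linear trends with or
without an allometric covariate, an exhaustive scan of OLS slopes over all
consecutive-year windows, LOESS smoothing of annual means, and a two-way
ANOVA with Tukey HSD grouping for spatial (museum-style) comparisons.

All analyses operate on individual records; annual summaries are
presentational.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._smoothing import loess

__all__ = [
    "trait_values",
    "annual_summaries",
    "welch_t_test",
    "max_sel_breakpoint",
    "fit_linear_trend",
    "slope_scan",
    "loess_smooth",
    "anova_tukey",
    "TTestResult",
    "BreakpointResult",
    "TrendFit",
    "SlopeScanResult",
    "AnovaResult",
]

TRAITS = ("bill", "tarsus", "ratio")


def trait_values(data: pd.DataFrame, trait: str) -> pd.Series:
    """Per-individual values of ``bill``, ``tarsus`` or their ``ratio``."""
    if trait == "bill":
        col = data["bill_mm"]
    elif trait == "tarsus":
        col = data["tarsus_mm"]
    elif trait == "ratio":
        col = data["bill_mm"] / data["tarsus_mm"]
    else:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    if col.isna().any():
        raise ValueError(f"trait {trait!r} has missing values")
    return col


def annual_summaries(data: pd.DataFrame, trait: str = "bill") -> pd.DataFrame:
    """Per-year n, mean and standard error (sd/sqrt(n); 0 when n = 1).

    Returns a DataFrame with columns year, n, mean, se, single_obs.
    """
    vals = trait_values(data, trait)
    g = vals.groupby(data["year"])
    out = pd.DataFrame(
        {
            "year": sorted(g.groups),
            "n": g.count().values,
            "mean": g.mean().values,
            "se": (g.std(ddof=1) / np.sqrt(g.count())).fillna(0.0).values,
        }
    )
    out["single_obs"] = out["n"] == 1
    return out


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t_test(x, y) -> TTestResult:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided p.

    Degenerate zero-variance inputs are handled explicitly: equal-mean
    constant samples give t = 0, p = 1; unequal-mean constant samples give
    p = 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, float(x.size + y.size - 2), 1.0, degenerate=True)
        sign = np.sign(x.mean() - y.mean())
        return TTestResult(
            float(sign * np.inf), float(x.size + y.size - 2), 0.0, degenerate=True
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


@dataclass
class BreakpointResult:
    best_cut: tuple[int, int]          # (last year before, first year after)
    maxT: float
    p: float
    per_cut: pd.DataFrame              # cut_after_year, statistic, n_left
    ties: list[tuple[int, int]] = field(default_factory=list)
    n_perm: int = 0


def _cut_statistics(values: np.ndarray, cut_sizes: np.ndarray) -> np.ndarray:
    """Standardized two-sample linear statistic at each left-group size.

    T(cut) = (S_left - n1 m) / sqrt(n1 n2 / (N-1) * sigma2) with
    sigma2 = mean((x - m)^2): the permutation-standardized difference in
    means, as used by maximally selected two-sample statistics.
    """
    n = values.size
    m = values.mean()
    sigma2 = np.mean((values - m) ** 2)
    csum = np.cumsum(values)
    n1 = cut_sizes
    n2 = n - n1
    s_left = csum[n1 - 1]
    var = n1 * n2 * sigma2 / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (s_left - n1 * m) / np.sqrt(var)
    return t


def max_sel_breakpoint(
    data: pd.DataFrame,
    trait: str = "bill",
    minprop: float = 0.1,
    maxprop: float = 0.9,
    n_perm: int = 10_000,
    seed: int = 0,
) -> BreakpointResult:
    """Maximally selected two-sample statistic over between-year cutpoints.

    Candidate cuts are year boundaries leaving at least ``minprop`` and at
    most ``maxprop`` of the observations on the left; a year is never split.
    maxT is the maximum absolute standardized statistic and the p-value is
    the permutation fraction (with the +1 correction) of shuffled-label maxT
    values at least as large, over ``n_perm`` permutations.
    """
    vals = trait_values(data, trait).to_numpy(dtype=float)
    years = data["year"].to_numpy()
    order = np.argsort(years, kind="stable")
    vals, years = vals[order], years[order]
    n = vals.size
    uyears, year_counts = np.unique(years, return_counts=True)
    bound_sizes = np.cumsum(year_counts)[:-1]  # obs left of each year boundary
    ok = (bound_sizes >= minprop * n) & (bound_sizes <= maxprop * n)
    cut_sizes = bound_sizes[ok]
    cut_years = uyears[:-1][ok]
    if cut_sizes.size < 2:
        raise ValueError("fewer than 2 eligible cutpoints")
    if np.ptp(vals) == 0:
        per_cut = pd.DataFrame(
            {"cut_after_year": cut_years, "statistic": 0.0, "n_left": cut_sizes}
        )
        first = (int(cut_years[0]), int(_next_year(uyears, cut_years[0])))
        return BreakpointResult(first, 0.0, 1.0, per_cut, n_perm=n_perm)

    t_obs = _cut_statistics(vals, cut_sizes)
    abs_t = np.abs(t_obs)
    max_t = float(abs_t.max())
    tie_idx = np.where(np.isclose(abs_t, max_t, rtol=0, atol=1e-12))[0]
    ties = [
        (int(cut_years[i]), int(_next_year(uyears, cut_years[i]))) for i in tie_idx
    ]
    best = ties[0]  # earliest boundary on exact ties

    rng = np.random.default_rng(seed)
    exceed = 0
    block = 512
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perm = rng.permuted(np.broadcast_to(vals, (b, n)), axis=1)
        csum = np.cumsum(perm, axis=1)
        m = vals.mean()
        sigma2 = np.mean((vals - m) ** 2)
        n1 = cut_sizes
        var = n1 * (n - n1) * sigma2 / (n - 1)
        t_perm = (csum[:, n1 - 1] - n1 * m) / np.sqrt(var)
        exceed += int((np.abs(t_perm).max(axis=1) >= max_t - 1e-12).sum())
        done += b
    p = (exceed + 1) / (n_perm + 1)
    per_cut = pd.DataFrame(
        {"cut_after_year": cut_years, "statistic": t_obs, "n_left": cut_sizes}
    )
    return BreakpointResult(best, max_t, float(p), per_cut, ties, n_perm)


def _next_year(uyears: np.ndarray, year) -> int:
    i = int(np.searchsorted(uyears, year))
    return int(uyears[i + 1])


@dataclass
class TrendFit:
    slope: float
    F: float
    p: float
    covariate_used: bool
    df_num: int
    df_den: int
    intercept: float = float("nan")
    residual_ss: float = float("nan")


def fit_linear_trend(
    data: pd.DataFrame,
    trait: str = "bill",
    start_year: int | None = None,
    end_year: int | None = None,
    covariate: str | None = None,
    annual_means: bool = False,
) -> TrendFit:
    """OLS fit of a trait on calendar year over individual records.

    ``F`` is the partial F for dropping the year term (the squared year
    t-statistic, 1 numerator df), so the fit answers "is there a time trend"
    both with and without the covariate (usually ``tarsus``) in the model.
    With ``annual_means=True`` the regression uses yearly means instead of
    individual records (an option for ratio-style analyses).
    """
    d = data
    if start_year is not None:
        d = d[d["year"] >= start_year]
    if end_year is not None:
        d = d[d["year"] <= end_year]
    if d["year"].nunique() < 3:
        raise ValueError("need at least 3 distinct years in range")
    y = trait_values(d, trait).to_numpy(dtype=float)
    year = d["year"].to_numpy(dtype=float)
    if annual_means:
        df_means = pd.DataFrame({"year": year, "y": y}).groupby("year").mean()
        year = df_means.index.to_numpy(dtype=float)
        y = df_means["y"].to_numpy()
    cols = [np.ones_like(year), year]
    if covariate is not None:
        if annual_means:
            raise ValueError("covariate adjustment requires individual records")
        cov = trait_values(d, covariate).to_numpy(dtype=float)
        cols.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate (collinear) design matrix")
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    t_year = fit.tvalues[1]
    F = float(t_year**2)
    return TrendFit(
        slope=float(fit.params[1]),
        F=F,
        p=float(fit.pvalues[1]),
        covariate_used=covariate is not None,
        df_num=1,
        df_den=int(fit.df_resid),
        intercept=float(fit.params[0]),
        residual_ss=float(fit.ssr),
    )


@dataclass
class SlopeScanResult:
    windows: pd.DataFrame  # start_year, end_year, length, slope, contains_early_years
    min_len: int
    max_len: int
    early_years: tuple[int, ...]


def slope_scan(
    data: pd.DataFrame,
    trait: str = "bill",
    min_len: int = 10,
    max_len: int = 25,
    early_years: set[int] | None = None,
) -> SlopeScanResult:
    """OLS slope for every window of consecutive observed years with length
    in ``[min_len, max_len]``.

    Each window is labelled by whether it contains any "early" year; by
    default the first five years of the series (for the great tit record,
    1982–1986).  A series of ``Y`` years yields ``sum_{l} (Y - l + 1)``
    windows.
    """
    vals = trait_values(data, trait).to_numpy(dtype=float)
    years = data["year"].to_numpy()
    uyears = np.unique(years)
    n_years = uyears.size
    if n_years <= min_len:
        raise ValueError("series must be longer than min_len years")
    if early_years is None:
        early = set(int(y) for y in uyears[:5])
    else:
        early = set(int(y) for y in early_years)
    rows = []
    for length in range(min_len, min(max_len, n_years) + 1):
        for i0 in range(n_years - length + 1):
            span = uyears[i0 : i0 + length]
            mask = (years >= span[0]) & (years <= span[-1])
            yy = years[mask].astype(float)
            vv = vals[mask]
            if vv.size == 0:
                continue
            slope = np.polyfit(yy, vv, 1)[0]
            rows.append(
                {
                    "start_year": int(span[0]),
                    "end_year": int(span[-1]),
                    "length": length,
                    "slope": float(slope),
                    "contains_early_years": bool(early & set(int(y) for y in span)),
                }
            )
    return SlopeScanResult(
        pd.DataFrame(rows), min_len, max_len, tuple(sorted(early))
    )


def loess_smooth(x, y, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Tricube-weighted local polynomial fit evaluated at the observed x."""
    return loess(np.asarray(x, float), np.asarray(y, float), span=span, degree=degree)


@dataclass
class AnovaResult:
    table: pd.DataFrame       # per-factor F, df, p (type-II sums of squares)
    tukey: pd.DataFrame | None
    letters: dict[str, str] | None
    tukey_factor: str | None


def anova_tukey(
    data: pd.DataFrame,
    trait: str = "bill",
    factors: tuple[str, str] = ("site", "sex"),
    alpha: float = 0.05,
    tukey_factor: str | None = None,
) -> AnovaResult:
    """Two-way additive ANOVA plus Tukey HSD with a compact letter display.

    Tukey HSD is run on ``tukey_factor`` (default: the factor with the
    smaller ANOVA p-value); levels sharing a letter are not significantly
    different at ``alpha``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    d = pd.DataFrame({"y": trait_values(data, trait).to_numpy(dtype=float)})
    for f in factors:
        lv = data[f].astype(str)
        if lv.isna().any() or (lv.groupby(lv).count() < 1).any():
            raise ValueError(f"factor {f!r} has empty levels")
        if lv.nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
        d[f] = lv.to_numpy()
    formula = "y ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=d).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    table = pd.DataFrame(
        {
            "factor": [f for f in factors],
            "F": [float(aov.loc[f"C({f})", "F"]) for f in factors],
            "df": [float(aov.loc[f"C({f})", "df"]) for f in factors],
            "p": [float(aov.loc[f"C({f})", "PR(>F)"]) for f in factors],
        }
    )
    if tukey_factor is None:
        tukey_factor = table.sort_values("p")["factor"].iloc[0]
    res = pairwise_tukeyhsd(d["y"], d[tukey_factor], alpha=alpha)
    tk = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    letters = _compact_letter_display(tk, d, tukey_factor)
    return AnovaResult(table, tk, letters, tukey_factor)


def _compact_letter_display(tukey_df, d, factor) -> dict[str, str]:
    """Letters from maximal cliques of the 'not significantly different' graph."""
    import networkx as nx

    groups = sorted(d[factor].unique())
    g = nx.Graph()
    g.add_nodes_from(groups)
    for _, row in tukey_df.iterrows():
        if not row["reject"]:
            g.add_edge(str(row["group1"]), str(row["group2"]))
    cliques = list(nx.find_cliques(g))
    means = d.groupby(factor)["y"].mean()
    cliques.sort(key=lambda c: means[list(c)].mean(), reverse=True)
    letters = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("A") + i)
        for grp in clique:
            letters[grp] += letter
    return {g_: "".join(sorted(v)) for g_, v in letters.items()}
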