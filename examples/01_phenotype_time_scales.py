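"""Detect an abrupt shift in a long-term phenotype series and show how the
inferred trend depends on the time window analysed.

Generates the default synthetic 26-year bill/tarsus record (a +0.45 mm level
shift in 1987 on top of a slow -0.011 mm/yr decline), then runs the
breakpoint scan, the cross-cut Welch test, and linear trends over the full
and post-shift ranges.
"""

from evoscales import pheno_trends as pt
from evoscales.synthetic_data import PhenoSimConfig, generate_phenotypes

df = generate_phenotypes(PhenoSimConfig(seed=4))
print(f"{len(df)} records, {df.year.min()}-{df.year.max()}")

bp = pt.max_sel_breakpoint(df, "bill", n_perm=5000, seed=1)
print(
    f"best cutpoint between {bp.best_cut[0]} and {bp.best_cut[1]}: "
    f"maxT = {bp.maxT:.2f}, permutation p = {bp.p:.2g}"
)

vals = pt.trait_values(df, "bill")
w = pt.welch_t_test(vals[df.year <= bp.best_cut[0]], vals[df.year > bp.best_cut[0]])
print(f"early vs late years: Welch t = {w.t:.2f}, df = {w.df:.1f}, p = {w.p:.2g}")

full = pt.fit_linear_trend(df, "bill")
post = pt.fit_linear_trend(df, "bill", start_year=bp.best_cut[1])
ratio = pt.fit_linear_trend(df, "ratio", start_year=bp.best_cut[1])
print(f"full-range slope:  {full.slope:+.4f} mm/yr (F = {full.F:.1f}, p = {full.p:.2g})")
print(f"post-cut slope:    {post.slope:+.4f} mm/yr (F = {post.F:.1f}, p = {post.p:.2g})")
print(f"bill/tarsus ratio post-cut: F = {ratio.F:.2f}, p = {ratio.p:.2f}")

# The sign of the trend flips once the pre-shift years are excluded: the
# full-range regression is dominated by the one-off level shift, while the
# post-shift record actually declines.  The flat ratio trend says bill and
# tarsus moved together (allometry conserved), i.e. no bill-specific change.
scan = pt.slope_scan(df, "bill")
w_ = scan.windows
with_early = w_[w_.contains_early_years]
without = w_[~w_.contains_early_years]
print(
    f"slope scan over {len(w_)} windows of 10-25 consecutive years: "
    f"{(with_early.slope > 0).mean():.0%} positive with early years, "
    f"{(without.slope < 0).mean():.0%} negative without them"
)
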