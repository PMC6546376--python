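# Methods

## Phenotype series model and analyses

The synthetic phenotype generator draws one (bill, tarsus) pair per bird per
year from a bivariate normal with year-specific means

```
mean(t) = mean0 + slope·(t − t0) + step·1[t ≥ step_year]
```

and constant SDs and correlation ρ. Defaults emulate a 26-year (1982–2007)
great tit record: 30 birds/year; bill 13.2 mm, SD 0.45, tarsus 19.2 mm, SD
0.60, ρ = 0.5; a +0.45 mm bill step in 1987 on top of a −0.011 mm/yr
decline, with tarsus values scaled by the 19.2/13.2 allometry so the
bill/tarsus ratio has no temporal signal. The decline magnitude is anchored
to the reported post-1987 trend strength (a partial F ≈ 13 over 21 years at
this sampling implies |slope| ≈ 0.011 mm/yr); the step size then keeps the
full-range regression positive and the early-vs-late Welch |t| ≈ 7. The
generator is a study-condition emulator, not an estimator: real records have
unequal yearly sample sizes, repeated measures of individuals, observer and
site effects, and non-normal tails, none of which are modelled — so passing
tests establish the *methods* behave correctly under the idealized
conditions, not that the defaults describe any real population.

**Breakpoint (maxT).** Candidate cuts are between-year boundaries keeping at
least `minprop = 0.1` and at most `maxprop = 0.9` of the observations on the
left; a year is never split. The per-cut statistic is the
permutation-standardized two-sample sum
`T = (S_left − n₁x̄)/√(n₁n₂σ̂²/(N−1))` with `σ̂² = Σ(x−x̄)²/N`; `maxT` is the
maximum absolute value, its p-value the fraction of label permutations
(default 10,000; +1 correction) whose maxT is at least the observed one.
Exact ties on maxT report the earliest boundary and list all tied cuts. This
permutation formulation is exact at any sample size; its type-I error is
verified at α = 0.05 over 500 null series.

**Trends.** Individual-level OLS of trait on calendar year, optionally with
tarsus as covariate; the reported F is the partial F for the year term
(squared year t-statistic), so "with covariate" and "without" answer the
same question about time. The allometry analysis fits the per-individual
bill/tarsus ratio (an annual-means mode exists for comparison).
Analyses always run on individual records; annual summaries (mean ± SE) are
presentational.

**Slope scan.** One OLS slope per window of `min_len=10` to `max_len=25`
consecutive observed years — `Σ_l (Y−l+1)` windows, 152 for a 26-year
series — each labelled by whether it contains an "early" year (default: the
first five years of the series).

**LOESS.** Tricube-weighted local polynomials (default degree 2, span 0.75,
`ceil(span·n)` nearest neighbours, no robustness iterations); reproduces
global polynomials of its degree exactly, which the tests exploit.

**ANOVA + Tukey.** Two-way additive ANOVA (type-II SS via statsmodels) over,
e.g., country and sex; Tukey HSD on the factor of interest, with a compact
letter display built from maximal cliques of the "not significantly
different" graph.

## Genome-scan statistics

All coordinates are 0-based bp; windows are half-open `[start, start+size)`;
window midpoints are the plotting/track coordinate; VCF's 1-based convention
is converted at I/O only.

- **LD**: haplotype r² (squared allele-column correlation) is the primary
  dialect; a genotype-dosage r² is provided for unphased input and labelled
  in track metadata. The decay curve averages r² in log-spaced distance bins
  (empty bins are missing, not zero); the long-distance track averages r²
  over pairs separated by 20–200 kb, assigned to 200 kb windows (50 kb step)
  by pair midpoint. MAF filter 0.05 by default.
- **Hudson FST** per SNP with the finite-sample numerator correction; raw
  (possibly negative) values are kept — clamping would bias window means.
- **eigenGWAS**: k = 1 leading eigenvector of the GRM built from
  `(d − 2p)/√(2p(1−p))`-standardized dosages (missing → 0 after centering);
  per-SNP 1-df χ² from OLS of the eigenvector on the SNP; genomic control
  by the χ²₁ median (0.4549). Both raw and GC-corrected p are reported.
  Note that when the same SNPs build the eigenvector and are tested against
  it, the null χ² is inflated toward the Marchenko–Pastur edge
  `(1+√(n/m))²`; λ_GC absorbs exactly this, which is why corrected p-values
  are uniform under panmixia while λ itself sits well above 1 unless
  m ≫ n.
- **EHHS/iES**: EHHS(0) = 1 by definition; beyond zero distance the
  partition includes the focal site's own alleles and every site up to x.
  iES integrates EHHS by trapezoid over bp in both directions, truncating
  at the first point below 0.05; a curve still above threshold at the last
  site is extended at its final value to the chromosome edge (so a fully
  homozygous sample integrates to the chromosome length). Values are per
  Mb; sites with no integrable support are missing.
- **π**: per-site pairwise-difference rates summed per window and divided
  by the window's own length (truncated end windows use theirs); no MAF
  filter, monomorphic positions count zero, so length-weighted window π
  sums to chromosome π exactly.
- **Smoothing**: LOESS along position with the span chosen so the local
  window covers a target width — 1 Mb on a 20 Mb chromosome, and
  chromosome/20 in the replicated experiment so the smoother scales with a
  scaled-down design; a Gaussian-kernel alternative is available.

## Forward simulation

Single panmictic diploid Wright–Fisher population, constant size N,
non-overlapping generations. Each generation: parent sampling proportional
to multiplicative fitness across selected sites (heterozygote `1+hs`,
homozygote `1+s`; log-space accumulation, abort with a diagnostic if even
the fittest genotype would underflow); per-gamete crossover counts
Poisson(map Morgans) with breakpoint density proportional to local rate;
per-gamete mutations Poisson(μL) at discrete uniform positions re-drawn on
collision (infinite-sites); fixed and lost mutations pruned, fixations kept
in a substitution log. DFE: fraction `p_deleterious` of mutations at
`s_mean < 0` (optionally gamma-distributed magnitudes), dominance h, rest
strictly neutral; no beneficial mutations by design. Runs are fully
deterministic given the seed, and the numba bit-packed engine and the dense
NumPy reference path consume the identical random stream (a test asserts
bit-identical samples).

**Scales.** Full-scale design: N = 5,000, 20 Mb, μ = r = 1e-8/bp, central
1.6 Mb coldspot at 1% recombination, p_del = 0.3, s = −0.02, h = 0.25,
burn-in 10N. The desk-scale preset used by the replicated experiment and
the validation suite shortens the chromosome to 5 Mb (coldspot 400 kb, same
proportion) and rescales by Q = 10 (N = 500, burn-in 5,000 generations,
s = −0.2), preserving Nμ, Nr, Ns; one replicate of 5,000 generations plus
its scan statistics takes ~30 s on one CPU, and 100 sampled haplotypes
carry ~2,300–5,300 segregating sites. Neutral-validation runs use smaller
single-purpose designs: π vs 4Nμ at N = 100, 400 kb, θ = 2e-4/bp (10
seeds); the site-frequency spectrum at N = 100, 2 Mb with sparse mutations
(μ = 1e-7) and strong recombination between sites (r = 1e-5, ρ·spacing
≈ 100), because a χ² goodness-of-fit on SFS counts pooled over tightly
linked sites is anti-conservative — sites must carry near-independent
genealogies for the test's assumptions to hold; fixation-probability checks
use a single locus at N = 20 with seeded standing variants and mutation
off.

**Coldspot contrast.** For each replicate the pipeline computes windowed π
(200 kb / 50 kb step), the long-distance LD track, iES per site, and the
eigenGWAS −log10 p of the sample's own leading eigenvector (the single-
population reading), smooths each track, and compares the mean inside the
coldspot against the flanks beyond a 200 kb margin (the margin excludes
positions whose statistics straddle the boundary). Across 10 replicates of
the desk preset, background selection yields lower coldspot π and higher
long-distance r², iES and eigenGWAS significance in ≥ 9/10 replicates for
the diversity and LD statistics; the eigenGWAS direction holds in ~8/10 —
with only 50 sampled individuals and ~1,100 SNPs the leading eigenvector
aligns with the coldspot haplotype clades with probability ≈ 0.8 per
replicate, a small-sample limitation of the scaled-down design rather than
of the statistic. The neutral control (p_del = 0) abolishes the π
reduction (ratio CI covers 1) but *not* the LD, iES or eigenGWAS
elevations: long haplotypes in a coldspot are a property of reduced
recombination alone, which is precisely why such regions can mimic sweeps.

## Numerical and design notes

- Random numbers: one master seed per pipeline; per-stage and per-replicate
  seeds derived via `SeedSequence.spawn` (all < 2³¹), recorded in the run
  manifest; re-running from a manifest reproduces outputs byte-for-byte.
- Welch's t is used for the epoch contrast (fractional Satterthwaite df);
  degenerate zero-variance inputs are handled explicitly.
- Breakpoint candidate cuts need ≥ 2 eligible boundaries; a zero-variance
  series reports maxT = 0, p = 1.
- Haplotype matrices validate binary alleles and strictly increasing
  positions; genotype dosages use −1 for missing, excluded from all allele
  counts.
- Known limitations: no demography (bottlenecks, migration, two-population
  divergence comes from the Balding–Nichols generator, not the forward
  engine); no beneficial-mutation or sweep mode; no gene structure or
  annotation-dependent DFE; LD statistics assume phased input (the genotype
  dialect is a fallback, not an equivalent); the museum-style ANOVA ignores
  collection-date weighting.
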