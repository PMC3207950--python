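# Methods

## Problem and data model

Bulk segregant analysis (BSA) maps quantitative trait loci by sequencing
two pooled DNA samples drawn from the phenotypic extremes of a
segregating population. At every biallelic site the data are a 2×2 table
of read counts: low/high bulk × high-/low-parent allele. Without a
nearby QTL the two bulks have the same expected allele frequency; near a
QTL they diverge.

Two levels of sampling separate the true F2 allele frequency from the
observed read counts:

1. **bulk composition** — each bulk holds `a` effective alleles
   (`a = 2n` for a diploid bulk of `n` F2 segregants, `a = n` when
   segregants are homozygous diploids), so the realised bulk frequency
   is a binomial draw around the expectation;
2. **sequencing** — each allele count is modelled as an independent
   Poisson draw whose mean is the per-bulk coverage `C` times the
   realised allele-class frequency.

## The statistics

**G** is the likelihood-ratio goodness-of-fit statistic of the 2×2
table, `G = 2 Σ O ln(O/E)` with margin-based expected counts and
`0·ln 0 = 0`. It grows linearly with depth at fixed frequencies, so it
carries strength of evidence, unlike a raw allele-frequency difference.

**G′** is the Nadaraya–Watson kernel average of G over all sites within
a half-bandwidth `W` of the focal site, with tricube weights
`(1 − D³)³`, `D = distance/W`. True QTL signal is shared between linked
sites while Poisson depth noise is not, so the average acts as a
low-pass filter. Chromosomes are smoothed independently; each series is
extended by reflection about its terminal sites before smoothing and
trimmed afterwards, which makes a constant series an exact fixed point
at the edges.

## Null theory

A delta-method treatment of the statistic under the two-level null
(both expectations equal, Poisson totals) gives

    E[G]   = 1 + C/a
    Var[G] = 2 (1 + C/a)²
    Cov(G_i, G_j) = 2 (C/a)² (1 − 2 r_ij)²

with `r_ij` the recombination fraction between sites (Haldane's map
function, `r = (1 − e^(−2d/100))/2` for `d` in cM, is used throughout —
the standard no-interference choice, shared with the simulator). The
covariance arises because bulk-composition noise is common to linked
sites with linkage-disequilibrium correlation `(1 − 2r)`, while
sequencing noise is site-independent. When `C ≪ a` the moments collapse
to the chi-square(1) values (1, 2); when `C ≳ a` the naive chi-square
test becomes strongly anti-conservative. The smoothed statistic
inherits `E[G′] = E[G]` and

    Var[G′] = Σ_j k_j² Var[G] + Σ_{j≠l} k_j k_l Cov(G_j, G_l).

At this order of approximation the null frequency `p0` cancels between
the numerator and the estimated margins, so segregation distortion does
not alter the null moments; `p0` is still accepted by `DesignParams`
for interface completeness and for designs whose observed frequencies
are interpreted against a distorted baseline. A `sequencing_only` mode
covers the fixed-bulks case (technical replicates of one pool), where
`G ~ χ²(1)` iid and `Var[G′] = 2 Σ k²`.

The right tail of G′ is approximated by a log-normal matched to
(E[G′], Var[G′]) via `σ² = ln(1 + var/mean²)`,
`μ = ln(mean²/√(var + mean²))`; scan p-values are its upper tail.

## Robust empirical null

Real scans mix null regions with QTL contamination in the right tail.
The null parameters are estimated robustly from `x = ln G′`: spread by
the **left MAD** (deviations at or below the median only, scaled by
1.4826), upper outliers flagged by **Hampel's rule** (`x > median +
5.2·leftMAD`), and `(μ, σ)` recovered from the trimmed sample through
the log-normal identities `median = e^μ`, `mode = e^(μ−σ²)`, with the
mode estimated on the unlogged values. This is the only reading under
which the median and mode jointly identify both parameters: the median
and mode of the *logs* coincide for a normal and cannot yield σ.

The default mode estimator is the half-sample mode (iterated shortest
half, ties to the lower-indexed half) for determinism and a 50%
breakdown point; a histogram mode is available. Mode estimators
converge at roughly n^(−1/3), so the σ estimate is noisy on scans of a
few thousand sites (relative error of order 10% even at 10⁵ sites for
small σ); μ, in contrast, recovers to well under 1%. The procedure errs
conservative under contamination because the contaminated median sits
right of the null centre.

## Region calling

Per-site log-normal p-values are corrected by Benjamini–Hochberg
(default FDR 0.01, as in genome-scale practice) and candidate QTL
regions are maximal runs of consecutive significant sites per
chromosome (no gap tolerance by default; `max_gap_sites` can bridge
isolated holes). The region peak is the leftmost in-region maximum of
G′.

## Bandwidth choice

The expected G′ profile around a QTL is modelled by attenuating the
at-QTL bulk frequencies toward the null frequency through `(1 − 2r)`
and evaluating the large-count divergence `2C Σ_bulks [p ln(p/p0) +
q ln(q/q0)]` on top of the `1 + C/a` baseline. For a causal allele
fixed in one bulk and at 0.5 in the other, the half-width at
half-maximum is 12.42 cM (FWHM ≈ 24.8 cM). Matched-filter reasoning
sets the default recommendation at a full window of ~30 cM (smoothing
ratio 1–1.5) for isolated peaks, and ~0.7 × FWHM ≈ 17 cM when adjacent
peaks must stay separable. Physical windows use a single user-supplied
cM/kb rate; regional recombination maps are out of scope.

## Simulator

`simulate_f2_bulks` realises the generative model exactly as the null
theory assumes it: Mendelian QTL genotypes (¼, ½, ¼) with additive
values (−δ/2, 0, +δ/2), unit-variance Gaussian residuals, truncation
selection of the `n` lowest and `n` highest phenotypes out of `N`,
marker haplotypes built outward from the QTL allele as a Markov chain
with Haldane interval recombination (independent intervals and
independent gametes — no crossover interference), and independent
Poisson counts per allele class. Homozygous designs double one gamete
per individual. All randomness flows through one injectable
`numpy.random.Generator`; fixed seeds reproduce scans bit-identically.

The default `SimDesign` encodes the package's reference study
conditions: `N = 1000`, `n = 150` per tail (15%, inside the 10–20%
bulk-fraction recommendation), `C = 50`, a 10 cM chromosome with 25
SNPs/cM, QTL at the central marker, and a tricube half-bandwidth of
5 cM for smoothing. The "weak QTL" scenario sets δ so the locus
explains exactly 2% of phenotypic variance (δ ≈ 0.404). Truncation-
selection theory (`Δp = i·p·q·α`, `i = φ(x)/p`) provides the
closed-form cross-check for the simulated selection response.

What the simulator does *not* emulate: variable SNP spacing, mapping
or base-calling bias, index hopping, overdispersed coverage, multiple
or linked QTLs, and interference in recombination. Calibration results
therefore show the behaviour of the statistics under the idealised
hierarchical model, not under every pathology of real sequencing data —
which is precisely why the robust empirical null exists.

## Calibration drivers and problem sizes

`run_null_calibration` scores the central SNP of each null replicate
three ways: naive chi-square(1) on raw G, the theoretical log-normal
null of G′, and the robust empirical null fitted to the focal G′ values
pooled across replicates (a proper iid sample from the null; a
per-replicate variant exists but is extremely conservative on a single
short chromosome because scan values are strongly autocorrelated).
`run_power` reports causal-site means and significant fractions over a
design grid. The bundled acceptance script runs both studies at 10,000
replicates (~40 s); the test suite uses 5,000 replicates with ±3
Monte-Carlo standard-error tolerances.

## Numerical choices and degenerate inputs

- Window membership is `|d| ≤ W`; the tricube weight vanishes at the
  boundary anyway, so the choice only matters (and is deterministic)
  for the rectangular kernel.
- Sites with zero depth in either bulk are excluded at read time;
  monomorphic sites score G = 0 (limit of `x ln x`), keeping scans
  dense for smoothing.
- Zero G′ values are dropped (with a logged count) before the log
  transform of the robust fit; all-equal G′ vectors and fits with
  mode ≥ median raise instead of returning a degenerate null.
- Phenotype ties in selection are broken by individual index (stable
  sort).
- BED output is 0-based half-open; all internal coordinates are 1-based.

## Known limitations

- The null moment formulas are leading-order delta-method
  approximations: direct Monte-Carlo of the two-level model shows the
  true null mean of G exceeds `1 + C/a` by ~1–2% at moderate coverage
  (e.g. 1.18 observed vs 1.167 predicted at `C = 50`, `a = 300`), with a
  matching excess in the variance. Smoothed-scan type-I errors computed
  from the closed forms are correspondingly a little above nominal.
- The robust σ estimate carries the mode estimator's n^(−1/3) noise
  (see above); on short scans the resulting tail thresholds vary
  appreciably between realisations.
- Single-QTL, F2-design scope: recombinant inbred lines, backcrosses
  and multi-QTL architectures are not simulated, though the null
  machinery applies wherever the effective-allele count is set
  appropriately.
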