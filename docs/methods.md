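# Methods

This note records the statistical model behind each component, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and region geometry

All coordinates are 1-based and inclusive on genome build hg18. A region's
`span_bp` is defined as `end − start`, matching the convention in which
published candidate-locus tables print region sizes; the closed interval
contains `span_bp + 1` bases. Probe counting always uses the closed
interval, so probes exactly at `start` or `end` count. BED-style 0-based
half-open input is converted on read (`start + 1`). Strand is ignored
throughout: copy-number events are unstranded.

Each region carries a flanking context (default 500 kb per side). Flank
probes never enter the region's probe-coverage count — the published
coverage columns this mirrors count strictly in-region probes (a locus can
have zero probes yet non-zero size) — but they do count toward a segment
call's probe support, which is what lets 1- and 2-probe regions yield
qualified calls.

## Carrier qualification

Segment calls carry an integer copy-number state (2 diploid; <2 loss,
including 0 for homozygous deletions; >2 gain). Callers emitting only
loss/gain labels should be mapped to 1/3; the integer encoding preserves
homozygous-deletion information without inventing caller-specific
semantics.

Per sample and region, the decision tree is:

1. discard calls of the wrong class, and calls supported by fewer than
   `min_consecutive_probes = 3` consecutive array probes (support counted
   within region + flank);
2. a region with zero in-region probes is *uncallable* for every sample;
3. below `merge_min_probes = 11` in-region probes, a sample is a carrier
   iff a single surviving call covers `[start, end]` entirely (full-span
   rule);
4. at ≥11 probes (*merge mode*), the in-region probes of all surviving
   same-class calls are unioned and the sample is a carrier iff strictly
   more than `merge_fraction = 0.5` of in-region probes are altered
   (15/28 qualifies, 14/28 does not). Merge-mode carriers are flagged
   `provisional`.

Design choices that were genuinely open:

* **7–10-probe regions.** Only the ≤6-probe (full-span) and ≥11-probe
  (merge) regimes are named by the source procedure, which also states
  that every scored call spanned its whole region; the full-span rule is
  therefore applied to all regions below the merge threshold.
* **Probe support** is counted over all array probes in region + flank,
  not only probes informative for the call — callers do not report the
  latter in their tabular output.
* **Merge mode unions per class separately**; a pathological sample
  altered at >50% of probes by losses *and* by gains would be scored as a
  carrier for the region's expected class only.
* **Manual review** of intensity data behind merge-mode calls cannot be
  automated faithfully; the `provisional` flag plus the carrier matrix's
  machine-readable support counts stand in for it.
* Overlapping same-sample calls with contradictory classes are both
  retained and evaluated independently per class.

A sample qualifying for the expected class is a `carrier`; otherwise, if
the opposite class qualifies under identical criteria, a
`reciprocal_carrier`. Excluded samples (e.g. known single-locus variant
carriers) stay in the matrix but never enter counts. Output is invariant
to input call order (calls are canonically sorted first).

## Case-control association

The two-sided Fisher P is the minimum-likelihood convention (sum of
probabilities of all fixed-margin tables no more probable than the
observed one), i.e. R's `fisher.test`, delegated to
`scipy.stats.fisher_exact`; the test suite verifies it against full
hypergeometric-support enumeration for every table with total ≤ 40. The
one-sided P is the upper tail toward enrichment in group 1. A table with
an empty group returns NaN with a warning; an all-zero carrier column is a
valid P = 1 table.

Two odds-ratio routes are reported side by side, because headline
estimates in the rare-CNV literature are cross-product ratios while the
printed intervals are typically conditional-exact:

* `sample`: ad/bc with the Woolf log-scale interval; zero cells flagged,
  optional Haldane–Anscombe +0.5;
* `exact`: conditional MLE with the exact conditional (Cornfield-type)
  interval from noncentral hypergeometric tails
  (`scipy.stats.contingency.odds_ratio`). Exact intervals over-cover
  slightly by construction; the suite measures ~96–97% realized coverage
  at a nominal 95% (within its ±4-point acceptance band).

Carrier-frequency intervals default to Wald (p̂ ± 1.96·√(p̂(1−p̂)/n),
truncated to [0,1]; degenerate [0,0] at x = 0), which is the convention
the reproduced published intervals follow; Clopper–Pearson is available.
Case-control comparisons exclude overweight samples (25 ≤ BMI < 30) from
both sides; weight classes are obese ≥ 30, normal < 25 kg/m². Pooled
comparisons require each cohort to appear on at most one side.

The child-total vs adult-total comparison (10/1985 vs 0/840) reproduces
the published 0.039 under the two-sided convention; the one-tailed value
is ≈0.029.

## Quantitative traits

BMI is analysed on the log₁₀ scale. The ANOVA is sequential (type I) with
sex fitted first, matching the `aov` idiom, with type II available for
robustness; only regions with ≥3 carriers in the cohort are tested, and a
joint model fitting all carrier indicators at once is provided for
samples carrying several variants. Effect sizes are back-transformed to
kg/m² as differences of geometric means, with the Welch CI of the log₁₀
difference applied multiplicatively to the non-carrier geometric mean.

The carrier Z-score analysis standardizes each carrier's BMI within its
own cohort, reports the mean Z with a CI from the observed SD of the Z's
(the unit-variance-null SE is available behind a flag) and a one-tailed
normal P at mean Z·√n. "Gender-corrected BMI" for the alternative Welch
route is offered both as sex-model residuals and as sex-stratified
Z-scores; neither is asserted as canonical.

Subgroup contrasts (large- vs small-variant carriers at a heterogeneous
locus) run three one-tailed tests: each subgroup against the population
and subgroup A (hypothesized reduced) against subgroup B. Singleton
subgroups fall back to a single-observation Z against the comparison
group's SD, since the Welch test degenerates.

## Exact power

Power is exact and unconditional: carrier counts are independent
binomials per group, and every realized 2×2 table is tested with the
conditional one-tailed Fisher test at α. The double enumeration is
truncated where cumulative binomial tail mass falls below
`truncation_eps = 1e-12` per side, and the discarded mass is reported as
a bound on the absolute error; halving the cutoff can never move the
result by more than the previous bound. "Frequency in cases" is carrier
(dominant-model) frequency; the control frequency is derived on the odds
scale, p₂ = odds₁/OR / (1 + odds₁/OR).

The reference design uses 1,816 cases and 4,526 controls — the pooled
obese and non-obese strata (645+701+470 and 557+843+3126) of the bundled
candidate-locus table. A per-locus power summary (median/minimum) is
provided, but the published per-locus summary figure depends on
original-report frequencies and effect sizes not contained in the bundled
tables, so it is validated structurally rather than numerically.

## Miscall inflation and genomic control

Under a shared true carrier frequency f, group-specific false-positive
and false-negative call rates make the *observed* frequency
f(1−fn) + (1−f)·fp per group. Equal error rates leave the null intact (an
analytic identity the suite asserts); differential rates create a real
difference in observed frequencies and hence excess type-I error. The
simulation draws true carriers, flips statuses per group, and computes
two-sided exact P's per replicate (cached over unique tables for speed),
reporting empirical type-I error on an α grid with Monte-Carlo SEs, QQ
coordinates, and λ = median(χ²₁)/0.4549 (the exact null median
`chi2.ppf(0.5, 1)` is used, not the rounded constant). Genomic control
divides χ² by λ and maps back; λ < 1 is passed through unchanged.

Because the exact test is discrete and conservative at rare counts, λ on
a clean null sits *below* 1 when expected carrier counts are small (a
logged caveat when median counts are < 5); the λ ≈ 1 sanity check in the
suite therefore uses a common-variant configuration (f = 0.05) where
discreteness is mild. The parameter grid shipped as a default
(f ∈ {0.002, 0.005} × fp ∈ {0, 0.001, 0.004} × case:control ratio
∈ {1, 2, 4}) is a reconstruction for rendering inflation-vs-error
summaries; no published quantitative claim is attached to it.

## Synthetic cohorts

The generator emulates: two case-control cohorts plus a population cohort
(default sizes 645/557 child, 701/843 adult, 5,213 population, mirroring
the bundled table's sample row); rare carriers per region with a
case-control effect given as an odds ratio on carrier frequency and/or a
population effect as a log₁₀(BMI) shift; spanning calls with breakpoint
jitter into the flanks (default up to 2 flank probes, plus sub-probe
coordinate noise); fragmentation of merge-mode events into two
sub-segments (default probability 0.3) that never drops a true carrier's
in-region coverage to or below the merge threshold, so ground truth stays
well defined; reciprocal variants; and group-differential fp/fn miscalls
(false negatives withhold a carrier's segments, false positives emit
spurious spanning calls). Everything derives from one `numpy` Generator
seeded by the mandatory spec seed; identical seeds give byte-identical
output files.

BMI is log₁₀-normal per sex, defaults μ = log₁₀(25.5)/log₁₀(24.5) (M/F),
σ = 0.07 — chosen once to give a realistic ~15–20% obesity prevalence;
nothing downstream asserts these values. Case/control group members have
BMI drawn truncated to their weight class (cases ≥ 30; controls < 25,
with the upper bound set just below 25 so that rounding emitted BMI to
two decimals cannot flip a control's weight class). Baseline carrier
frequency defaults to 0.002, the order of the rare variants this design
targets.

Not emulated: raw LRR/BAF intensities and probe-level noise, linkage
disequilibrium, family structure, cohort-specific ascertainment beyond
weight class, and per-sample data-quality variation beyond group-level
fp/fn. Passing tests therefore demonstrate correctness of the carrier
logic and the statistical machinery under the stated generative model,
not robustness to intensity-level artefacts.

## Problem sizes in the test suite

Long-running property tests use deliberately scaled designs, chosen for
their statistical tolerances: pipeline null calibration runs 500 seeded
300+300-sample cohorts at carrier frequency 0.03 with tail-randomized
P-values (the exact test's P is discrete and super-uniform; the
randomized version p⁻ + U·(p − p⁻) is exactly uniform under the null, so
a KS test is applicable); ANOVA type-I calibration uses 600 null
replicates at n = 1,500 with 10 carriers; exact-CI coverage uses 400
cohorts of 400+400 at a case frequency of 0.2 (expected ~80 vs ~10
carriers, enough information that the exact interval's conservatism stays
within a few points of nominal); the inflation checks use 2,000–4,000
replicates of 2,000+2,000 designs. The effect-realism check (median
empirical OR near a simulated OR of 25) uses 200 cohorts of 1,500+1,500
at baseline frequency 0.01.
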