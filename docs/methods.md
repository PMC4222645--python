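# Methods

## Model

For gene *g* in an F1 hybrid of maize line *M* and teosinte line *T*, let
*h_m*, *h_t* be the maize- and teosinte-allele read counts at segregating
sites, and *p_m*, *p_t* the corresponding own-allele counts in the two
parent inbreds.  The cis effect is `log2(h_m/h_t)`; because both alleles
of the hybrid share one trans environment, this ratio is unaffected by
trans divergence.  The parent ratio `log2(p_m/p_t)` carries cis + trans,
so the trans effect is estimated by subtraction.  Statistical calls use
the counts, not the logs: exact binomial tests of each ratio against 1:1
and a Fisher's exact test of parent vs hybrid, all two-sided under the
minimum-likelihood definition.  The two-sided binomial at p = ½ is
computed as `min(1, 2·P(X ≤ min(m,t)))`, which equals the minlike sum by
symmetry (unit-tested against exact enumeration).

q-values follow Storey with π₀ estimated at a single fixed λ = 0.5 (no
smoother, for determinism), clamped into (0, 1]; a π₀ estimate of exactly
zero is floored at 1/m so q-values stay positive.  Each test family
(parent binomial, hybrid binomial, FET) is corrected separately within
tissue: the families test different hypotheses on partly different gene
subsets.  The FET is run only for genes where at least one binomial test
is significant; genes with both binomial tests non-significant are
conserved regardless of any FET.  Effect signs with zero counts use a
+0.5 pseudocount, and a sign of exactly 0 groups with "same direction".

## Ratio engine

Replicates are pooled by summation (replicate depths are strongly
correlated in this design, and the tests operate on totals).  Parent
counts in each cross are corrected for library size by scaling the
larger-library parent **down** to the smaller library (half-to-even
rounding); scaling down keeps the count tests from becoming
anti-conservative.  Per-cross records require depth ≥ 100 (configurable)
in both the hybrid and the corrected parent comparison.

For overall (across-cross) ratios the hybrid side is a plain sum over
passing crosses.  The parent side must not count an inbred's reads once
per cross it appears in: each involved line's raw count enters once,
scaled to the smallest involved library.  Relative line weights follow
the number of passing crosses the line participates in (so a line that
supports more comparisons carries proportionally more weight, matching
the hybrid side's implicit weighting), normalized so both sides carry
the same total weight — the smaller side's line count.  This makes
every per-line scale factor ≤ its cross count, counts are only ever
scaled down, and the rounded weighted sums remain valid (slightly
conservative) inputs to the binomial and Fisher tests.  The scheme is
isolated in `overall_ratios` so an alternative weighting can be swapped
in.  Log ratios involving a zero count are undefined (NaN) and excluded
from effect-size summaries; the counts still feed the tests.

## Candidate lists

CCT = cis ∪ cis+trans; cis-only and trans-only lists are built the same
way.  The coverage filter requires ≥ 15 passing F1s spanning ≥ 3 maize
and ≥ 5 teosinte inbreds.  Directional consistency per gene is the
depth-weighted fraction of passing crosses whose hybrid ratio points the
majority way; hybrid depth is the weight and hybrid direction the
signal, because the tiers qualify the cis effect specifically (using
parent depth as well would mix in trans information).  Exactly-1:1
crosses contribute depth to the denominator only.  Tiers: A ≥ 1.0,
B ≥ 0.9, C ≥ 0.8; ties in favored allele break toward maize (they occur
only at exactly equal weighted depth).  The reference-bias check pools
hybrid counts separately over crosses involving the reference maize line
(B73 by default) and the rest, tallies per-gene directions, and compares
the two tallies with a two-sided FET.

## Variance partition

Crosses whose teosinte parent appears in exactly one cross are removed
first to balance the factor structure.  Per gene, the per-cross hybrid
log2 ratio is fitted by weighted least squares on maize-parent and
teosinte-parent factors, weights = per-cross hybrid depth.  Each side's
R² is its drop-one (Type II) weighted SS increase divided by the total
weighted SS about the weighted mean — chosen to match the drop-one
F-tests used for per-side significance (p < 0.05, unadjusted); in an
unbalanced design the two R² values need not sum to the model R².  The
headline summary is the ratio of the mean maize R² to the mean teosinte
R² (ratio of means, not mean of ratios), with a delta-method SE by
default or a seeded gene bootstrap.  Note that even with equal planted
line variances this ratio sits below 1 (≈ 0.84 under the default
design): the teosinte factor has more levels and therefore absorbs more
degrees of freedom of noise.  Validation against planted variance ratios
therefore compares the measured ratio to the same statistic computed on
the noiseless truth, not to the raw variance ratio.  The per-gene fits
are plain numpy least squares for speed; they are unit-tested against
statsmodels WLS with Type-II ANOVA.

## Dominance

Expression totals are made comparable by dividing each genotype's counts
by its library size and rescaling by the tissue-mean library.  For each
cross, a = (P_M − P_T)/2, d = F1 − midparent, D/A = d/|a| — so +1 always
means the F1 matches the *higher* parent, and the dominant allele is
mapped back to species through the sign of a.  D/A is undefined when
a = 0.  Per-gene D/A values across crosses are cleaned by iterating
Dixon's Q test at α = 0.05 with the staged statistic (r10 for n ≤ 7, r11
for 8–10, r21 for 11–13, r22 for n ≥ 14; two-sided 95% critical values
embedded for n = 3..30, with the n = 30 value reused above 30).  The
iteration stops when nothing is rejected or only three values remain.
Classes: additive |D/A| < 0.25; dominant 0.75 < |D/A| < 1.25; otherwise
"other".

## Enrichment

All overlap tests are hypergeometric FETs on 2×2 tables within an
explicit universe (the genes assayed in the relevant tissue); expected
overlap is the product formula |list|·|set|/|universe|.  Enrichment
tests default to one-tailed ("greater"); the tail is a per-call option
because depletion is of interest for some annotations.  QTL intervals
with more than 20 member genes are dropped before per-trait tests with
Bonferroni correction over traits.  Selection-scan scores are compared
between candidate and conserved genes on the natural-log scale with a
two-sample KS test and a Welch t-test.  BH and Bonferroni corrections
come from statsmodels.

## Synthetic data generator

The generator emulates the study conditions: 6 maize × 9 teosinte
inbreds, 29 of the 54 possible F1s, biological replicates averaging
1.96 per genotype, three tissues (drawn independently — no cross-tissue
correlation is simulated), and per-gene allele counts with
overdispersion and library-size variation.  Per gene × tissue it plants
a category (conserved / cis / trans / cis+trans / cis×trans /
compensatory; "ambiguous" is never planted — it can only arise from test
outcomes), a base cis effect c and trans effect t honoring the category
constraints (compensatory: t = −c; cis×trans: opposite signs), and
per-line cis deviations — an allelic series — with smaller spread on the
maize side than the teosinte side, mimicking the bottleneck's loss of
diversity.

Counts: hybrid total depth is negative binomial (gamma–Poisson; variance
μ + αμ², α = 0 degenerates to Poisson) and the maize-allele count is
binomial given that total with log-odds equal to the cross-effective cis
effect c* = c + dev_M − dev_T, so hybrid allele counts sum to the drawn
total exactly and the hybrid ratio is a pure cis readout.  Parent lines
express only their own allele, with mean ∝ library × 2^(±(c+t)/2 + dev),
which makes the parent log2 ratio c* + t by construction.  Library
factors are log-normal with mean 1 per sequencing library (per
genotype × tissue × replicate).

Defaults and why:

* `mean_depth = 150` reads per gene per library — a moderate
  allele-informative depth giving overall pooled depths of a few
  thousand reads per gene under the default design; real per-gene depth
  distributions are not modeled, so this is a knob, not an estimate.
* `dispersion α = 0.001`.  Chosen by a power analysis of the testing
  framework before any tests were written: the binomial/FET battery
  models counting noise only, and parent-side NB overdispersion acts as
  spurious trans signal whose z-inflation grows with pooled depth.  With
  ~12 parent libraries per side, α ≤ 10⁻³ keeps the parent-test
  inflation below ~1.25 so the battery remains near-calibrated at the
  simulated depths — consistent with the very low residual variance
  expected between replicate libraries of genetically identical inbreds
  grown in controlled conditions.
* `sigma_cis_maize = 0.23`, `sigma_cis_teosinte = 0.25` log2 — an
  allelic-series variance ratio of ≈ 0.85, the nucleotide-diversity
  retention of maize relative to teosinte.
* `category_mix` — 30% conserved, 15% cis, 20% trans, 10% cis+trans,
  10% cis×trans, 15% compensatory: a mix in which roughly two-thirds of
  genes carry some divergence, as genome-wide hybrid studies find.
* effect magnitudes `min_effect + |N(0, 1)|` log2 with `min_effect = 0`:
  small effects dominate, as in real data.

What passing tests on this generator do **not** show: robustness to
alignment bias, to correlated tissues, to per-site (rather than
per-gene) effects, or to realistic depth distributions — none of which
are simulated.

Validation conditions: classifier-recovery and null-calibration checks
run with the allelic series switched off (σ = 0).  With a nonzero
series, the realized line-average deviation (~σ/√n_lines ≈ 0.1 log2) is
a *real* shift of the sampled population's ratios that deep pooled
counts detect; recovery of the planted base category is then not a
correctness criterion.  Parameter-recovery checks for the variance
partition instead plant only the allelic series.

## Numerical and design choices

* Determinism: all randomness flows from explicit seeds through
  numpy Generators; output TSVs are sorted (tissue, gene) and written
  with fixed float formatting, so reruns are byte-identical.
* Problem sizes: validation suites use 500–2,000 genes and a single
  tissue where one suffices; these sizes give sampling errors well
  inside the asserted tolerances.
* Storey λ is fixed at 0.5; a λ-grid smoother is deliberately not used.
* The 5% FDR sensitivity variant is a configuration change
  (`fdr_threshold`), not a separate code path.
* Pseudocounts are never added to tested counts; a +0.5 pseudocount is
  used only to determine effect signs for category assignment.
* Bootstrap CIs (cis-share bins) resample genes within bins, 1,000
  replicates by default, percentile intervals.

## Known limitations

* The parent-side overall weighting is one concrete realization of
  "count each parent once, weight by participation"; other defensible
  schemes exist and the operation is isolated so they can be swapped.
* Dixon critical values are embedded only for α = 0.05.
* The FET's conditioning ignores residual overdispersion between parent
  libraries; with strongly overdispersed real data the trans calls
  will be anti-conservative (as in any count-conditional framework).
* GO enrichment with gene-length bias correction is out of scope; the
  enrichment module provides generic set tests only.
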