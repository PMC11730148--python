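# Methods

`divscan` implements a selection-scan contrast between two experimental
conditions — a control cohort and a heat-treated cohort of individually
genotyped diploid coral larvae — built from windowed diversity statistics,
percentile-tail outlier classification, mixed-model group inference and
rank-based functional enrichment, together with a synthetic-data generator
that provides ground truth for every stage.

## Windowed statistics

Windows are non-overlapping, half-open bins `[k*w, (k+1)*w)` per scaffold
(0-based; default `w` = 5000 bp, chosen to suit short scaffolds), anchored at
the scaffold origin; a final partial window is retained.  For a window with
segregating sites `S` among the group's non-missing calls:

* Per-site nucleotide diversity is the mean pairwise difference
  `a(n - a) / C(n, 2)` with `a` the alternate-allele count and `n` the
  non-missing chromosome count at that site.  Window π is the sum over
  sites divided by the full window size (including monomorphic positions),
  the convention of standard windowed-π outputs.
* Tajima's D is `(π_sum − S/a1) / sqrt(e1 S + e2 S (S − 1))` with the
  classical constants `a1, a2, b1, b2, c1, c2, e1, e2` evaluated at the
  window's effective chromosome count.  D is undefined (NaN, not zero) when
  `S = 0` or fewer than 4 chromosomes are available; `S = 1` uses the same
  formula (the `e2` term vanishes).

Missing genotypes are excluded site by site, so `n` varies across sites.
The variance constants need a single `n` per window; the default is the
median per-site non-missing chromosome count, rounded to the nearest
integer (`n_mode="median"`).  `n_mode="full"` instead uses twice the number
of individuals everywhere, for sensitivity checks.  The median convention
has one knowable side effect: under missingness the constants are evaluated
at a slightly different `n` than each site's own, giving D a small bias
whose size depends on cohort size.  Cohorts of different sizes therefore
acquire slightly different mean D even under identical neutral generation,
which matters only for calibration experiments (below).

## Site filtering

Jointly-called sites pass three filters in a fixed order so exclusion counts
are deterministic: missing-call fraction (default ≤ 0.25), minor allele
frequency over non-missing calls of both groups pooled (default ≥ 0.01),
and the two-sided Hardy–Weinberg exact test on pooled genotype counts
(default p ≥ 1e-6).  The HWE test is the classical conditional exact test
(no mid-p): given `n` diploids and minor-allele count `m`, heterozygote
count `h` has probability proportional to
`2^h n! / (((m−h)/2)! h! ((2n−m−h)/2)!)`, and the p-value sums the
probabilities of all attainable `h` no more likely than the observed one.
Log-gamma arithmetic keeps it exact to ~1e-12 up to hundreds of samples.
Pooled testing matches filtering a single combined call set before
splitting analyses; per-group filtering is available (`pooled=False`).

## Outlier classification and gene mapping

Per condition, tail cutoffs are linear-interpolation percentiles (default
5th and 95th) of Tajima's D over valid windows; membership is closed
(`≤ lower`, `≥ upper`).  High-D windows are candidate balancing selection,
low-D windows candidate positive selection (sweeps).  Each 5-kb window is
one region; adjacent outlier windows are not merged.  Cross-condition
sharing is plain window-key set intersection, and inclusion–exclusion
identities are asserted in tests.  Outlier windows are linked to CDS
annotations by coordinate overlap with the window extended by a flank
(default 1000 bp) on each side, strand-ignored — a coordinate-space
restatement of searching flanking sequence for nearby coding regions.
Optionally only genes with larva-detected proteins are linked.

## Group inference

The condition contrast fits, by maximum likelihood, the linear mixed model
`value ~ condition` with a random intercept per window against the reduced
model without the condition term, and refers `2 ΔlogLik` to chi-square with
1 df.  Condition is a fixed effect: that is the only reading under which a
1-df likelihood-ratio test of the group contrast exists.  ML (not REML) is
required for an LRT on a fixed effect.

Because the paired layout always has exactly two observations per window,
the ML fit factorises through the per-window difference and sum, which are
independent Gaussians; the default engine solves this in closed form,
including the `σ_b² ≥ 0` boundary case (where the two variances pool).
`engine="mixedlm"` fits the identical likelihood numerically with
statsmodels MixedLM; the two agree to ~1e-6 and are cross-checked against
lme4 in the test suite.  Degenerate inputs (e.g. the two conditions exactly
equal) receive a variance floor of 1e-12 shared by both models, so the LRT
is 0 rather than an error.

The subsampling robustness procedure draws `k = 10` of the control
individuals without replacement (seed `base_seed + iteration`, so every
iteration is independently reproducible), recomputes windowed statistics on
the subsample and re-runs the contrast against the fixed heat-group
statistics, 100 times by default; the summary reports the fraction of
iterations significant at α = 0.05 and the fraction agreeing on the
direction of the effect.  `heat_stats` may be supplied pre-computed, which
is how the injected-shift experiments perturb the heat side without
touching the generator.

Survival comparison takes per-tank counts, smooths survival proportions per
condition with lowess (span 0.75, recorded in the output) and compares
per-tank proportions between conditions with a two-sided Wilcoxon rank-sum
test — exact by enumeration for combined samples up to 20, asymptotic
otherwise.  Endpoint aggregation (final-day proportion per tank) is the
default; per-day pooling is available since the aggregation feeding such
tests is often unstated in practice.

## Enrichment

Genes mapping to outlier windows of one tail and condition score 1, all
other genes in the background (larva-detected proteins) score 0.  Each GO
category with 5 to 50% of the background is tested for enrichment of
score-1 genes with a one-sided Mann–Whitney U test of category vs rest.
Binary scores make the U distribution almost entirely ties, so tie handling
is explicit: midranks with tie-corrected variance and continuity correction
for the normal approximation, and full enumeration of group assignments for
combined samples up to 20.  The exact p-value is the closed tail
`P(U ≥ u)`; with large tie atoms the continuity-corrected normal p tracks
the middle of the atom, so the two can differ by a visible fraction of the
atom mass — the tests bracket the approximation between the strict and
closed tails rather than asserting closeness to one of them.  Raw p-values
are Benjamini–Hochberg adjusted within each namespace (BP/MF/CC), and both
raw and adjusted values are always reported.  GO-graph ancestor
propagation is not performed; categories are taken as given in the mapping.

## Synthetic data generator

The generator emulates the target study design: 16 control + 10 heat
diploids, 20 scaffolds × 25 windows of 5 kb per condition (500 windows),
SNP count per window Poisson with mean 40, per-genotype missingness 0.05,
5% of windows sweep-like and 5% balancing per condition with half of each
selected set shared between conditions.  Sites are independent draws from a
regime-specific site frequency spectrum over derived-allele counts
`i = 1..n−1`:

* neutral: weight `1/i`;
* sweep: weight `1/i^α` (default α = 3), skewing toward rare alleles;
* balancing: neutral law mixed with a Gaussian bump centred at `i = n/2`
  (sd `n/8`) with mixture weight `β/(1+β)` (default β = 5).

Derived alleles are placed on chromosomes uniformly without replacement and
paired into diploids; allele counts are therefore conserved exactly when
missingness is off.  Each window carries one CDS fully inside it (making
flank mapping unambiguous), 1–3 background GO terms from a configurable
vocabulary, and a per-(condition, regime) planted GO term attached with
probability 0.9 to genes in matching selected windows (0.02 elsewhere);
80% of genes are marked larva-detected and 50% egg-detected.  A truth table
records each window's generating regime per condition.

What the generator deliberately does **not** emulate: pedigree structure
(the real larvae are siblings from eight mixed colonies), linkage
disequilibrium within windows, recombination, demographic history and
read-level noise.  Independent sites keep expected window statistics
analytically controllable — neutral windows have mean D ≈ 0 with a smaller
variance than coalescent data, so regime separation is cleaner than in real
cohorts.  Two further consequences are worth knowing.  First, because each
cohort's site frequencies are drawn conditioned on polymorphism within that
cohort, expected π per window differs between cohorts of different size, so
π is not a null contrast in this simulator even for all-neutral
configurations.  Second, with the default distortion strengths the sweep
and balancing D distributions separate almost completely from neutral, so
percentile tails are occupied nearly exclusively by selected-truth windows
and tail recovery sits near 100%; passing recovery tests therefore shows
correct bookkeeping and ranking, not detection power at realistic effect
sizes.

## Calibration and problem sizes

The type-I calibration of the mixed-model contrast uses all-neutral cohort
pairs with missingness switched off: 200 replicates of 150 windows
(5 scaffolds × 30 windows, 20 SNPs/window mean).  Missing-free data makes
both cohorts' window D exactly mean-zero under the generator, isolating the
test's calibration from the small cohort-size-dependent bias the median-n
convention introduces under missingness (see above).  The injected-effect
power check adds +0.5 to every heat window D at 300 windows.  Enrichment
recovery uses 50 default-condition replicates (20 in the acceptance script)
and a 200-category random-score null for p-value uniformity.  These sizes
are the package's own choices and keep the full suite fast on a single CPU.

## Known limitations

* The HWE exact test and the exact MWU enumeration are O(minor count) and
  O(C(n, n1)) respectively — fine at cohort scale, not for thousands of
  samples or exact MWU beyond ~20 observations.
* The closed-form LMM engine applies only to the balanced two-observation
  layout this pipeline produces; other designs must use `engine="mixedlm"`.
* Windows beyond the last SNP-bearing bin of a scaffold cannot be emitted
  because scaffold lengths are not carried in the genotype matrix.
* Percentile tails control nothing inferentially; they are a fixed-fraction
  screen, and no multiple-testing correction is applied across windows.
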