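# Methods

## Model of condition and stress

Individual condition `c` is drawn from `Normal(1, σ)`. The mean is fixed
at 1 because condition is relative within each sex; stress acts purely by
inflating σ, representing cryptic variation revealed under challenging
environments. σ is set independently per sex (`sigma_f`, `sigma_m`), which
defines the four scenarios *none*, *both*, *female_only* and *male_only*.

Negative draws are truncated to 0 rather than resampled or allowed:
condition enters contest success as `c^g` and fecundity linearly, both of
which require nonnegative values, and truncation preserves the rank order
of draws. For σ ≤ 0.3 the truncated mass is below 5·10⁻⁴, so the sample
mean deviates from 1 by less than 0.002 at n = 10⁵; at the default sweep
range the choice is numerically invisible.

## Reproduction in mating groups

Reproduction is resolved in groups of two females and two males, the unit
of competitive fitness assays. Baseline:

- fecundity `Eggs_i = c_fi`; sperm never limiting, so `w_fi = c_fi`;
- males split total realized female fitness by the contest share
  `c_m1^g / (c_m1^g + c_m2^g)` with `g_m = 2` by default.

Conventions: `c^0 = 1` for all `c ≥ 0` so `g = 0` always yields an even
split, and the 0/0 tie at `c_focal = c_rival = 0` is defined as 0.5 (the
limit along the diagonal). The share is computed on the log scale so the
winner-take-all limit (`g` of order 100+) does not overflow.

Variants (flags on `ReproductionParams`, all off by default):

- **female competition** — the two fecundities are pooled and split by a
  contest with intensity `g_f`. Because baseline fecundity is linear in
  condition, `g_f = 1` reproduces the baseline identically; this identity
  is used as a calibration anchor in the tests.
- **sperm limitation** — fertilized fraction `min(1, mc·c̄_m)` with `c̄_m`
  the mean condition of the group's males: a piecewise-linear saturating
  map, capped so it is a proportion.
- **male harm** — fecundity multiplied by `max(0, 1 − harm·c̄_m)`.
- **nuptial gift** — fecundity multiplied by `1 + gift·c̄_m`.

The harm/gift/sperm forms are this package's design choices: the simplest
multiplicative modifiers of fecundity by mean male condition that are
monotone in the advertised direction and collapse exactly to the baseline
at zero coefficient (or a saturated cap). Males act through the group
mean rather than through a single mated male — with two males and two
females per group and no explicit pairing, the mean is the only
symmetric choice. In every variant male fitness partitions realized
female fitness, so `w_m1 + w_m2 = w_f1 + w_f2` holds to machine
precision; this conservation law is property-tested over random groups
and parameter draws.

## Simulation experiments

A replicate draws 500 individuals per sex (population size 1000),
partitions each sex uniformly at random into disjoint 2+2 groups
(re-partitioned every replicate), resolves every group, and computes
Crow's `I = σ_w²/w̄²` per sex over all individuals pooled — not per group
— since the opportunity for selection is a population-level quantity.

Sweeps vary σ over a default grid 0.05–0.50 in steps of 0.05. In
sex-limited sweeps the unstressed sex keeps a small nonzero baseline
σ = 0.05 so its fitness variance stays positive and the log ratio
`log(I_m/I_f)` is defined; the grid, baseline and replicate counts
(20 by default) are configurable. Seeding uses a `SeedSequence` tree: one
integer seed deterministically derives independent sub-streams per sex,
per partition and per (scenario × grid × replicate) cell, so whole sweeps
are reproducible from one integer.

Expected qualitative behavior, verified by the acceptance tests: equal
stress keeps the opportunity for selection male-biased at every grid
point (a consequence of `g_m = 2`); female-only stress raises both `I_f`
and `I_m` (males share variable female fecundity) but `I_f` faster, so
the mean log ratio decreases monotonically; male-only stress leaves `I_f`
untouched exactly and drives the ratio up.

## Estimation pipeline

Input is a CSV/TSV with one row per assay: `focal_sex` (F/M),
`treatment` (CT/HT/AT), `assay_date`, `offspring_count` (adult offspring,
the fitness measure) and optional `total_offspring_weight` (mg).

Within each sex × treatment group, fitness is mean-standardized to mean
1; the variance of the standardized values is then `I`. Assay date is a
random effect: the total variance is decomposed into between-date and
within-date components with the one-way random-effects method-of-moments
(ANOVA) estimator for unbalanced designs — `within = MS_within`,
`between = max(0, (MS_between − MS_within)/n₀)`,
`n₀ = (N − Σn_i²/N)/(a − 1)` — and `I` is reported as their sum (total
phenotypic variance, not residual-only). When fewer than two dates have
at least two assays the between component is reported as 0 with a
warning. The frequentist method-of-moments point estimate plus a
nonparametric bootstrap (resampling individuals, stratified by date
within each group; percentile intervals, B = 2000 by default) stands in
for a Bayesian variance-component posterior: the estimand — per-group
total variance of relative fitness, and the per-treatment
`log(V_m/V_f)` with a 95% interval — is the same.

Treatment contrasts of the log ratio use the paired bootstrap
distributions: the two-sided exceedance probability of zero difference,
multiplied by the number of contrasts (3, Bonferroni) and capped at 1.

Estimator choices, stated so the tests can be exact: unbiased sample
variance (n−1) everywhere; natural log for the variance ratio (only sign
and ordering carry meaning); adjusted Fisher–Pearson skewness (the
common default in major statistics software), computed on raw counts
pooled over sexes per treatment.

## Synthetic data generator

The generator emulates the structure the pipeline assumes: three
treatments × two sexes at study-scale group sizes (CT 102/102, HT
105/87, AT 101/97 males/females; 594 assays), ten assay dates, and
overdispersed counts. Counts are negative-binomial with the shape `k`
solved from the law of total variance so the marginal variance of
relative fitness hits the configured target `I`:

```
I = 1/μ + (1 + τ²)/k + τ²    ⇒    k = (1 + τ²) / (I − 1/μ − τ²)
```

where τ is the between-date SD on the relative-fitness scale, implemented
as a mean-1 multiplicative lognormal factor per date. Targets at or below
the floor `1/μ + τ²` are sub-Poisson and rejected with an explicit error
rather than silently approximated. An optional per-treatment ceiling
(maximum count) produces negatively skewed fitness, mimicking a
performance ceiling.

Defaults encode the emulated study conditions: CT mean 40 adult
offspring, HT 14% lower (34.4), AT 36% lower (25.6); male
relative-fitness variance double the female one in CT and AT
(log ratio ln 2 ≈ 0.69) and triple in HT (ln 3 ≈ 1.10), with both sexes'
variances depressed in HT and elevated in AT; τ = 0.15; individual
offspring weight 4.0 mg in CT/HT and 5.2 mg (1.3×) in AT with 8% CV.
Where the emulated study prints no value (number of dates, τ, the
absolute variance levels) the defaults are one-time choices of
realistic magnitudes for beetle fitness assays, not tuned quantities.

A second generator (`generate_from_mechanism`) bridges simulator and
pipeline: each assay simulates one mating group under a
treatment-to-scenario map and converts the focal individual's relative
fitness `w` to a count by a Poisson draw with mean `base_mean · w`.
Under zero stress this yields Poisson counts, whose relative-fitness
variance sits at the floor `1/base_mean` — a known anchor. The ground
truth records the realized (pre-Poisson) `I` per group, which recovery
tests compare against pipeline estimates.

What the generator does *not* emulate: bean-level spatial structure,
larval competition, lifespan, sex differences in mean fitness from
assay asymmetries, or any genetic structure. Passing recovery tests
therefore show the estimators are calibrated for data with the assumed
count-family, date-effect and independence structure — not that real
assay data satisfy those assumptions.

## Problem sizes and numerical notes

The analytic-limit check uses n = 10⁵ individuals (Monte-Carlo error on
`I` well below the 0.003 tolerance); sweeps use 20 replicates of 1000
individuals over a 10-point grid; pipeline recovery uses 100 synthetic
datasets at study-scale n with B = 400–500 bootstrap replicates; summary
statistics in the reproduction script average 30 datasets. Bootstrap
intervals are percentile (no BCa correction); at n ≈ 100 per group and
the default variance targets, the CI for `log(V_m/V_f)` covers the truth
at close to nominal rate (verified by the calibration tests).

## Known limitations

- The variance decomposition assumes independent assays within date;
  shared environmental structure beyond date is absorbed into the
  within-date component.
- Bootstrap p-values for contrasts are granular at small B.
- The bridge from group fitness to counts (Poisson rounding) adds a
  `1/base_mean` variance floor that slightly inflates realized `I`
  relative to the mechanistic truth; recovery tests account for it.
- The variant functional forms are stand-ins chosen for transparency and
  exact baseline collapse; alternative monotone forms would change
  quantitative, not qualitative, sweep behavior.
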