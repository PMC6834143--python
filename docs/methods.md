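# Methods

## Model overview

`polyadmix` simulates the prevalence dynamics of early- to middle-age-onset
polygenic diseases in two diploid populations evolving through discrete,
non-overlapping Wright–Fisher generations, with configurable admixture,
recombination, and heritable gene editing. The model rests on four
assumptions:

1. **Multiplicative risk.** Causal SNPs act multiplicatively on relative
   risk, equivalently additively on the log scale: an individual's PRS is
   `β_i = Σ_k a_ki ln(r_k)` and their relative risk is `exp(β_i)`.
2. **Common low-effect architecture.** Every causal allele is common
   (frequency 0.05–0.5) and of small effect (relative risk 1.05–1.15); no
   Mendelian or rare large-effect variants, no mutation influx, no selection,
   no pleiotropy.
3. **Logistic residual liability.** Heritability is enforced on the log-RR
   scale by calibrating the genetic variance to
   `V(h²) = (h²/(1−h²))·π²/3`, i.e. the environmental liability component is
   standard logistic (variance π²/3). This single convention fixes the locus
   count given the effect-size and frequency distributions and is
   corroborated by three independent quantities it reproduces: architecture
   sizes of ~700/1400/3700 loci at h² = 0.44/0.60/0.80, ~515 carried risk
   alleles per individual at h² = 0.5, and a logistic-shaped PRS→probability
   curve with unit slope on the log-RR scale.
4. **Prevalence as lifetime risk.** "Prevalence" means cumulative incidence
   past the typical onset ages. The probability mapping is calibrated once
   per (architecture, prevalence) pair and reused across generations; this is
   appropriate for diseases whose incidence is concentrated before
   reproduction-relevant ages and is increasingly strained above ~10%
   prevalence (the package warns there).

## Genetic architecture

`build_architecture(h², mean_rr, maf_range, seed)` draws relative risks
uniformly on `mean_rr ± 0.05` and frequencies uniformly on `maf_range`,
appending loci until the cumulative Hardy–Weinberg variance
`Σ 2p(1−p)(ln r)²` reaches `V(h²)`. The stop rule overshoots by at most one
locus (≤ 0.3%), so the realized variance always matches the target within 1%.
Positions are uniform on a single linear genome of map length 1; there are no
chromosomes.

Two derived constructions cover the admixture experiments:

- `split_differing(arch, f)` makes a fraction `f` of each population's mean
  PRS attributable to population-specific loci. Specific loci are
  *effect-matched pairs*: each population-1-specific locus has a twin with
  identical frequency and relative risk (new position, zero frequency in the
  other population), guaranteeing exactly equal liability in both
  populations. Whether the original study drew the two specific subsets
  independently or matched them is unknowable from its text; pairing is the
  only choice that enforces the stated equal-liability premise exactly
  rather than on average.
- `add_high_risk_subset(arch, Δβ, common=0.5, rare=0.001)` appends loci at
  frequency 0.5 in population 2 and 0.001 in population 1, each carrying the
  architecture's mean effect, with the last locus trimmed so the expected
  mean-PRS gap equals `Δβ` exactly (~25 loci for Δβ = ln 10).

## PRS → disease-probability mapping

For prevalence `K`, the calibration draws `n = N·K` *diagnosed* individuals
from a reference sample of `N` PRS values without replacement, with
probability proportional to `exp(β)`, then sets the per-band probability
`π(β, β+Δβ)` to diagnosed/members per PRS band. Three implementation details:

- **Per-band normalization.** The band probability is the *conditional*
  fraction diagnosed-in-band / individuals-in-band. This is the only
  normalization under which re-applying the mapping per individual
  reproduces `K` (it does so exactly on the calibration sample, by
  construction) and under which the curve is the logistic-shaped function of
  β expected from the liability-threshold analogy.
- **Sampling without replacement** is implemented with exponential-race keys
  (`E_i / w_i`, keep the n smallest), which is equal in distribution to
  successive draws proportional to the remaining weights; tests verify this
  against exhaustive enumeration of ordered draws on ≤ 8-individual
  populations. In the large-N limit the inclusion probability is
  `π(β) = 1 − exp(−t·e^β)` with `t` solving `E[π] = K` — a
  complementary-log-log curve that is logistic-like at low prevalence and
  saturates at 1.
- **Smoothing and extrapolation.** Band probabilities are averaged over
  replicates (default 5), smoothed by count-weighted isotonic regression
  (which preserves the overall diagnosis rate, hence conservation of `K`),
  and extended beyond the sampled PRS range by a count-weighted logistic fit
  clamped to [0, 1]. Default band width Δβ = 0.1 log-RR; default calibration
  sample 10⁷ PRS draws × 5 replicates. Calibration samples are drawn from
  the exact linkage-equilibrium PRS distribution, computed by convolving the
  per-locus trinomial distributions on a 0.002 log-RR grid (off-grid shifts
  are split linearly between bins, keeping the mean exact and adding < 0.1%
  spurious variance).

Expected-mode prevalence (`mean of π(β_i)`) is the default estimator;
Bernoulli-sampled diagnoses are available for realism.

## Reproduction, admixture, recombination

Each generation produces exactly the configured number of offspring per
population label. A mating pair is cross-population with probability `m`;
parents are drawn uniformly with replacement among the eligible sex (sexes
are tracked with a configurable ratio but have no genetic effect). Cross-pair
offspring belong to either population with equal probability; within-pair
offspring keep their parents' label. For equal-size populations (all shipped
scenarios) drawing each label's offspring with an independent Bernoulli(m)
cross indicator is identical in distribution to pooling slots and resampling
to fixed sizes, and is how it is implemented. Generation 0 is initialization,
generation 1 the first (within-population) reproduction; admixture begins at
`blend_start` (default 2).

Gametes carry Poisson(λ) crossovers placed uniformly on the genome, with a
fair-coin starting haplotype. Because the crossover process is Poisson, the
allele source along ordered loci is a Markov chain with flip probability
`(1 − e^{−2λd})/2` across a gap of map length `d` (Haldane); the vectorized
generator samples either crossover segments (sparse λ) or per-locus flips
(dense λ), both exactly equivalent to explicit crossover placement. A numba
kernel is used when available; a pure-numpy path produces the same
distribution.

The analytic mean-PRS recurrence
`β₂(g+1) = β₂(g) − ½·m·(β₂(g) − β₁(g))` (mirrored for population 1, or with
β₁ held constant for maintenance-therapy projections) is exact for the
simulation's expectations and is exposed as `mixing_projection`.

## Gene therapy

`edit_individual` switches carried risk alleles to the neutral state one at a
time — uniformly at random by default, or largest-effect-first — until the
removed effect reaches the target. The stop rule crosses the target, so
realized improvements overshoot by up to one allele effect (mean edit counts
for ln 4 / ln 10 targets are ≈ 15.1 / 24.7 against analytic expectations
14.6 / 24.2 plus half-allele overshoot). Maintenance mode measures the
population's mean-PRS excess over the configured level each generation and
distributes the required total effect uniformly over treated individuals.
Editing never increases a PRS; allocation of a fixed total removed effect
across individuals does not change the next generation's mean PRS (verified
as a property test via Hardy–Weinberg re-equilibration).

## Statistics

Per generation and population the runner records mean and variance of the
PRS, expected-mode prevalence, Hudson's Fst (sample-size-corrected numerator,
genome-wide value as the ratio of sums, loci monomorphic in both populations
excluded) and the mean absolute allele-frequency difference. The
linkage-equilibrium variance `Σ 2p(1−p)β²` at realized frequencies is
exposed separately; its gap to the sample variance measures cross-population
linkage disequilibrium, the mechanism behind the admixture-driven prevalence
rise.

**Drift-adjusted prevalence.** At desk-scale population sizes (10⁴–10⁵ per
group instead of the nominally drift-free large populations), random drift of
the mean PRS over tens of generations is a leading noise term in prevalence
trajectories. The runner therefore also reports a control-variate estimator:
each population's PRS sample is recentred on its analytic mean (from the
mixing recurrence, re-anchored after therapy) before applying the mapping.
This removes mean drift without touching the variance dynamics under study;
the raw estimator is always reported alongside.

## Problem sizes and precision

The acceptance script (`scripts/acceptance.py`) uses populations of
3×10⁴ per group × 10 replicates for the one-generation admixture quantities,
10⁴–1.5×10⁴ × 10 replicates for multi-generation trajectories, 2×10⁴ × 10
for the disease presets, 10⁵ × 20 for mapping self-consistency, and 10⁷ × 5
calibration draws for mappings — sizes chosen so that the Monte-Carlo
standard error of each reported quantity is a few percent of its value while
a full run stays near ten minutes on one CPU. The dominant noise source is
tail sampling of the individual disease probabilities
(`SD(π)/K ≈ 3–4.5`), which scales as `1/√(N·replicates)`.

The self-consistency quantity is reported as the 95%-confidence upper bound
on the relative deviation between the configured prevalence and the mean
re-applied prevalence over replicates, `(|mean − K| + 2·SE)/K` — the
deviation of the *estimate*, not the per-replicate scatter, which at finite N
reflects population sampling rather than mapping error.

## Known limitations

- **Variance-convergence timescale under blending.** With Poisson
  recombination on a unit-length genome, locus pairs at typical map
  distances recombine at fraction ≈ 0.5 per generation, so the negative
  cross-population linkage disequilibrium created by blending two
  differing-SNP populations dissipates almost entirely by the second admixed
  generation — at λ = 36 just as at λ = 1000. The simulated PRS variance and
  prevalence therefore reach their equilibrium (≈ +25% variance, ≈ +39%
  prevalence at K = 1% for fully disjoint SNP sets) within 2–3 admixed
  generations regardless of λ in this range; a gradual, decades-long
  approach at λ = 36 would require crossovers sparse relative to the locus
  span (λ ≲ 1 per genome). The equilibrium levels themselves, and the
  accelerated-recombination dynamics, are insensitive to this and agree with
  the analytic large-N prediction (`π(β) = 1 − e^{−t e^β}` applied to the
  variance-inflated PRS distribution gives +38.1% for fully disjoint sets
  and +7.0% for one-fifth disjoint at h² = 0.5, K = 1%).
- The synthetic generator models idealized architectures: uniform MAF and
  effect-size distributions, linkage equilibrium at initialization, a single
  linear genome, exactly two populations, and 100%-efficient editing.
  Passing tests demonstrate internal consistency of the population-genetic
  machinery, not realism of human MAF spectra, linkage maps, or GWAS effect
  estimates.
- The PRS→probability mapping assumes the architecture's effect scale is
  fixed; it may be reused across derived architectures (frequency changes,
  subsets, editing) but not across different effect-size distributions.
- High-prevalence diseases (≳ 10%, e.g. the 25% preset) stretch the
  multiplicative mapping; results there should be read qualitatively (the
  package warns on calibration).
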