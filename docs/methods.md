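# Methods

## The problem

Replicated *Drosophila subobscura* populations founded from two contrasting
European latitudes, in two separate years, adapt to a common laboratory
environment. Two kinds of data track them: chromosomal-arrangement
(inversion) frequencies karyotyped at a few generations, and life-history /
physiology traits assayed in synchrony with long-established control
populations. The package asks, for each replicate population, whether the
observed change in arrangement frequency can be explained by genetic drift
alone, and, for the phenotypes, how evolutionary rates relate to how far a
population started from the control optimum.

## Drift-null selection test

### Model

Arrangements of one chromosome are mutually exclusive haplotypes, i.e.
alleles of a single multiallelic haploid locus carried in 2N copies by N
diploid flies. Evolution is simulated as a Wright–Fisher chain: each
generation the next cohort's 2·Ne chromosome copies are a multinomial draw
over the current frequencies (all arrangements of a chromosome jointly —
never independent binomials, which would break the simplex constraint).
There is no mutation or migration, so fixation and loss are absorbing. A
genic (haploid) selection option multiplies frequencies by relative
fitnesses w_i = 1 + s_i and renormalizes before each draw; it is used only
by the synthetic-data generator, the test's null is strictly neutral.

### Effective size

Ne is tied to the census N through a ramp: the fraction Ne/N interpolates
linearly from 0.10 at the first karyotyped generation to 0.30 at the last.
The linear shape is the simplest monotone version of "rising from 10% to
30%"; newly wild-derived populations transmit a small fraction of the
census at first and a larger one later. Census records are sparse and are
carried forward across gaps; Ne is rounded to the nearest integer with a
floor of 2.

### Test procedure

For each replicate × chromosome:

1. the observed start-generation sample frequencies are treated as the true
   initial state (no start-uncertainty model);
2. B neutral trajectories (default B = 9999; the desk experiments use
   B = 2000) are simulated to the end generation under the Ne ramp;
3. by default each simulated end state is karyotyped with the observed
   terminal sample size, so the null contains the same terminal sampling
   noise as the observed end frequency;
4. per arrangement, the empirical p-value is the proportion of simulated
   end values ≥ the observed one when the observed frequency rose, ≤ when
   it fell (ties count as extreme; an exactly zero change gives direction
   "none" and p = 1, a conservative convention);
5. Benjamini–Yekutieli FDR (valid under arbitrary dependence, harmonic
   correction c(m)) is applied over all arrangement × replicate p-values of
   one foundation (a per-replicate family is available — the appropriate
   family is genuinely open);
6. a foundation is called as under selection for an arrangement when at
   least two of its three replicates remain significant.

The p-value estimator is count/B, so p = 0 can occur; a (count+1)/(B+1)
flag exists for users who need strictly positive p-values. An arrangement
absent at the start but observed to rise is flagged (`degenerate_null`):
all neutral trajectories stay at zero and the test degenerates.

### Operating characteristics (measured by `inversion_ee.experiments`)

Two properties matter for interpretation, both computed by the calibration
experiment and reported by `scripts/acceptance.py`:

* With the direction of the one-sided test fixed a priori, the empirical
  p-value is calibrated: rejection rate ≈ α under a matched neutral null
  (measured ≈ 0.04–0.05 at α = 0.05 over 216 tests).
* The pipeline chooses the direction from the observed sign of change.
  That sign-selection makes the procedure two-sided with realized size
  ≈ 2α (measured ≈ 0.08–0.12), slightly above 2α because the start
  frequencies are sample estimates treated as exact. Users comparing
  rejection counts against a nominal α should keep this in mind; it is a
  property of the published procedure, reproduced deliberately.

Foundation-call power is modest under desk conditions (constant census 600,
generations 2→25, terminal samples of 100): the Ne ramp 60→180 makes the
neutral null wide, and the BY step (rejection thresholds near 0.0008·k for
an 18-test family) followed by the 2-of-3 consensus discards replicates
with p in the 0.005–0.03 range, where much of the s = 0.10 mass lies.
Measured call rates: ~0 at s = 0, ~0–0.04 at s = 0.05, ~0.3–0.6 at
s = 0.10. This is a property of the stacked correction-plus-consensus
procedure, not of the simulator: per-replicate pre-FDR rejection of s=0.10
effects is high.

## Karyotypic summary statistics

* **Frequency filter** — the ">5% frequency" inclusion rule is implemented
  as a strict max rule: an arrangement qualifies if it exceeds the
  threshold in any replicate-population × generation sample, so initially
  rare but rising arrangements are retained. Scope is per foundation by
  default, jointly across all populations as an option.
* **CMH** — the Cochran–Mantel–Haenszel chi-square combines one 2×2 table
  per replicate (focal arrangement vs all others, initial vs final
  generation), M² = (|Σ(a_k − E a_k)| − correction)²/ΣV_k with
  hypergeometric moments from the stratum margins; df = 1; no continuity
  correction by default. When the initial generation precedes replication
  only a pooled sample exists, and the comparison collapses to a single
  pooled-vs-summed stratum.
* **Slopes** — per-replicate OLS slopes of arcsin(√p) (the standard
  variance stabilizer; a literal arcsin(p) mode exists) against generation;
  foundations are compared by a balanced fixed-effects two-way ANOVA (Year ×
  Location, each effect tested against the among-replicate-within-cell
  mean square on (1, 4(r−1)) df; Type III = Type I under balance). The
  individual-level mixed-model fits of the original analyses are out of
  scope.
* **Differentiation** — Weir–Cockerham-style moment estimators on haploid
  allele counts (each karyotyped chromosome is one allele copy, so no
  heterozygosity terms): θ_p from a one-way layout over populations, θ_f
  from a two-level nested layout (foundations / replicates within /
  chromosomes within replicates) solving the unbalanced expected-mean-square
  equations. Components are summed over alleles and the five chromosome
  "loci" and combined as a ratio of sums; negative estimates are reported
  as computed. With only five loci a bootstrap-over-loci CI is noisy, so a
  permutation test (shuffling sampled chromosomes among populations,
  sample sizes preserved) is offered and preferred.
* **Ordination** — frequencies are mapped to y = 2·√p, pivoted to
  population × generation rows with arrangements as columns (an
  arrangement absent from a scored chromosome is a genuine 0; an unscored
  chromosome raises), and decomposed by eigen-analysis of the variable
  correlation matrix. Axis sign is fixed by making the largest-magnitude
  loading positive, so results reproduce across linear-algebra backends.
  Observation unit is the replicate by default, foundation means as an
  option.

## Phenotype trajectories

All analyses work on deviations from the mean of the synchronously assayed
control populations: plain differences for trajectories, relative
deviations ((exp − ctrl)/ctrl) for the rate-versus-early-differentiation
analysis — two deliberately distinct standardizations. A population's
evolutionary rate is the OLS slope of its standardized trait value on
generation; early differentiation d0 is the relative deviation at the
foundation's first assayed generation. The rate-vs-d0 regression reports
the pooled slope, per-foundation slopes, and an extra-sum-of-squares F
comparing common-slope vs group-specific-slope fixed-effects models; at
replicate level with balanced data this tests the same interaction as the
original mixed-model ANCOVA, and is documented as that approximation. A
per-trait generation cap supports traits whose terminal assays are missing
(male body size).

## Synthetic data

The generator emulates the study design, not its numbers: 2 locations × 2
years (the default preset gives "north" and "south" initial frequencies
differing by ≥ 0.3 on clinal arrangements of chromosomes O and E), one
shared trajectory per foundation from the first karyotyped generation to
replication at generation 4 (replicate non-independence is real and is
modeled), then three independent replicate trajectories; karyotype samples
of 65–159 chromosomes per population-generation; constant census 800
within the 500–1200 maintenance range; phenotype assays of 15–24
individuals per population-generation with control values stationary
around the control mean and experimental means converging geometrically at
a programmed per-generation fraction, with a small lognormal (σ = 0.15)
replicate-specific factor on the initial offset so replicates differ as
founder sampling would make them. The generation truth (selection
coefficients, convergence rates, seeds) is serialized next to the dataset.

What the generator does not emulate: linkage between chromosomes,
dominance or karyotype-level fitness, temporally varying census,
inversion-content differences between locations, and trait-trait
correlations. Tests passing on synthetic data therefore show the machinery
is correct under the model's own assumptions, not that the biological
conclusions transfer.

## Numerical and design choices

* Frequencies are validated to sum to 1 within 1e-9 per group; p0 for the
  simulator within 1e-6.
* The perfect-fit guard in the homogeneity F-test treats residual sums of
  squares below 1e-12·‖y‖² as zero.
* Statistical-significance recovery experiments average over independent
  generator seeds rather than over replicates of one dataset, because
  replicates share the synchronous control means and their errors are
  correlated.
* Desk experiment sizes (6 datasets × 36 arrangement tests for
  calibration, 12 datasets per selection level for power, B = 2000,
  10^5 draws for the one-step variance) were chosen to give stable rates
  at interactive runtimes.
* A single master seed spawns per-stage generators at fixed indices
  (`numpy.random.SeedSequence`), so disabling one pipeline stage never
  changes another stage's randomness.

## Known limitations

* No likelihood or ABC estimation of s or Ne — the drift test is a pure
  null test.
* The realized size of the data-driven-direction test is ≈ 2α (see above).
* Bootstrap CIs over five loci are wide; use the permutation test.
* The hierarchical θ_f uses moment equations; variance components can be
  negative and are not truncated.
* Exact conditional CMH p-values are not provided (asymptotic chi-square
  only).
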