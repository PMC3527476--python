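# Methods

## Scientific setting

Dairy cows are routinely pregnant while lactating, so an embryo's first
months unfold inside a dam under high metabolic load. The analysis asks
whether that circumstance leaves a measurable trace in the daughter's adult
performance. Three exposures are coded per cow at her conception date:

* `lact_group` — 0 when no maternal lactation was open at conception
  (gestation in a heifer), otherwise the parity of the open lactation,
  collapsed to {1, 2, 3+};
* `yield_group` — 0 for non-lactating dams, else the decile (1–10) of the
  dam's daily milk at conception relative to the lactating-dam population,
  with left-open/right-closed boundaries;
* `mastitis` — whether any dam somatic-cell test inside the exposure window
  (conception to 220 d of gestation) exceeds 400,000 cells/ml.

## Two-stage estimation

**Stage 1 (adjustment).** Each trait is fitted with a univariate Bayesian
animal model `y = Xb + Zu + e` with `Var(u) = A σ²_u`. Fixed effects: age at
first parity in 1-month classes, year-region at birth, herd-year at first
calving; the lifespan model adds the cow's own first-lactation milk as a
centered covariate, so the adjusted lifespan is functional longevity
(culling propensity net of the cow's own production level). Age can instead
enter as a covariate (`age_as="covariate"`); the class parameterisation is
the default. Traits are fitted independently.

Priors: flat on fixed effects (full one-hot blocks without an intercept;
the confounded directions are flat random walks that leave `Xb`, residuals
and contrasts identified); scaled-inverse-χ²(ν = 4, S²) on both variances.
The scales S² come from an ANOVA-style moment estimate: residuals of a
fixed-effects-only least-squares fit are decomposed by a one-way paternal
half-sib ANOVA, and four times the between-sire component is the additive
scale (clipped to [10⁻⁴, 0.9] of the total; an h² = 0.25 split is the
fallback when no sire families exist). This keeps the prior scale of σ²_u
on the order of the actual genetic variance instead of an arbitrary share
of the total, which matters because an inflated σ²_u posterior makes the
breeding values absorb part of any unmodelled cow-level signal.

Sampling is single-site Gibbs over all location parameters followed by the
two variance draws, in a JIT-compiled kernel (~10 s for 5,000 iterations on
~25,000 parameters). The chain stores full samples of fixed effects and
variances and running posterior means/variances of the genetic vector; all
downstream operations (residuals, merit percentiles) only consume posterior
means. Default chain: 10,000 iterations, 1,000 burn-in, single chain, the
scheme used in the literature this reimplements; the recovery preset uses
5,000/500.

**Stage 2 (maternal contrasts).** Posterior-mean residuals are treated as
fixed data (no propagation of stage-1 uncertainty — an acknowledged
limitation of the two-stage scheme) and modelled as `ê = μ1 + Mm + e_m`,
one maternal factor per model. Priors: N(0, 10¹⁰) on μ and every level
effect (flat-by-large-variance; residuals keep trait units), scaled-
inverse-χ²(ν = 4, moment scale) on the variance. The conditionals depend on
the data only through level counts/sums and the total sum of squares, so
chains are effectively free. Contrasts `m_level − m_0` are summarised by
posterior mean, batch-means MCSE (30 batches; initial-sequence estimators
would be an acceptable alternative behind the same interface), the 2.5–97.5%
equal-tail interval (reported under the literature's "HPD95" label, which
that literature defines verbatim as these quantiles), and the posterior
sign probability.

**Merit stratification.** Cows are ranked by posterior-mean breeding value
for milk; inside the bottom and top deciles (ties broken by cow id) an OLS
model `residual ~ intercept + concurrence` estimates the binary concurrence
effect with its standard error.

## Pedigree machinery

Inbreeding uses the exact Meuwissen–Luo recursion; `A⁻¹` is assembled by
Henderson's rules with inbreeding-corrected Mendelian-sampling variances
(hard error if a corrupt F table makes one non-positive); the dense tabular
`A` is available for cross-checks on small pedigrees. Unknown parents are
unrelated non-inbred founders — no genetic groups. Completeness statistics
(equivalent generations `Σ(1/2)^g`, per-generation ancestor completeness up
to 14 generations) use an O(n·g) recursion.

## The synthetic herd generator

The generator emulates the structure of multi-decade national milk
recording. Key design choices, with rationale:

* **Pedigree**: discrete generations, founders unrelated, sires heavily
  reused (half-sib families of ~80 daughters), final-generation females are
  the analysis cows with one recorded daughter per dam. Recovery preset:
  2,000 founder females + 120 sires, generations of 3,000 / 10,000 /
  10,000 → ~25,000 individuals, ~10,000 analysis cows.
* **Breeding values**: founders N(0, σ²_u); offspring = parent average +
  Mendelian deviate with variance σ²_u(0.5 − 0.25(F_s + F_d)).
* **Calendar**: conception dates are uniform over a 15-year recording
  window and each dam's calving history is reconstructed backwards from her
  daughter's conception. This is the steady state of a long-running scheme;
  a forward construction from a narrow dam birth cohort would make maternal
  parity nearly collinear with the daughter's birth year and the year
  effects would then absorb much of any maternal signal (verified by
  projecting planted effect vectors onto the design: 25–50% absorbed in a
  2-year window, ~2% in the steady-state construction).
* **Conception timing**: shifted log-normal, shift 30 d (voluntary waiting
  period), with (μ, σ) solved so the density mode is 73 d and 80% of mass
  lies in [54, 160] d — the two summaries available for the real
  population. Infeasible mode/window requests raise.
* **Dam milk at conception**: a Wood-type lactation curve
  (t^0.25·e^(−0.0035t), peak ≈ 71 DIM) scaled to the dam's 305-d total for
  the open parity; monthly test days add 0.8 kg measurement noise, from
  which preprocessing reconstructs the daily yield (nearest test by
  default, linear interpolation as an option). Table-style decile groups
  therefore blur by about one group either way — deliberate measurement
  realism.
* **Mastitis**: flags drawn so the overall exposed share is 13% (only dams
  with an open lactation can be flagged); a flagged dam gets one
  somatic-cell test above 400,000 cells/ml placed inside the exposure
  window, on a log-normal baseline (median 100k, σ_log 0.4) whose natural
  exceedance rate is negligible.
* **Traits**: trait = mean + herd-year + year-region + age-class effects
  (iid normal levels with configurable sd) + u + planted maternal effects +
  noise. Lifespan additionally gains `0.02 d/kg × (MY − mean)` — a minimal
  culling mechanism that the stage-1 milk covariate must absorb — and can
  use exponential noise (paper-scale preset) instead of normal (recovery
  preset).
* **Filter-exercise rows**: 1% of cows carry a pre-first-lactation abortion
  flag and 0.5% a first-lactation total below 1,000 kg, so the record
  filters always have work to do.

**Presets.** `paper-scale` mimics the real population's magnitudes (mean MY
≈ 8,500 kg, phenotypic sd ≈ 1,550 kg, h² ≈ 0.3). `recovery` is the
validation condition: residual sd shrunk to 100 kg MY / 30 d DIM / 0.15% FP
so planted contrasts of tens of units are estimable at n ≈ 10⁴, and
σ_u/σ_e = 0.1. The genetic ratio is kept small **by design**: posterior-mean
breeding values absorb a share w ≈ ½σ²_u/(½σ²_u + σ²_e) of any cow-level
effect omitted from stage 1, so at h² = 0.3 the two-stage scheme itself
attenuates maternal contrasts by ~8–18% (a property of the method, visible
in `test_residuals_track_planted_effects_when_omitted`), while at the
recovery ratio the leakage is under 1% and recovery isolates
implementation correctness. Herd-year cells hold ~70 cows; estimating a
cell effect from m observations mechanically absorbs ~1/m of any cow-level
signal, so small cells would bias recovery the same way. `smoke` is a
400-cow miniature for fast tests.

The generator does **not** model: within-lactation test-day dynamics beyond
the Wood curve, seasonality, heifer growth-rate heterogeneity, genotypes,
non-random mating, or selection over time. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the assumed
data-generating process, not robustness to the confounding structures of
real field data.

## Known limitations and numerical notes

* The merit-stratified coefficient is intrinsically attenuated when the
  planted interaction is defined on *true* top-decile merit but strata are
  formed from *estimated* merit: the measured coefficient equals
  planted × (1−w) × P(true top | estimated top), and at h² = 0.3 the decile
  classification precision is bounded near 0.45–0.55 by attainable EBV
  accuracy (own record + half-sib information). The suite asserts the
  published magnitude band as stated, and the bottom-stratum null check is
  the informative companion.
* Stage-2 treats residuals as data; no stage-1 uncertainty propagation.
* 305-d standardization is linear in lactation length with the length
  capped at 400 d (longer records are treated as recording artefacts).
* Decile boundaries use numpy's linear-interpolation percentiles; with
  heavy ties all mass falls into group 1 by the right-closed rule.
* MCSE requires ≥ 100 samples (10+ batches); constant chains return 0.
* Chains are reproducible given a seed; the stage-1 kernel uses numba's
  per-thread RNG seeded from the config.
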