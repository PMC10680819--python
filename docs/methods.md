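# Methods

## Model

The package analyzes growth-rate effects Δλ_mge (h⁻¹) of mutations *m*
measured in background strains *g* under environments *e*, together with
the strains' background growth rates λ_ge. The working model has two
levels.

**Microscopic (per mutation).** Within one environment, effects are
linear in the background growth rate,

    Δλ_mge = a_me + b_me λ_ge + ξ_mge,

with idiosyncratic residual ξ_mge. Two empirical regularities motivate a
reduction: slopes are nearly environment-independent (b_me ≈ b_m), and
intercepts track slopes as a_me = −λ̄_e b_me + η_me with zero-mean pivot
noise η_me. Substituting gives the generalized global-epistasis equation

    Δλ_mge = b_m (λ_ge − λ̄_e) + η_me + ξ_mge,

in which the environment enters only through the pivot growth rate λ̄_e:
the background growth rate at which a typical mutation's effect changes
sign.

**Macroscopic (DFE).** Treating b as a random draw per mutation with
mean μ_b, variance σ_b² and third central moment γ_b, and assuming b, η,
ξ mutually independent with η, ξ zero-mean and symmetric, the DFE in a
strain with adjusted growth rate x = λ_ge − λ̄_e has

    mean(x) = μ_b x
    var(x)  = σ_b² x² + σ_η² + σ_ξ²        (+ σ_meas² for measured data)
    m3(x)   = γ_b x³,   skewness(x) = m3 / var^{3/2}.

All odd central moments vanish and all even ones are minimized at x = 0.
These closed forms are cross-checked in the test suite against a
Monte-Carlo oracle (10⁶ draws from the generative model, batch-based
standard errors) over randomized parameter sets realized with a
shifted-gamma slope family whose third moment is known analytically.

## Synthetic-data generator

The generator emulates a bulk barcoded competition assay: 99 mutations
of which 5 form a putatively neutral reference, 42 background strains,
6 environments. Defaults (all rates h⁻¹):

| parameter | default | meaning |
|---|---|---|
| μ_b, σ_b | −0.5, 0.3 | slope ensemble (normal; truncated-normal optional) |
| λ̄_e | 6 values on [0.25, 0.45] | pivot growth rate per environment |
| σ_η | 1.7×10⁻² | pivot-noise SD |
| σ_ξ | 1.0×10⁻² | idiosyncratic-epistasis SD |
| σ_meas | 7×10⁻³ | measurement-error SD per entry |
| strain rates | uniform on [λ̄_e − 0.15, λ̄_e + 0.10] | true background growth rates |
| missing_fraction | 0 | independent missingness probability |

True background growth rates are drawn independently per environment on
an environment-specific interval. The interval straddles the pivot so
that sign proportions vary across strains and the DFE mean crosses zero
inside the observed range, and the independent draws make strain rank
orders reshuffle across environments by default. Measured growth rates
add N(0, σ_meas²) noise.

**Reference normalization.** Measured effects are reported relative to
the mean measured effect of the 5 reference mutations within each strain
× environment, mirroring neutral-reference designs; the reported
standard error is σ_meas·√(1 + 1/n_reference). Reference mutations have
b = 0, η = 0, ξ = 0 exactly; their adjusted effects (exactly mean-zero
per cell) are exposed through the ground truth rather than the effect
table, so downstream stages see only the 94 analyzed mutations. The
ground truth also records the raw per-entry measurement-noise draws so
that noise calibration can be checked on either side of the reference
adjustment.

**What is not emulated.** Read counts, barcode-frequency dynamics and
lineage tracking are not modeled; Gaussian error on the effect scale
stands in for the whole measurement chain. Missingness is missing
completely at random; real assays lose measurements preferentially in
slow-growing or low-coverage contexts. Environments perturb only the
pivot and the strain-rate interval — there are no environment-specific
slope changes, so tests passing on these data show that the estimators
recover the model's structure when it holds, not that real data obey it.
All draws flow from a single seeded NumPy generator, making every
dataset bit-reproducible.

## Estimators and numerical choices

- **Sign calls** use two-sided normal CIs (default level 0.99):
  beneficial iff the lower bound exceeds 0, deleterious iff the upper
  bound is below 0. Effects aggregate many barcode observations, so the
  normal approximation is appropriate. Proportions are computed over
  non-missing measurements per strain.
- **Per-(mutation, environment) fits** are ordinary (unweighted) least
  squares of Δλ on λ, ignoring error in the regressor; measurement SEs
  are carried along for downstream weighting only. The regressor-noise
  attenuation at default settings is ≈1% of the slope, well below its
  standard error. A fit needs ≥3 strains (two points fit any line
  exactly). Constant effects return slope 0 with p = 1.
- **Model significance per mutation** is an F-test of the full
  per-environment-lines model against a single grand mean, pooled over
  the mutation's measurements; variance explained is reported from the
  same pooled comparison.
- **Benjamini-Hochberg** is the standard step-up procedure (adjusted
  p(i) = min over j ranked at or above i of m·p(j)/j, capped at 1), with
  three families: model F-tests across mutations, slope/intercept
  t-tests across all fits, pairwise slope tests across all pairs.
- **Slope-equality tests** use t = (b₁−b₂)/√(SE₁²+SE₂²) with
  Welch-Satterthwaite degrees of freedom built from the per-fit residual
  degrees of freedom (n−2).
- **Invariant-slope model**: one common slope plus per-environment
  intercepts, solved by least squares on an explicit design matrix; the
  full model adds per-environment slopes. Both R² values use the pooled
  total sum of squares around the mutation's grand mean, so nesting
  guarantees r2_shared ≤ r2_full.
- **Pivot estimation** is a through-origin regression of intercepts on
  slopes (the relation a = −λ̄ b + η has no intercept term);
  λ̄ = −Σab/Σb², SE² = [Ση²/(n−1)]/Σb². A diagnostic fit with a free
  intercept is reported so a material violation can be flagged. All
  successfully fitted mutations enter by default; a switch restricts to
  BH-significant slopes as a robustness check. Pivot residuals are taken
  from this regression, not re-estimated jointly. Pivot differences use
  two-sided z-tests, BH-corrected over pairs.
- **DFE moments** use divisor-n estimators (variance = m₂, skewness =
  m₃/m₂^{3/2}, no bias correction) to match the population moments the
  model predicts. SEs come from a nonparametric bootstrap over mutations
  (default 1,000 resamples, seeded). Cells need ≥20 observed mutations
  (configurable) to enter moment-curve fits. Moment curves are weighted
  least squares with 1/SE² weights: mean = μ_b·x through the origin,
  variance = σ_b²·x² + floor, m3 = γ_b·x³ through the origin, alongside
  unconstrained degree-1/2/3 polynomials as descriptive fits. The
  theory-side variance includes the measurement variance by default so
  that comparisons against measured data are like-for-like.
- **Pivot from the DFE mean** is the root of the OLS line of per-strain
  DFE means on growth rates, flagged as extrapolated when the root lies
  outside the observed range — the estimator of choice for a new
  environment where only DFE means are available.
- **DFE similarity** is the two-sample Kolmogorov-Smirnov statistic.
  Cross-environment strain pairs are matched nearest-neighbor within
  0.01 h⁻¹ on adjusted or absolute growth rate (unmatched strains
  dropped); one-sided Mann-Whitney rank-sum tests compare the resulting
  distance samples.
- **Rank reshuffling** splits items at the median rank per environment,
  descending by value with ties broken by item id; with odd counts the
  middle item belongs to the top half.

## Problem sizes

The validation suite and the acceptance script run on the generator's
default scale — 94 analyzed mutations × 42 strains × 6 environments
(≈24k measurements) — which matches the assay design the defaults
emulate; repeated-seed checks use 20 replicate datasets, and the
Monte-Carlo moment oracle uses 10⁶ draws per parameter set. At this
scale the whole pipeline runs in a few seconds on one CPU.

## Known limitations

- Two-stage estimation (fits, then pivot regression) slightly inflates
  the recovered pivot-noise SD through slope/intercept estimation error
  (≈1% at default settings, larger for fewer strains); a joint
  maximum-likelihood treatment is deliberately out of scope.
- The slope-variance debiasing in `params_from_fits` subtracts the mean
  squared slope SE and clips at zero; with very noisy fits the clip
  biases σ_b² upward from zero.
- Unweighted OLS is mildly inefficient when measurement SEs vary across
  entries; in the generator they do not.
- The DFE distance and the matching tolerance are pragmatic choices;
  conclusions about *which* pairing collapses the DFE are insensitive to
  the tolerance at default noise levels, but the absolute KS values are
  not comparable across sample sizes.
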