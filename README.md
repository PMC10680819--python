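# pivotdfe

Global-epistasis analysis of mutation fitness effects measured across
many genetic backgrounds and environments: per-mutation linear fits,
environment-specific **pivot growth rates**, and predictions of the
**distribution of fitness effects (DFE)** as a function of the
environment-adjusted background growth rate.

## The problem

High-throughput competition assays can measure how a panel of mutations
changes the growth rate λ (h⁻¹) of many background strains in several
environments. The effects Δλ_mge of a mutation *m* in strain *g* and
environment *e* typically display *global epistasis*: they decline
roughly linearly with the background growth rate,

    Δλ_mge = a_me + b_me · λ_ge + ξ_mge,

where b_me is the global-epistasis slope, a_me the intercept and ξ_mge
the residual ("idiosyncratic") epistasis. When slopes are nearly
environment-independent and intercepts satisfy a_me ≈ −λ̄_e · b_me + η_me,
the model collapses to the generalized global-epistasis equation

    Δλ_mge = b_m · (λ_ge − λ̄_e) + η_me + ξ_mge,

in which the environment acts through a single parameter, the pivot
growth rate λ̄_e — the background growth rate at which a typical mutation
switches sign. Writing x = λ_ge − λ̄_e for the adjusted growth rate, the
DFE moments follow closed forms: mean μ_b·x, variance σ_b²·x² + σ_η² +
σ_ξ², and third central moment γ_b·x³, where (μ_b, σ_b², γ_b) are the
moments of the slope ensemble. The package implements the full chain:

- **synthgen** — a synthetic-data generator with known ground truth that
  emulates the assay design (94 analyzed + 5 neutral-reference
  mutations, 42 strains, 6 environments, reference-normalized
  measurement error of 7×10⁻³ h⁻¹);
- **signcalls** — beneficial/deleterious/neutral calls from 99% normal
  confidence intervals, sign-proportion regressions and rank-reshuffling
  statistics;
- **gefit** — per-(mutation, environment) OLS fits, Benjamini-Hochberg
  correction, pairwise slope-equality tests and the invariant-slope
  (parallel-lines) model;
- **pivot** — through-origin regression of intercepts on slopes giving
  λ̄_e, its SE and the pivot-noise residuals η_me;
- **dfe** — empirical DFE moments with bootstrap SEs, the closed-form
  moment predictions, moment-curve fitting, pivot estimation from the
  DFE-mean zero crossing, and matched-pair DFE comparisons
  (Kolmogorov-Smirnov distances, rank-sum tests).

It is aimed at researchers analyzing bulk fitness assays across
genotypes and environments, and at anyone who wants a fully simulatable
testbed for global-epistasis statistics.

## Worked example

```python
import pivotdfe as pdfe

config = pdfe.GeneratorConfig(seed=1)          # assay-scale defaults
growth, effects, truth = pdfe.generate_dataset(config)
result = pdfe.run_pipeline(effects, growth, seed=1)

s = result.summary
print(f"significant slopes: {s['epistasis']['frac_slopes_significant']:.1%} "
      f"({s['epistasis']['frac_negative_among_significant_slopes']:.1%} negative)")
print(f"variance explained: full {s['invariant_slope']['mean_r2_full']:.1%} vs "
      f"invariant-slope {s['invariant_slope']['mean_r2_shared']:.1%}")
for env, piv in s["pivots"].items():
    print(f"pivot {env}: {piv:.3f} h^-1 (true {truth.pivots[env]:.3f})")
print(f"pooled pivot-noise SD: {s['pivot_noise_pooled']['sd']:.4f} h^-1")
print(f"DFE collapse rank-sum p: {s['dfe_matched_pairs']['p_adjusted_vs_absolute']:.2e}")
```

Output:

```
significant slopes: 97.3% (98.5% negative)
variance explained: full 88.8% vs invariant-slope 88.6%
pivot env1: 0.246 h^-1 (true 0.250)
pivot env2: 0.290 h^-1 (true 0.290)
pivot env3: 0.326 h^-1 (true 0.330)
pivot env4: 0.374 h^-1 (true 0.370)
pivot env5: 0.413 h^-1 (true 0.410)
pivot env6: 0.448 h^-1 (true 0.450)
pooled pivot-noise SD: 0.0177 h^-1
DFE collapse rank-sum p: 1.72e-144
```

Reading the numbers: nearly all per-environment slopes are significantly
nonzero and negative (global epistasis), a shared per-mutation slope
loses almost no explanatory power relative to six environment-specific
slopes (slope invariance), the six pivot growth rates are recovered to
within a few 10⁻³ h⁻¹, the pivot-noise SD matches the generating value
of 1.7×10⁻² h⁻¹, and DFEs of strains matched on *adjusted* growth rate
are far more similar than DFEs matched on absolute growth rate — the
single-parameter environmental collapse.

The same pipeline is available from the shell:

```sh
pivotdfe simulate --seed 1 --out sim/
pivotdfe report --effects sim/effects.csv --growth sim/growth.csv --out report/
```

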