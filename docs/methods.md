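# Methods

`svclogit` fits Bayesian logistic regression models for a binary disease
outcome observed on individuals nested in a small set of contiguous regions
(the motivating setting: nine provinces, a household survey of respondents
aged 35+, outcomes such as diabetes or hypertension status).  This note
records the model, the priors, the sampler, the synthetic-data generator,
and the numerical and design choices a maintainer would want explained.

## The model grid

For individual *i* in region *j*, `y_ij ~ Bernoulli(p_ij)` with
`logit(p_ij)` built from up to six components:

| piece | form | prior |
|---|---|---|
| intercept `β0` and fixed effects `β` | `β0 + x'β` | N(0, 1000) |
| unstructured region effect `ν_j` | exchangeable heterogeneity | iid N(0, 1/τ_ν) |
| structured region effect `s_j` | spatial smoothing | intrinsic CAR, precision `τ_s (D − W)` |
| varying coefficients `π_cj = μ_c + φ_cj` | region-specific slope for covariate c | `μ_c ~ N(0, 1000)`, `φ_c ~` proper CAR, precision `λ_c (D − ρW)` |
| non-linear age effect `f(age)` | one bin per integer year | RW2, precision `τ_a D2'D2` |

The eight-model grid is the usual progression: Models 1–4 are stationary
(fixed effects, +ν, +s, +ν+s; age enters linearly, centred, per 10 years),
Models 5–8 repeat the progression with spatially varying coefficients and
the RW2 age smooth in place of the linear term.

All GMRFs are parameterized by **precision** scalars; variance-scale
numbers appear only in reporting.  The proper-CAR weights follow
`g_ik = ρ a_ik / d_i` with conditional variances `τ_i² = σ²/d_i`, the
standard scheme satisfying the CAR symmetry condition; the propriety
parameter is fixed at ρ = 0.9 (config knob `HyperPriors.car_rho`, not
sampled).  Regions with no neighbours are rejected at graph-build time
because the intrinsic-CAR conditional (the neighbour average) is undefined.

Identifiability: `s` carries a sum-to-zero constraint per connected
component, `f_age` a sum-to-zero constraint, and each `φ_c` a sum-to-zero
constraint with the mean carried by `μ_c`.  Constraints are enforced by
post-sweep re-centring with the removed mean transferred into `β0` (or
`μ_c`), which leaves the linear predictor unchanged; for a connected graph
the transfer is exact.  No zero-linear-trend constraint is placed on
`f_age` — there is no separate linear age term in Models 5–8, so the trend
belongs to the smooth (this is what lets a monotone age-risk curve be
estimated at all).

## Posterior computation

The sampler is a Pólya-Gamma-augmented Gibbs scheme.  Augmenting each
record with `ω_i ~ PG(1, η_i)` makes the Bernoulli-logit likelihood
conditionally Gaussian in every linear block (working response
`z_i = (y_i − ½)/ω_i`, weight `ω_i`), so all updates are exact draws:

1. `ω_i | η_i` — exact Devroye alternating-series sampler for PG(1, z),
   written for this package (numba-jitted; validated against the
   closed-form PG moments and Laplace transform).
2. The fixed block `(β0, β, μ)` — one dense multivariate-normal draw.
3. Each GMRF block (`φ_c`, `ν`, `s`, `f_age`) — a multivariate-normal draw
   at region/bin dimension.
4. Each GMRF precision (`λ_c`, `τ_ν`, `τ_s`, `τ_a`) — **slice-sampled from
   its conditional with the corresponding block integrated out** of the
   working Gaussian model, immediately before the block is redrawn.

Step 4 deserves the explanation.  The conjugate Gamma update for a GMRF
precision is valid but, with only nine regions, falls into a near-absorbing
funnel: once a block is shrunk to ~0 its quadratic form is ~0, the Gamma
conditional then concentrates at very large precision, which pins the block
at zero on the next sweep.  In testing, the varying-coefficient precision
locked at the prior mode (~2000) even when the marginalized posterior
favoured precision ≈ 2 by ~24 log-units.  Because the augmented model is
linear-Gaussian given ω, the marginal likelihood of the precision with the
block integrated out is available in closed form (one Cholesky per
evaluation), so the precision can be updated on the collapsed space and the
block redrawn afterwards — a valid joint blocked draw that removes the
funnel entirely.  Slice sampling (stepping-out/shrinkage, width 1 on the
log scale) keeps the update exact without tuning.

Hyperpriors: all precisions get Gamma(1, 5·10⁻⁴) (the weakly informative
disease-mapping default; shape/rate exposed in `HyperPriors`).  Fixed
effects and SVC means get N(0, 1000).

Chain defaults are 12,000 iterations, 2,000 burn-in, thinning 2; a seed is
mandatory and drives every random draw including the PG streams.  DIC needs
only the per-draw deviance and the running mean of the linear predictor,
both accumulated online, so draws files stay small.  `pD` uses the standard
plug-in at the posterior-mean linear predictor; negative `pD` is reported
with a flag, never clamped.

## Synthetic-data generator

The generator (`svclogit.simulate`) emulates a nine-region household
survey of respondents aged 35+ using exactly the Model-8 generative
structure; simpler truths are obtained by zeroing components:

* ~5,571 records split across regions in the provincial proportions of
  such a survey; covariate level frequencies from its descriptive table
  (the rural share is the complement of the urban share);
* discrete-uniform ages 35–80, one RW2 bin per integer year;
* outcome prevalence anchored by the intercept (default 10%,
  diabetes-like; 35% is used for the hypertension-like scenarios);
* structured effects drawn *exactly* from the constrained intrinsic CAR via
  the eigendecomposition of the pseudo-inverse of Q (per connected
  component, no MCMC inside the generator); varying coefficients from the
  proper CAR; a logarithmic default age curve (centred, range = amplitude,
  default 1 on the log-odds scale).

What the generator does **not** emulate: the two-stage PPS survey design,
household clustering, survey weights, item-level missingness patterns, or
measurement error in self-reported disease status.  Passing recovery tests
therefore demonstrate correctness of the inference under the model's own
assumptions, not robustness to real-survey complications.

## Validation studies (frozen scenarios)

`svclogit.scenarios` freezes the three simulation studies used by the test
suite and `scripts/acceptance.py`:

* **Recovery** (Models 4 and 7; 9 regions, n = 5,000, 20 seeds, 1,200
  sweeps / 400 burn-in): 95% credible intervals for the non-varying fixed
  effects must cover truth ≥ 90% of the time with mean absolute bias
  < 0.15.  The scenario's covariates are those whose rarest level clears
  the events-per-variable ≥ 10 design floor at 10% prevalence; a 1%-
  frequency level (~5 expected events) is excluded because its
  posterior-mean bias is a property of such a cell, not of the sampler.
* **Selection** (Model 7 vs Model 3, 20 seeds per arm): prevalence 35%
  (the higher-information outcome), per-region coefficient sd ≈ 0.3 on the
  log-odds scale as "moderate" non-stationarity, and a zero age effect in
  both arms so the contrast isolates coefficient heterogeneity rather than
  RW2-versus-linear age treatment.  A pilot power analysis fixed these
  conditions: at 10% prevalence the per-region interaction information is
  too weak for any method (frequentist interaction standard errors 0.4–0.6
  against a 0.2–0.3 signal).
* **Age** (Model 7, logarithmic truth, 35% prevalence, 5 seeds): the
  posterior-mean curve must Spearman-correlate > 0.9 with truth and with
  the age grid (monotonicity), both as medians over seeds.  Medians are
  used because single-seed rank correlations fluctuate between ~0.86 and
  1.0 purely through the ordering of near-tied bins in the log curve's
  flat upper tail; the 35% prevalence matches the selection study's
  information rationale (46 integer-year bins need per-bin events).

Sampler correctness is checked separately against dense numerical-
integration posteriors (intercept-only and one-covariate models, n ≤ 50,
50,000 retained draws, Kolmogorov–Smirnov distance < 0.03).  The oracle
CDF is accumulated trapezoidally; a left-Riemann cumulative sum carries a
half-bin bias that would dominate the KS distance at coarse spacings.

## Numerical choices and degenerate inputs

* Gaussian draws use precision-Cholesky (`cho_factor` + triangular solve).
* CAR propriety is asserted (symmetry to 1e−10 relative, positive
  definiteness); `ρ` outside [0, 1) and conditional variances incompatible
  with the weight scheme are rejected.
* Covariate columns with zero variance after eligibility filtering are
  dropped with a warning; unseen categorical levels at encode time raise.
* Percentages are rounded half-up to one decimal in descriptive tables.
* Empty age bins are handled by the RW2 prior coupling; the precision
  `τ_a K + diag(weights)` stays positive definite whenever two distinct
  bins are occupied.
* A non-finite linear predictor aborts the chain with a diagnostic state
  dump.

## Known limitations

* With nine regions, GMRF precisions are weakly identified; posterior
  summaries of `τ_s`, `λ_c` are prior-sensitive and should not be
  over-interpreted.
* The per-component re-centring transfer into a single intercept is exact
  only for connected graphs; for disconnected graphs the size-weighted
  transfer is approximate and the chain rebuilds the linear predictor.
* DIC is computed from the identity `D̄ + pD` with the plug-in at the mean
  linear predictor; alternatives (WAIC, LOO) are out of scope.
* The CLI draws file is CSV (scalar chains); very long chains with many
  spatially varying covariates produce wide files.
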