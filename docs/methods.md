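# Methods

## Process model

A tree-year is described by two latent quantities: an absorbing
maturation state ρ and a conditional fecundity ψ (seeds per year given
maturity); realized fecundity is f = ρψ.  While immature, a tree
transitions to maturity each year with probit hazard Φ(β0^ρ + β1^ρ d),
d the diameter in cm; once mature it stays mature, and any year with an
observed crop pins maturity for all later years.  Conditional fecundity
is log-linear in the covariate row (intercept, d, d², shade class 1–5,
CEC in cmol(+)/kg, temperature and moisture-deficit site means and
anomalies, and the terrain vector u1 = sin slope, u2 = sin slope·sin
aspect, u3 = sin slope·cos aspect), plus a per-tree Normal(0, τ²_ind)
intercept, a year effect γ_{g,t} ~ Normal(0, τ²_yr) shared within each
species × ecoregion group g (the phenomenological representation of
masting synchrony), and Normal(0, σ²) process noise.

Climate anomalies are defined relative to each site's mean over its own
observation years; no external normals period is assumed (the window is
a config choice, `anomaly_window`).

## Data models

Seed traps: the expected count in a trap of area A at distance r from
each tree is A·Σ f·k(r) with the 2Dt kernel k(r) = u/(π(u + r²)²)
(shape parameter fixed at 1).  This family is fat-tailed, integrates to
one over the plane, and is the established choice for seed-shadow
inversion in masting networks; the kernel scale u (m²) is per species
and fixed at its configured value by default, with joint estimation
available behind `estimate_kernel_scale`.  Counts are Poisson; counts
recorded at genus level use the intensity summed over congeneric trees,
which is what couples congeners during fitting.

Crop counts: the observer reports a count of reproductive structures
and an estimate φ̂ of the fraction of the crop observed.  The realized
fraction is Beta(νφ̂, ν(1−φ̂)) and the count is Binomial(f, φ), giving a
beta-binomial likelihood with concentration ν (default 50).  φ̂ = 1 is
a point mass at the full crop.  A count exceeding the current integer
fecundity has zero likelihood rather than being clipped, so the sampler
is pushed toward states consistent with the data.  One structure is one
seed unless a per-species multiplier is configured.

## Inference

Metropolis-within-Gibbs, ≥ 2 chains:

* log ψ per tree-year: adaptive random-walk Metropolis against the
  Gaussian process prior and both data likelihoods, with cached trap
  intensities updated incrementally.  Step sizes adapt toward a 0.44
  acceptance rate during burn-in only, so the post-burn-in chain is
  Markovian.  Tree-years touched by no observation are drawn exactly
  from their conditional prior.  exp(log ψ) is capped at e^60 to keep
  Poisson terms finite under extreme proposals.
* maturation: the first-mature year of each tree is drawn exactly by
  enumerating all T+1 candidates; the log-likelihood of each candidate
  is assembled from prefix/suffix sums of the per-year "fertile" vs
  "sterile" contributions.  This is a Gibbs draw, preserves the
  absorbing structure by construction, and automatically forces
  maturity where trap counts are attributable to only one tree.
* probit maturation coefficients: Albert–Chib latent-variable update on
  the at-risk transition events.
* fixed effects, random effects, variances: standard conjugate
  Gaussian and inverse-gamma updates over mature tree-years only.
  Year effects are shrunk by their Normal(0, τ²_yr) prior rather than
  hard-centered; the generative direction centers within group.

Priors (weakly informative, on the standardized covariate scale):
Normal(0, 10²) fixed effects, Normal(0, 2²) probit coefficients,
inverse-gamma(2, 1) on σ², τ²_ind, τ²_yr.  Continuous design columns
are centered and scaled with stored transforms so coefficients can be
reported on the raw scale.  Convergence is reported per fixed effect as
Gelman–Rubin R̂ with a 1.1 flag threshold — report-only, never an
automatic rerun.  DIC = D̄ + pD with pD = D̄ − D(θ̄), the plug-in
deviance evaluated at the posterior-mean fecundities.

Variance parameters are per species; congeners share nothing except the
trap likelihood.  A `pool` option is deliberately absent — pooled
variants can be emulated by relabeling species, which the posterior is
invariant to (tested).

## Production summaries

Weights are inverse CVs, w = f̂/s: small, noisy estimates get little
weight.  Degenerate cases: f̂ = 0 gets w = 0 (excluded from the mean);
s = 0 with f̂ > 0 would make w unbounded, so it is capped at the 99th
percentile of the finite weights.  ISP = (m/b)·Σw f̂/Σw in g·m⁻² of
basal area, with b taken at the last observed diameter; SSP and GSP are
inverse-CV-weighted means over trees; GSP's standard error is
(1/n_k)·√Σs², where n_k counts tree-year observations (the sum inside
the radical runs over tree-years, so n_k is on the same scale).  CSP =
Σ ISP / plot area, g per ha of forest floor, computed only for
inventory plots with known area — never by extrapolating trap counts to
per-area seed rain, which the trap geometry does not support.
Summaries include only trees whose posterior maturation probability
exceeds 0.5 in at least one year (configurable), matching the analysis
restriction to mature trees.

The benchmark conversion uses two Taylor terms for the expectation of
10^α when α̂ carries error s_α: E(10^α) ≈ 10^α̂(1 + s_α²l²/2) ± 10^α̂ s_α l,
l = ln 10.  Worked per-tree yields multiply this expectation (scaled by
m^β̂) by basal area π(d/200)²; the Taylor correction is applied by
default because the headline yields are expectations of a lognormal
quantity, not plug-ins (pass s_alpha=0 for the plain power law).

## Comparative analyses

The trade-off regression is unweighted OLS of log₁₀SSP on log₁₀m
(weighted variants can be run directly through statsmodels on the
returned frame); the seed-number slope β − 1 is reported against the
strict trade-off null of −1.  The by-order variant adds order as a
factor with an order × seed-size interaction; orders with fewer than 3
species are pooled into "other".

Pagel's λ multiplies the off-diagonal entries of the Brownian-motion
tip covariance (C[i,j] = depth of the MRCA).  The ML fit profiles the
root mean and rate σ² analytically and optimizes λ on [0, 1] by bounded
scalar search with endpoint checks, so log L(λ̂) ≥ log L(0) and
≥ log L(1) by construction.  The LRT p-value against λ = 0 uses the
plain χ²₁ upper tail; because λ = 0 is a boundary value this is
conservative by roughly a factor two, a deliberate choice kept for
simplicity.  Phylogenetic GLS uses the same λ-transformed covariance
with λ estimated jointly by ML (or fixed), and coefficient standard
errors use the n−p–corrected rate.  Ancestral states are the GLS
conditional expectations of internal nodes given the tips; the root
estimate equals the GLS mean.  Both λ and the GLS path are
cross-checked in the tests against a dense multivariate-normal oracle
and against R (phytools::phylosig).

β_cec eligibility defaults to a CEC span of ≥ 10 cmol(+)/kg across
≥ 3 distinct sites — species seen at one site or a narrow fertility
band cannot support a within-species response estimate.  Ineligible
species are flagged with a reason, never dropped.  Response curves are
predicted holding other covariates at references: half the species'
maximum observed diameter, shade class 3 ("medium"), site-mean
climate.  Per-species signs are reported raw, with no multiple-testing
adjustment, as a descriptive summary.  The CSP-fertility analysis is
OLS of log₁₀CSP on plot CEC.

## Synthetic data

The generator produces exactly the structure the model assumes:
absorbing probit maturation, log-linear ψ with the three random
components, 2Dt seed shadows with Poisson trap counts (optionally
genus-level with congeneric pooling), beta-binomial crop counts, and
λ-scaled Brownian traits on Yule phylogenies (rescaled to unit depth,
terminal edges extended past the final speciation so all branch lengths
are positive).  Each stage draws from an independent child stream of
one root seed, so enlarging one stage never perturbs another.

Default study conditions for the recovery experiments: stands of 20
trees observed 10 years by 5 traps of 0.5 m², maturation hazard
Φ(−2 + 0.1d), fecundity intercept 6.5 and diameter effect 0.03 on the
log scale (≈ 1,500 seeds for a 30-cm tree), τ_ind = 0.3, τ_yr = 0.4,
σ = 0.4, kernel scale 80 m², crop counts on half the tree-years with
φ̂ = 0.5 and ν = 50.  These are modest, realistic magnitudes for a
temperate masting stand and small enough that a 2-chain, 1,200-iteration
fit takes seconds; the recovery tests run 20 such worlds.  λ-recovery
tests use 200-tip trees with 100 replicates per generating λ.

What the generator does not emulate: spatially explicit or anisotropic
dispersal, resource-budget masting dynamics (synchrony is
phenomenological), temporal autocorrelation in ε beyond year effects,
measurement error in diameters, or real geographic/climatic structure.
Passing tests therefore demonstrate internal consistency of the
inference under the model's own assumptions at desk scale, not
robustness to the full messiness of field data or to continent-scale
sample sizes.

## Numerical notes

* Beta-binomial pmf: lgamma-difference evaluation loses precision when
  ν is extreme; above ν = 10⁶ the gamma ratios are evaluated as exact
  sums of log integer offsets (counts are integers), which reproduces
  the binomial limit to ~1e-9.
* Maturation enumeration works with separate "fertile"/"sterile"
  per-year log-likelihoods rather than their difference, so −∞ terms
  (hard exclusions) propagate without producing NaNs.
* Design matrices are checked for rank; collinear columns are named in
  the error.
* Tree tips are matched to species case-insensitively; unmatched tips
  are reported, and trees with non-positive branch lengths are rejected
  where the λ transform would be undefined.
* Missing diameter years are linearly interpolated inside a tree's
  observed window and flagged, never extrapolated.
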