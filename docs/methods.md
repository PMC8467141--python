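# Methods

## The model

`gphurdle` fits count responses that are simultaneously zero-inflated (or
zero-deflated) and over- (or under-) dispersed, the situation typical of
self-reported illness counts such as ear infections among swimmers: far more
zeros than a Poisson law predicts, and a sample variance several times the
mean among the positive counts.

The building block is the two-parameter generalized Poisson distribution
(the mean/dispersion, "GP2", parameterisation):

    Pr(Y = y) = [μ/(1+αμ)]^y (1+αy)^(y−1)/y! · exp(−μ(1+αy)/(1+αμ))

with mean E[Y] = μ and variance Var[Y] = μ(1+αμ)². The dispersion parameter
α controls the variance-to-mean ratio: α > 0 over-dispersion, α < 0
under-dispersion, α = 0 the Poisson limit. The rate parameterisation
(λ₁, λ₂) is available through the one-to-one map λ₁ = μ/(1+αμ),
λ₂ = αμ/(1+αμ); the package fits only the mean parameterisation.

The hurdle construction separates the zero process from the positive
process. With zero probability w and a zero-truncated GP2 for the positive
part,

    Pr(Y = 0) = w,
    Pr(Y = j) = (1−w) · g(j) / (1 − g(0)),   j ≥ 1,

where g is the GP2 pmf. Covariates enter through a log link for the count
part, ln μ = xᵀβ, and a logit link for the zero part, logit w = zᵀδ; the two
covariate sets may coincide or differ. Parameters are packed as
θ = (α, βᵀ, δᵀ)ᵀ. The Poisson hurdle (PH) model is the α = 0 slice; the GP
regression (GP) drops the zero process. Model comparison uses
AIC = −2ℓ + 2p with p the number of free parameters: p+q+3 for the full
hurdle model, p+q+2 for PH, p+2 for GP.

### Moments and the α < 0 support

With hurdle factor c = (1−w)/(1−e^{−μ/(1+αμ)}), the first two raw moments
are E[Y] = cμ and E[Y²] = c(μ(1+αμ)² + μ²); the second follows from the GP2
variance plus μ². (An alternative linear-in-(1+αμ) form of the bracket
circulates in the literature; it is inconsistent with the GP2 variance and
is provided only as the `raw2_form="linear"` sensitivity switch.)

For α < 0 the pmf is defined as zero wherever 1 + αy ≤ 0, so the
distribution is supported on 0..⌈−1/α⌉−1 and its total mass falls slightly
short of one. The package follows that truncated definition literally —
no renormalisation — and reports the shortfall via `gp_mass_deficit`.
Summation and sampling enumerate the support until cumulative mass exceeds
1 − 10⁻¹² (hard ceiling 10⁶); samplers are inverse-CDF over that table,
which stays O(support) even when the zero atom is large (rejection sampling
would not).

## Estimation

**Maximum likelihood.** The log-likelihood splits into the zero part
Σ_{y=0} log w_i and the positive part Σ_{y>0} [log(1−w_i) + log g(y_i) −
log(1−g(0))]. All pmf evaluation is in log space with `lgamma` for y!, so
counts into the hundreds are safe. Starting values are moment-style: count
intercept at log of the positive-response mean, zero intercept at the
empirical logit of the zero fraction, slopes 0, α = 0.01.

**GMM.** Stacking X_i = (x_iᵀ, z_iᵀ)ᵀ, the moment conditions pair X_i with
the first- and second-raw-moment residuals,
h_i = [X_i(Y_i − g1_i); X_i(Y_i² − g2_i)], and the estimator minimises
Q_n = h_nᵀ W h_n in the sample average h_n. The default weight is the
identity; the two-step option rebuilds W as the pseudo-inverse of
Σ̂ = n⁻¹Σ h_i h_iᵀ at a first-stage identity-weight estimate and
re-minimises once. GMM is initialised at the ML estimate by default.
Internally the optimizer minimises n·Q_n — the same minimiser, but the
objective stays O(1) near the optimum so an absolute stopping tolerance is
meaningful.

When x = z (as in the ear-infection application) the two blocks of h
duplicate rows: only 2(p+1) distinct moments face 2(p+1)+1 parameters and
the system is under-identified. The default reproduces that setup faithfully
(a local minimiser from the ML start); setting `augment_zero_moment=True`
appends z_i(1{Y_i=0} − w_i), which restores identification. The sandwich
variance Γ̂ = (GᵀWG)⁺GᵀWΣ̂WG(GᵀWG)⁺ is exposed as a diagnostic, with G a
central finite-difference Jacobian (relative step 10⁻⁵) and pseudo-inverses
throughout (singular values below 10⁻¹⁰ of the maximum dropped); the
reported Jacobian rank makes under-identification visible rather than
fatal. Note that this moment system is always over-identified when fully
identified at all — dim h = 2(p+q+2) exceeds dim θ = p+q+3 for any p, q ≥ 0.

**Feasibility.** The simplex search is unconstrained, so infeasible regions
(any 1 + αμ_i ≤ 0, overflowing linear predictors, or a data point beyond
the α < 0 truncation) contribute a large finite penalty (10¹⁰) instead of
raising; fits started at feasible points back away from the boundary.

## The simplex optimizer

Both objectives are minimised with a self-contained Nelder–Mead
implementation using the standard coefficients: reflection η = 1, expansion
γ = 2, contraction ξ = ½, shrink κ = ½. The initial simplex places one
vertex per coordinate at a displacement of `init_step`·max(|x₀ᵢ|, 1)
(default 0.05). Ties in the vertex ordering are broken by insertion order
(stable sort), making runs bit-reproducible.

Stopping: the run converges when the root-mean-square spread of the
objective over all m+1 vertices falls below `eps` (default 10⁻⁸) **and**
the simplex diameter falls below `xtol`·(1+‖best‖) (default 10⁻⁶). The
f-spread alone cannot certify the argmin — near a smooth minimum the
vertices can equalise their objective values on a level set while sitting
~10⁻⁴ away from the optimum, which is exactly what happens on a convex
quadratic — hence the conjunction with a spatial tolerance. An exactly flat
simplex (constant objective) stops at the first iteration. Non-convergence
within `max_iter` (default 5000) is flagged, and ML fits then retry once
from a 10%-jittered start (fixed jitter stream, so still deterministic).

## Inference

Bootstrap variance resamples the data rows with replacement B times
(default B = 50, resample size n), re-runs the estimator, and reports the
componentwise empirical variance (1/(B−1))Σ(θ̂*ᵇ − θ̄*)². A replicate on
which the estimator fails is redrawn, up to 5B attempts, with the redraw
count reported. Wald intervals are est ± z_{1−level/2}·se with two-sided
normal p-values; a zero SE yields p = 0 for a nonzero estimate and p = 1
otherwise. ML standard errors default to the numerically-differenced
observed information ("Fisher"); GMM standard errors default to the
bootstrap. Bootstrap resamples of size ≠ n are supported but not used by
default.

## Synthetic data

The generator samples the hurdle model exactly: covariates drawn
independently from finite value sets, (w_i, μ_i) through the links, a
Bernoulli(w_i) zero indicator, and zero-truncated GP2 draws otherwise. The
`earlike` preset emulates the structure of the ear-infection survey the
model family targets: n = 190; swimming frequency coded Often = 1 /
Occas = 2 and swimming place coded Beach = 1 / NonBeach = 4, each
equiprobable; dispersion α = 0.28 with count slopes (0.63, 0.07) and zero
slopes (−0.71, −0.37); intercepts β₀ = −0.39584, δ₀ = 1.91920 solved
numerically so the population zero share is 0.484 and the marginal mean
1.6 (implied marginal variance ≈ 6.1). What the preset does **not** emulate:
the real survey's covariate dependence structure, its exact empirical
frequencies, or any unrecorded covariates — so passing tests demonstrate
correct model arithmetic and estimator behaviour under the model, not fit
to the actual survey.

## Test harness sizes and numerical choices

Monte-Carlo validation uses a recovery scenario with distinct count/zero
covariates (one binary covariate in each part, θ* = (0.2, 0.1, 0.5, 0.4,
−0.8)), chosen so the moment system is identified and the dispersion is
moderate. Problem sizes — 50 replicates at n = 2000 for bias, 12 replicates
each at n ∈ {500, 2000, 8000} for consistency, 200 replicates (n = 500,
B = 50) for bootstrap coverage — are the package's desk-scale defaults;
repeated bootstrap refits warm-start from the full-data estimate with a
slightly looser tolerance (eps 10⁻⁶, xtol 10⁻⁵, 800 iterations), which does
not change the fitted optima at the reported precision. Identity-weight GMM
on second-moment conditions has heavy-tailed replicate errors at moderate n,
so the consistency check for GMM uses the median absolute error where the
ML check uses RMSE; for the same reason the two-step-versus-identity
efficiency comparison and the sandwich-variance calibration use robust
(median-based) spread — a handful of divergent two-step replicates, caused
by re-weighting with the pseudo-inverse of a noisy fourth-moment matrix,
dominate raw variances without affecting the typical-case ordering.

## Known limitations

- With x = z the moment system is under-identified and the choice of GMM
  weight matrix materially changes the estimates, so GMM results for the
  ear-infection design are reproducible only qualitatively.
- No analytic gradients or Hessians; the observed-information SEs are
  finite-difference based.
- No offsets, formula language, or interaction expansion; design matrices
  are explicit columns.
- Continuously-updated GMM, over-identification (J) tests, and HAC
  weighting are out of scope.
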