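# Methods

## The measurement model

Wheezing illness severity is treated as a continuous latent variable
η that cannot be observed directly but drives four observable,
ordered-categorical consequences recorded by the ISAAC Wheezing Module:
episode frequency (4 levels), wheeze-related sleep disturbance (3),
speech-limiting wheeze (2), and exercise-induced wheeze (2).  Each item
y_i is modelled as a coarse measurement of a continuous latent response
y*_i:

    y*_i = λ_i η + ε_i,        y_i = k  ⟺  τ_{i,k} < y*_i ≤ τ_{i,k+1},

with c_i − 1 strictly increasing thresholds τ_i for an item with c_i
categories.  We use the delta parameterization throughout: Var(y*_i | x)
= 1, so λ_i is a standardized loading and the model-implied correlation
between two latent responses is λ_i λ_j.  Identification fixes the factor
variance ψ = 1 and latent mean α = 0 in single-group models, with all
loadings free; the four-indicator model therefore has
6 correlations − 4 loadings = 2 degrees of freedom.

Structural extensions regress η on covariates (η = γ'x + ζ, Var ζ = 1)
and regress distal outcomes — modelled as one more ordinal variable — on
η (coefficient β, reported on the outcome's y* scale) and directly on the
covariates.  Under the unit conditional-variance convention the outcome's
residual variance given (η, x) is 1 − β²ψ.

### Assumptions

* unidimensionality: one severity factor explains all inter-item
  association;
* conditional bivariate normality of the latent responses given
  covariates (the polychoric model);
* missing responses are missing at random given the model covariates,
  operationalized by available-case univariate probits and
  pairwise-complete polychoric correlations, both conditional on x;
* children are independent except where school clustering is modelled
  explicitly.

## Estimation: two-stage diagonally weighted least squares

Stage 1 estimates, per item, the thresholds and probit slopes (ordered
probit with unit residual variance; closed-form inverse-normal transforms
of cumulative proportions when there are no covariates), then each
pairwise polychoric correlation by maximizing the bivariate-normal
likelihood of the cross-table with the univariate parameters held fixed.
The stacked statistic vector s (thresholds, slopes, correlations) gets an
asymptotic covariance Γ assembled from estimating-equation influence
functions in sandwich form; the two-stage dependence of each correlation
on its items' thresholds is propagated through the stacked-equation
Jacobian (triangular structure, information-identity estimates of the
cross blocks).  Summing influence functions within school before the
outer product yields the cluster-robust Γ.

Stage 2 minimizes the diagonally weighted quadratic form

    F(θ) = (s − σ(θ))' diag(Γ)⁻¹ (s − σ(θ)),

by trust-region least squares (deterministic start: loadings 0.7,
structural coefficients 0, thresholds at stage-1 values; gradient
tolerance 10⁻¹² on the weighted problem).  Standard errors use the full
sandwich (J'W⁻¹J)⁻¹ J'W⁻¹ Γ W⁻¹ J (J'W⁻¹J)⁻¹.

### Fit statistics

The reported goodness-of-fit statistic is the scaled-and-shifted form of
T = (s−σ̂)'W⁻¹(s−σ̂): with U the residual projection matrix and M = UΓ,

    T_ss = √(df / tr M²) · (T − tr M) + df,

whose first two moments match the χ²_df reference.  The companion
mean-variance-adjusted variant (estimated df* = (tr M)²/tr M²) is always
computed and reported alongside.  RMSEA is √(max(0, (χ²−df)/(df·n)))
with a 90% interval from inverting the noncentral χ²; n is the number of
children with at least one observed indicator, and the divisor is df·n —
this reproduces two-decimal printed values like .02/.04/.00 for
(2.35, 2, 657), (3.76, 2, 657) and (0.83, 2, 102).  CFI compares against
the independence baseline (thresholds and probit slopes free, all
correlations fixed at zero).

Where χ² < df the RMSEA is 0 by construction; multilevel fits report it
the same way (a published nonzero multilevel value under χ² < df follows
an undocumented convention we do not emulate).

### Multilevel approximation

For cohorts with children nested in schools within sites, severity is a
child-level construct only: the within-school model is the factor model
above, the between level is treated as saturated.  We approximate
two-level weighted least squares by (i) estimating stage-1 statistics
conditional on study-site dummies with free (saturated) slopes, and (ii)
replacing Γ with its school-cluster-robust version.  Degrees of freedom
match full two-level accounting (df 2 without, 5 with a child-sex
predictor).  The approximation leaves school-level covariance inside the
pairwise correlations, so with a school intercept share ICC the fitted
loadings absorb up to ≈ICC of common covariance (exact equivalence holds
at ICC = 0); full two-level estimation is out of scope.

## Measurement invariance

Two-group ladders (e.g. female vs male children) fit four nested models:
configural, equal loadings, equal thresholds, equal residual variances.
Identification releases under the delta parameterization are chosen as
the unique pattern consistent with the df sequence 46 → 49 → 51 → 55 when
each group's factor is regressed on seven covariates:

* configural: ψ_g = 1, α_g = 0, scale factors 1 in both groups;
* equal loadings (−4 parameters): free the group-2 factor variance ψ₂
  (net Δdf = 3);
* equal thresholds (−7): free the four group-2 scale factors and the
  group-2 latent mean (net Δdf = 2);
* equal residual variances: the scale factors become functions of (λ, ψ₂)
  and are no longer free (Δdf = 4).

Nested fits are compared with a scaled difference test built from the
raw fit-function difference and the trace of (U_restricted − U_free)Γ.
The default matches the first two moments of the reference distribution
(scale and shift); the mean-only first-order variant is also reported but
over-rejects at the thresholds step in our calibration runs (~0.14 at
α = .05 versus 0.03–0.06 for the default), which decided the default.

Longitudinal (two-wave) ladders model all eight items jointly with
correlated wave factors and free within-child residual correlations
between the same item across waves; wave-2 releases mirror the two-group
convention.  This yields configural df 57 (with seven covariates) and a
thresholds-step Δdf of 2; published two-wave tables based on other
(undocumented) identification choices can differ, so longitudinal df
values are reported but not treated as reproduction targets.

## Graded-response route, scores, information

The probit graded response model with a_i = λ_i/√(1−λ_i²) and
b_ik = τ_ik/λ_i is an exact reparameterization of the measurement model.
Fitting it by marginal maximum likelihood (EM over 61-point Gauss–Hermite
quadrature, convergence at Δloglik < 10⁻⁸, discriminations capped at 10)
provides an independent estimation route used for cross-validation:
loadings from the two routes agree within 0.02 at n = 50,000 in the
standing experiments.  EAP severity scores (posterior mean/SD under a
standard-normal prior) and Fisher information curves are computed from
the same parameterization; with thresholds targeting the observed
marginals, total information peaks above +0.5 SD — the items measure
moderate-to-severe wheezing best and discriminate poorly among mildly
affected children.

## Synthetic cohorts

The generator draws η = γ'x + ζ, latent responses λ_i η + ε_i with unit
conditional variance, and cuts them at thresholds that invert Φ at target
cumulative proportions.  Defaults emulate an infant cohort of
ever-wheezers: item marginals (episodes .32/.52/.12/.04; sleep
.72/.13/.15; speech .18 endorsed; exercise .10 endorsed among observed),
covariate prevalences from the same cohort's descriptive table, a
female–male factor difference of −0.20 SD, loadings (0.8, 0.7, 0.6, 0.5)
spanning strong-to-moderate (no published loadings exist; these are
synthetic defaults), and distal-outcome effects β = 0.7 on the y* scale
(published estimates span 0.54–0.90).  Two-wave configs share a factor
correlation (default 0.6) and same-item residual correlation (0.2);
noninvariance is injected by shifting wave-2 loadings, thresholds, or
residual variances.  Missingness is additive-in-probability in the
covariates, independent of the latent responses by construction (MAR).
Clustering adds school intercepts with variance equal to the target ICC
share and site-level mean shifts.

What the generator does not emulate: recruitment and attrition dynamics,
exposure substructure, multidimensional symptom profiles, informative
missingness, and item-specific method effects.  Passing tests therefore
certify the estimator chain under the model's own assumptions, not
robustness to their violation in real cohorts.

## Standing validation experiments and problem sizes

The experiments module fixes the replication sizes the package runs by
default (chosen to give Monte-Carlo error well inside each decision
band):

* loading recovery: 300 cohorts of n = 2,000; reports Monte-Carlo bias
  |E[λ̂]−λ| (≈0.002) and pooled 95% CI coverage (target band 0.93–0.97).
  The per-draw absolute error is also reported; it is dominated by
  sampling noise (≈0.8 × SE ≈ 0.025 at this n) and is not a bias measure.
* goodness-of-fit calibration: 500 cohorts of n = 1,000, α = .05 band
  0.03–0.07; difference-test calibration: 300–400 two-group replications.
* power: a one-factor fit to two-factor truth (n = 2,000) rejects in
  ≈100% of replications.
* oracle checks: polychoric vs 2-D Gauss–Legendre rectangle integration
  maximized on a correlation grid (50 tables, agreement ≤ 10⁻⁴); EAP vs
  dense-grid trapezoid posteriors (≤ 10⁻⁴); information vs central finite
  differences (≤ 10⁻⁵).
* latent-vs-discrete contrast: 200 cohorts of n = 1,000 with continuous
  latent truth; the latent exposure's −3→+3 SD risk difference exceeds
  the endorsement count's 0→4 contrast in ≥80% (empirically ≈100%) of
  replications.

## Numerical choices

* Bivariate normal CDF: correlation-integral identity with 64-node
  Gauss–Legendre quadrature (vectorized; cross-checked against an
  independent implementation at 10⁻¹⁰), correlations capped at |ρ| =
  0.999.
* Ordered probit: L-BFGS with analytic gradients on an unconstrained
  reparameterization (first threshold + log-spacings); polychoric ρ by
  bounded scalar minimization (tolerance 10⁻¹⁰).
* Empty categories are collapsed into a neighbour before estimation;
  boundary collapse leaves estimable quantities unchanged.
* Polychoric estimates are made exactly symmetric in their arguments by
  canonical argument ordering.
* Heywood cases are bounded at |λ| = 0.999 with a warning; negative
  corrected difference statistics are flagged and reported as 0 with
  p = 1.
* Everything downstream of the data is deterministic: identical
  summaries and specs give bit-identical fits.

## Known limitations

* No full-information ML or Bayesian estimation; theta parameterization
  not implemented.
* The multilevel approximation biases within-loadings upward by up to
  ≈ICC (see above).
* Two-item factor models are not identified (loadings enter only through
  the single correlation); at least three indicators are required.
* Delta-method intervals for predicted probabilities degenerate when
  probabilities saturate near 0/1.
* SEM-style latent severity is for explanatory modelling; EAP scores are
  provided for research convenience, not clinical prediction.
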