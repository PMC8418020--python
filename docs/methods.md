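# Methods

## The model

`dynlpm` implements a multivariate latent process model for the joint
trajectories of two unobserved dimensions — cognitive ability and functional
dependency — measured repeatedly by bounded psychometric scores in a
three-stage clinical cohort (cognitively normal CN, mild cognitive
impairment MCI, Alzheimer-type dementia AD).

### Measurement part

Each marker `y_m` (MMSE 0–30, IST 0–82, BVRT 0–15, TMT-B positive
continuous, and the 0–18 BADL+IADL limitation sum) is mapped to the latent
scale by a marker-specific monotone link

    H_m(y) = eta0_m + sum_l (eta_raw_{m,l})^2 I_l(y),

where `I_l` are quadratic I-splines with boundary knots at the marker's
theoretical range and interior knots at the empirical quartiles (median for
the limitation sum).  Squared raw coefficients guarantee monotonicity on an
unconstrained parameter space.  The transformed observation is

    H_m(y_{imj}) = Lambda_{d(m),i}(t_j) + eps_{imj},
    eps ~ N(0, sigma_m^2),

and the likelihood carries the change-of-variable Jacobian `H_m'(y)`.
M-splines are density-normalized (each integrates to 1), so every I-spline
rises from 0 to 1; any other normalization would simply rescale the
weights.

### Structural part

Time runs on a discretized grid `t_j = j * delta`, with `delta = 0.25`
years (3 months), deliberately unrelated to the visit schedule; visits are
assigned to the nearest grid node (exact half-way ties round down, an
arbitrary but fixed convention that never triggers on 6-monthly visits).
For subject `i` with covariate vectors `x_init` (stage, age category, APOE
e4, sex, education, education × stage) and `x_change` (same without the
interaction, matching the published change-association layout; both designs
configurable):

    Lambda_i(0)        = beta' x_init + u_i
    Lambda_i(t_{j+1})  = Lambda_i(t_j)
                         + delta * [ gamma' x_change + v_i
                                     + A_stage(t_j) Lambda_i(t_j) ]

`A_stage(t)` is the temporal-influence matrix: entry `[d, k]` is the effect
of the current level of dimension `k` on the subsequent *annual* change of
dimension `d`.  Self-effects (`k = d`) are constant in time; cross-effects
are linear in time (`alpha_0 + alpha_1 t`), both stage-specific.  Because
the recursion is affine in the Gaussian random effects `(u, v)`, the latent
vector at every node is exactly `E_j + P_j u + Q_j v` with deterministic
`E_j, P_j, Q_j` following the same recursion — the model is linear-Gaussian
and the marginal likelihood is available in closed form.  This recursion is
the minimal process consistent with a discretized change equation and no
process noise; adding innovation noise would require longitudinal
replication below the 3-month scale that cohort data do not provide.

### Identifiability

Latent scales are fixed by standardizing at baseline in the reference
category (CN, male, higher education, youngest age class, APOE e4
non-carrier): the reference intercept of each initial level is structurally
zero and `Var(u_d) = 1` exactly.  All coefficients are therefore in units
of the baseline SD of their dimension.  The random-effect covariance of
`(u_1, u_2, v_1, v_2)` is parameterized by a Cholesky factor whose `u` rows
are unit vectors (hyperspherical angles), making the `u` block exactly a
correlation matrix; a `diagonal` option (independent effects) is provided
for small-sample stability.  Measurement-error SDs are log-parameterized.

### Missing data

Markers are intermittently missing by design (TMT-B at two planned visits
only, BVRT sparse for CN) and monotonically through dropout.  Subjects
contribute the marginal Gaussian density of whatever was observed — valid
under missing-at-random, which covers stage- and covariate-dependent
dropout.

## Estimation and inference

The unconstrained parameter vector (for the default five-marker battery:
102 entries) is estimated by maximizing the marginal log-likelihood with
L-BFGS-B, forward-difference gradients (relative step 1e-7), and optional
multi-start from jittered initial values.  Convergence requires the
optimizer's relative function-change criterion (1e-8) and a final
central-difference gradient check; failure is reported, never silent.  The
asymptotic covariance is the inverse observed Hessian computed by central
differences (relative step 1e-4); a non-positive-definite Hessian is
flagged and confidence intervals are suppressed.  Initialization is
deterministic: link coefficients from non-negative least squares matching
each marker's empirical quantiles to a Gaussian scale, fixed effects from
crude per-dimension regressions of transformed baseline values and
within-subject slopes, influences at zero.

Derived quantities:

- **Wald tests** of linear contrasts `c'theta` with `SE = sqrt(c'Vc)`,
  two-sided normal p-values, 1.96-based 95% CIs.
- **Influence at time t**: the effect on the annual change is linear in the
  coefficients (`alpha_0 + alpha_1 t`), so the delta method is exact; the
  magnitude is also reported as the "reduction" convention used when the
  signed effect is negative.
- **Covariate contrasts** on the latent scale, e.g. education within stage,
  as differences of cell linear predictors with Wald CIs.
- **Trajectory bands** by Monte Carlo: 2000 draws from
  `N(theta_hat, vcov)`, each propagated through the dynamics; pointwise
  2.5/97.5 percentiles.  Bands reflect estimation uncertainty only
  (confidence, not prediction, bands); random effects are not drawn.
- **Marker-scale predictions** `E[H^-1(Lambda + eps)]` by seeded Monte
  Carlo over the measurement error (and random effects for marginal
  predictions); the inverse link clamps to the marker's range.

## The synthetic cohort generator

No individual-level data from the motivating cohort are distributable, so
the generator produces cohorts with the structure the analysis assumes:
102 CN / 123 MCI / 72 AD; per-stage covariate mixes (female 67.7/58.5/65.3%,
lower education 22.6/34.2/37.5%, APOE e4 14.7/13.8/36.1%, age categories
uniform over the five quintile classes); visits at months 0, 6, 12, 18, 24,
36, 57; BVRT restricted to months 0/36/57 for CN and TMT-B to months 0/36
for everyone; monotone per-visit dropout hazards 0.13/0.13/0.20
(CN/MCI/AD), chosen so the median number of visits is 5 (4 for AD),
with AD highest as attrition accompanies disease severity.  True parameters
default to the published coefficient tables; quantities the tables do not
print use documented defaults: `corr(u_cog, u_fun) = -0.4`,
`sd(v) = (0.15, 0.40)`, `corr(v_cog, v_fun) = -0.3`, error SDs
0.30–0.55, and link shapes spanning roughly [-12, 4] latent units for
cognitive markers (weights rising toward the ceiling: MMSE ceiling effect)
and [-2.5, 12] for the limitation sum (TMT-B weights fall toward the
bound: floor effect).

`continuous` mode emits `H^-1(latent + error)` exactly; `discrete` mode
additionally rounds to each score's integer grid (one decimal for TMT-B)
and clamps, reproducing realistic ceiling/floor pile-ups.  Rounding and
bound-clamping introduce small biases relative to the Gaussian model, so
discrete mode is excluded from parameter-recovery assertions, and the
generative-vs-analytic moment checks use links wide enough that the latent
range never reaches the score bounds.  What passing tests show is therefore
internal validity — the estimator recovers the generating process the model
assumes — not robustness to the misspecifications real psychometric data
add (ordinal scales, diagnosis conversion, informative dropout).

## Numerical choices and test-scale settings

- Grid horizon 4.75 years (57 months); 19 steps of 3 months.
- Age enters as an abstract five-level category (`q1`–`q5`); published
  analyses used quintile cut points whose printed values differ slightly
  between tables, so the package deliberately does not hard-code them.
- TMT-B (correct moves per minute) needs a finite upper boundary knot; 90
  comfortably exceeds observed ranges.
- Duplicate interior knots (possible for very discrete scores) are
  collapsed with a warning.
- Inverse links use 80 vectorized bisection iterations (error below 1e-16
  of the range, comfortably inside the 1e-8 round-trip contract).
- The replicate simulation study behind the recovery and coverage tests
  uses the package's own scaled design: the 297-subject three-stage cohort
  in continuous mode with one near-Gaussian marker per dimension (degree-1
  links), a stage-only covariate design, diagonal random-effect covariance,
  40 replicates, optimizer started from a jittered neighbourhood of the
  truth, and link coefficients held at their generating values (pilots show
  this changes influence estimates by <0.03 while halving fit time).  These
  choices keep the full suite's simulation budget modest while exercising
  the complete estimation path for the 32 remaining parameters.
- The end-to-end pipeline determinism check runs a 44-subject inline
  cohort; all pipeline randomness flows from a single seed.

## Known limitations

- No process (innovation) noise in the latent dynamics; heterogeneity
  enters only through `(u, v)`.
- Wald inference is first-order asymptotic; with ~300 subjects, CIs for
  variance-adjacent parameters can be mildly anticonservative.
- The bounded-score model treats scores as continuous through a link;
  ordinal threshold models are out of scope.
- Dropout is assumed MAR; informative missingness is not modelled.
- Fitting the full five-marker battery (102 parameters) with numerical
  gradients is minutes-scale on one CPU; the reduced designs exist
  precisely to keep simulation studies affordable.
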