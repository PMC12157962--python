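# Methods

## The setting

`npidce` implements the full analytical machinery of a stated-preference
(discrete choice experiment, DCE) study of public preferences for
nonpharmaceutical interventions (NPIs) against respiratory epidemics:
designing the blocked survey, simulating respondent panels, estimating
mixed-logit and latent-class mixed-logit models, and converting coefficients
into willingness to pay (WTP). The canonical attribute space covers seven
NPIs familiar from pandemic-era Singapore: mask mandates (none / indoors /
in public), dining-in group limits (any / 5 / 2 / none), vocalization
activities, large-scale events, post-travel quarantine (none / home /
government facility), vaccine-booster mandates, and a one-time fee of
0/10/30/50 SGD that identifies the money metric.

## Random-utility model

Respondent *i* facing alternative *j* derives utility

    U_ij = beta_i' x_j + eps_ij,          eps_ij ~ i.i.d. type-1 extreme value,

where `x_j` stacks dummy codes for every non-reference attribute level (the
reference is always the least stringent level, "no restriction"), the fee in
SGD, and an alternative-specific constant (ASC) marking the first-listed
option, which detects left–right reading bias. Individual tastes follow

    beta_i = beta + eta_i,                eta_i ~ Normal(0, diag(sigma^2)),

on a configurable subset of predictors (the *random set*). The default
random set — both mask levels, the dining ban, government-facility
quarantine, and the booster mandate — reflects where individual-level
heterogeneity is typically found for these attributes. `eta_i` is diagonal
by default: only heterogeneity SDs are identifiable in practice from panels
of this length, and the simulator exposes a correlation matrix switch for
users who want the full multivariate-normal variant. The fee coefficient is
non-random by default so that WTP ratios have a well-defined distribution.

The latent-class extension (mixed-mixed multinomial logit) assumes *K*
segments with their own mean vectors `beta_c` and SD vectors `sigma_c`;
within a class everyone shares the means but keeps an individual `eta_i`.
Membership is multinomial logit on respondent covariates `z_i` (sex,
ethnicity, marital and parental status, education, housing, employment,
vaccination, age, health-risk attitude), with the first class as reference:
`P(class c | z_i) ∝ exp(gamma_c' z_i)`, `gamma_1 = 0`. Age enters per decade
centred at 48 years and the 13-item health-risk-attitude (HRAS-13) sum score
per 10 points centred at 42, purely for conditioning; odds ratios are
therefore per decade / per 10 points. The class count is selected by
BIC = −2·LL + p·ln(N), with N the number of *respondents* — the panel's
independent sampling units — not the number of choice observations.

## Design construction

Designs are unlabeled, one-stage and blocked: B blocks × a tasks × t
full-profile alternatives (canonically 20 × 7 × 2). The generator is a
seeded swap-based optimizer over profile assignments minimizing

    w_bal · (level-balance deviation)
  + w_D   · D-error of the dummy-coded design at zero coefficients
  + w_ov  · mean per-task squared distance of the full-overlap fraction
            from a target (default 1/3).

The balance term is the mean absolute deviation of level counts from
perfect balance; the D-error is `det(information)^(-1/P)` with the ASC
included; the overlap term implements the *balanced overlap* idea —
penalizing both zero overlap (hard for respondents) and full overlap
(uninformative), rather than driving overlap to zero as pure D-efficiency
would. Defaults (w = 2, 1, 1; 6000 single-level swap proposals, strict
improvement) produce canonical designs whose level balance beats the best
of 1000 uniformly random designs while keeping the D-error finite and the
overlap near target. Exact duplicate alternatives within a task are
prohibited throughout. Respondents are assigned to blocks uniformly at
random, seeded.

Two sample-size rules are provided: the Johnson–Orme rule
`n > 500·c/(t·a)` (ceiling-rounded; `c` = largest level count) and the
20-respondents-per-block rule; the recommendation is the maximum. For the
canonical design these give 143 and 400.

## Synthetic populations

`simulate_profiles` draws covariates independently from the published
sample marginals of the motivating survey (58.2% female, 84.7% Chinese,
51.6% university-educated, 92.8% with 3+ vaccine shots, …), age from a
normal(48, 14) truncated at the 18-year eligibility floor, and HRAS-13 from
normal(42, 8). Truncation raises the realized age mean slightly (~48.6) —
the price of honouring the eligibility bound with the published moments.
Because no cross-tabulations are published, covariates are independent;
synthetic panels therefore reproduce marginal structure, not real-world
covariance between demographics, and recovery results should be read as
statements about the estimators under the stated generating process, not
about any particular population.

Choices are simulated exactly per the model: one taste draw per respondent,
fresh Gumbel noise per respondent × task × alternative (the panel structure
enters only through `beta_i`), argmax utility chosen. All randomness flows
from one seed through spawned substreams.

## Estimation

**Simulated likelihood.** The mixed-logit panel probability integrates the
product of within-task logit probabilities over `eta_i`. The integral is
simulated with scrambled Halton draws mapped through the normal quantile,
antithetic by default (an odd draw count is rounded up to even). One draw
block per respondent is generated once and held fixed across optimization,
making the simulated log-likelihood a smooth deterministic function of the
parameters. Heterogeneity scales enter through |sigma|, so the likelihood
is exactly sign-invariant and estimates are reported as absolute values.
Defaults: R = 500 draws (validation studies below use 200–300).

**Optimization.** Predictors are internally rescaled to unit range (the fee
column's 0–50 SGD scale otherwise ruins the conditioning of quasi-Newton
steps); estimates and covariances are mapped back, so the scaling is
invisible to callers. L-BFGS with the analytic gradient of the simulated
likelihood runs from a conditional-logit warm start (sigma started at 0.5).
Convergence: projected gradient below 1e-5 (mixed logit) or 1e-4
(mixtures, whose near-degenerate-class directions are very flat), relative
function tolerance 1e-10 (relaxable for model scans via `ftol`). The
mixture is maximized directly — one code path shared with the mixed logit —
from several seeded starts: a quantile-split start (respondents ranked by
the stringency of their chosen alternatives, a conditional logit fitted per
stratum) plus random perturbations of the pooled conditional-logit
solution; the best final likelihood wins. Non-convergence and degenerate
classes (share < 1e-3) are flagged, never silently reported.

**Label switching** is resolved post hoc by sorting classes on the
public-mask-mandate mean, descending, so class 1 is always the most pro-NPI
segment; membership coefficients are re-referenced accordingly.

**Inference.** Standard errors come from the inverse numerical Hessian
(central differences of the analytic gradient) at the optimum; a singular
Hessian yields a flagged result without standard errors. Wald 95% CIs and
p-values are reported per coefficient; a significant heterogeneity SD is
the operational test for individual-level preference heterogeneity.
Posterior class probabilities use Bayes' rule at the estimates; reported
class shares are posterior means (prior shares are also reported and agree
closely in well-fitted models).

## Willingness to pay

WTP for attribute level k is `beta_k / |beta_fee|` with `beta_fee < 0`
required (otherwise the ratio has no money-metric meaning and the request
errors). Positive WTP is pay-to-implement; negative is pay-to-avoid. CIs
are delta-method by default or Krinsky–Robb (10,000 seeded draws from the
estimated joint normal of the coefficients, percentile interval; draws with
a non-negative fee coefficient are discarded and the method errors if they
exceed half the draws). For latent-class fits WTP uses each class's own fee
coefficient. Tables carry full precision plus a whole-SGD rounded column.

## Validation studies and their problem sizes

The acceptance suite validates the chain bottom-up: exact identities
(sample-size arithmetic, sigma = 0 collapse to conditional logit, K = 1
collapse to mixed logit), independent oracles (brute-force likelihood
products; Gauss–Hermite quadrature at 2000 draws, agreement to 1e-3), and
parameter recovery at survey scale. The recovery studies — the package's
own choice of scale — use 20 replicate panels of 1500 respondents × 7
binary tasks at R = 300 for the mixed logit (requiring mean absolute error
of the means < 0.1 and ≥16/20 CI coverage per coefficient), and 10
replicate panels of 800 respondents at R = 200 for the two-class mixture
(requiring class-share recovery within 0.05, the correct sex direction in
membership, and BIC selecting K = 2 over {1, 3} in ≥7/10 panels).

## Known limitations

- The survey microdata behind the motivating study are not deposited; the
  package reproduces the *pipeline*, and its claims are about estimator
  behaviour under the stated generating process.
- Mixing distributions are normal only; WTP-space estimation, lognormal or
  triangular mixing, nested/probit kernels, and scale heterogeneity
  (G-MNL) are out of scope.
- The balanced-overlap optimizer is a transparent composite-criterion
  hill-climber, not a re-implementation of any proprietary design engine;
  it matches the stated intent (balance + moderate overlap), not any
  particular commercial output.
- Simulated covariates are independent; membership-model odds ratios from
  synthetic data inherit that independence.
- With few respondents or draws the numerical Hessian can be singular
  (flagged); Krinsky–Robb CIs are then unavailable as well.
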