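# Methods

This note documents the statistical model implemented by `distarget`, the
numerical choices behind the implementation, the design of the synthetic
data generator, and the limits of what the package's tests demonstrate.

## Model

A person *i* carries latent disability **η**ᵢ with Q = 1 or 2 factors.
Three blocks are estimated jointly:

- **Structural (disability) equation**: η_iq = θ_q'Z_i + ν_iq with
  ν ~ N(0, Σ_ν). Z contains piecewise-linear splines of age (default knot
  73 years) and of log equivalized monthly income (default knot
  log 615.70, 2002 prices), a post-compulsory-education dummy, an
  outright-home-ownership dummy. Gender is deliberately excluded: gender
  differences in reporting cannot be separated from gender differences in
  true disability, so gender instead enters through optionally
  gender-specific measurement parameters.
- **Measurement model**: each ordinal indicator j with M_j categories is an
  ordered probit in the index λ_j'η, with strictly increasing thresholds
  A_j1 < … < A_j,M_j−1, indicator intercepts fixed at 0 and residual
  variance fixed at 1. Binary items are M_j = 2 with code 2 = "has
  difficulty". Cross-loadings are allowed (used for a continence item in
  the two-factor variant, since incontinence can stem from physical or
  cognitive impairment).
- **Receipt equation**: probit of the benefit indicator on Z (including a
  constant, the female dummy and a partnership dummy) and η with
  coefficient vector γ.

Conditional on (η, Z) the indicators and receipt are independent — the
classical measurement-error assumption. The likelihood of a person's
observed (D, R) therefore integrates the product of ordered-probit cell
probabilities and the receipt probit over the Gaussian prior of η given Z.
Missing indicator responses are simply omitted from the product, which is
valid under missingness at random given Z; receipt may not be missing
because it is the outcome. Rows missing all indicators or missing receipt
are dropped at load time with a logged count.

### Identification and normalization

Location: indicator intercepts are fixed at 0 with all thresholds free
(they are not jointly identified; the free-threshold convention matches
ordered-probit practice), the structural equation has no intercept, and the
receipt equation has a free intercept. Scale: either one anchor loading per
factor is fixed at 1 (`anchor_loading`; the anchor is a mobility-style item
in every template) or Σ_ν has unit diagonal (`unit_variance`). The two are
linked by the exact reparameterization λ→λσ_ν, θ→θ/σ_ν, γ→γσ_ν, and fits
under both must agree in likelihood; the test suite checks this to 1e-6.
A factor is identified only if the zero/nonzero loading pattern has full
column rank ("completeness"); `check_completeness` enforces this before
any fit.

## Numerics

### Quadrature

The latent integral uses tensor-product Gauss–Hermite quadrature with the
rule centred and scaled by the *prior* (structural mean θ'Z and covariance
Σ_ν), 21 nodes per dimension by default and configurable everywhere.
Because ten or more informative indicators make the posterior of η much
narrower than its prior, the prior-adapted rule converges slowly: on a
typical one-factor survey the per-person log-likelihood error is roughly
1e-2 at 10 nodes, 1e-4 at 40 and below 1e-8 at 160. The suite contains an
explicit node-doubling convergence test and a Monte-Carlo oracle comparison
(61 nodes against 5×10⁵ prior draws). Consequences worth knowing:

- 21 nodes is accurate enough for estimation and inference at the sample
  sizes used here (interval coverage is correct, see below);
- visibly coarser rules can be harmful: at 11 nodes the cross-survey Wald
  test over-rejects because quadrature error interacts with sample
  composition. Repeated-fit simulations therefore use the 21-node default,
  except the two-factor recovery exercise (11 nodes per dimension = 121
  nodes), where the test's ±0.1 tolerance on the factor correlation
  absorbs the coarser rule.

Per-person posterior-mean factor scores reuse the same rule without the
receipt term.

### Optimization

The likelihood is maximized by L-BFGS-B in an unconstrained internal
parameterization: thresholds as (first threshold, log-increments), which
guarantees monotonicity; variances and Cholesky diagonals as logs; the
two-factor `unit_variance` correlation through atanh. Gradients are
analytic scores of the quadrature approximation (differentiating through
the fixed nodes), validated against finite differences to ~1e-8 relative
error in the tests.

Internally the optimizer sees centred and scaled covariates — an exact
reparameterization (free thresholds and the receipt intercept absorb the
centring) that conditions the problem well when age in years sits next to
0/1 dummies; estimates are mapped back to the original scale in closed
form. This standardization is skipped when individual coefficients are
pinned to fixed values, because pinned values refer to the original scale.

Convergence is declared when the max-norm gradient of the mean (per-person)
log-likelihood falls below `gtol` (default 1e-5; the normalization
equivalence exercise uses 1e-8). Starting values: thresholds from
inverse-normal empirical cumulative category frequencies clipped to
[0.001, 0.999] (per gender group where applicable), non-anchor loadings 1,
structural coefficients 0, σ_ν² = 1, the receipt intercept at the probit of
the sample receipt rate and the remaining receipt coefficients 0.

### Cluster-robust covariance

Standard errors come from the sandwich H⁻¹MH⁻¹, where H is the negative
Hessian of the total (weighted) log-likelihood — obtained by forward
finite differences of the analytic score, step 1e-5·(1+|x|) — and M sums
outer products of household score totals with a G/(G−1) finite-sample
factor over G households. With singleton households this reduces to the
heteroskedasticity-robust sandwich (tested). Weighted (pseudo-likelihood)
fits put the weights in both the Hessian and the meat. A singular Hessian
triggers a loud warning and a regularized pseudo-inverse.

The covariance is reported for the canonical free-parameter vector
(measurement by indicator then gender group, structural, factor covariance,
receipt), so covariance blocks are comparable across runs and surveys —
this ordering is what the Wald equality test consumes.

## Inference machinery

- **Wald equality tests**: for independent surveys a and b, W =
  d'(V_a+V_b)⁻¹d with d the difference of the named coefficient subset,
  χ²(k) under equality; per-coefficient z statistics use the diagonal.
  Per-coefficient p-values are reported raw, with an optional Bonferroni
  column as a multiple-comparison guard.
- **Factor scores** condition on the indicators and covariates but *not*
  on receipt, so receipt-by-score targeting curves are not mechanically
  circular. Persons with no observed indicators receive the prior mean.
- **Targeting curves**: local linear regression of receipt on the score
  with a Gaussian kernel (bandwidth 0.4 by default), evaluated on 101 grid
  points spanning the 1st–99th score percentiles, values clipped to [0,1];
  plus decile-mean receipt tables (deciles split the sorted scores into
  tenths, ±1 person). Fewer than 20 observations are refused.
- **Benchmark profiles**: Φ(β'z + γη) along a grid of η given in
  SD units; by default the grid is scaled by the residual SD √σ_ν², and
  callers comparing population profiles should pass the total SD of the
  fitted scores (the choice is exposed because the two conventions differ).

## Matching

Cross-survey matching is greedy one-to-one nearest-neighbour without
replacement: base rows in input order (optionally shuffled by a seed), each
taking the closest unused donor within the caliper, ties broken by lowest
donor index — deterministic given the inputs. The metric is the Mahalanobis
distance in the pooled (base + donor) covariance of the matching variables;
binary variables enter directly, and with tight calipers this is equivalent
in practice to exact matching on them. A constant or collinear matching
variable raises an error naming the offending columns.

Trimming of extreme within-pair income differences uses ceiling semantics:
with n pairs and top-p% trimming, the ⌈n·p/100⌉ largest absolute
differences are targeted, and a pair is dropped only when strictly above
the largest retained difference, so fully tied differences are never
trimmed. Balance diagnostics report pre/post means, standardized
differences (mean gap over pooled pre-match SD) and Welch t-tests on the
matched samples.

Calipers (the 0.04–0.5 range is typical) and trim percentages are
configuration inputs, not constants.

## Synthetic data

The generator emulates the *structure* of three real survey families
without reproducing any real microdata: households of one or two members
aged 65–95; age-dependent education/ownership propensities; log income
normal (mean = the income knot, SD 0.45) shared within a household;
indicators and receipt drawn exactly from the model equations. Templates:
`frs_like` (8 binary items + optional proxy-response flag, prevalence
~6.5%, loading 0.6 — proxy respondents are substantially more disabled),
`elsa_like` (12 binary ADL/IADL items, with map/telephone/money items
forming the cognitive factor in the two-factor variant), `bhps_like` (6
binary + 4 six-category ordinal items; no cognitive factor is
identifiable, mirroring the narrower instrument).

Default true parameters are round numbers with the empirically typical sign
pattern — positive, steepening age gradient; negative education, income and
ownership gradients; γ = 0.55; σ_ν² = 3 (Q=1) or variances (3, 2.5) with
residual correlation 0.6 (Q=2). Thresholds and the receipt intercept are
calibrated once against a fixed canonical covariate draw (seed 202, 20 000
households) so that item prevalences land in a realistic 10–35% band and
the receipt rate near 9%; because this calibration never varies with the
user's configuration, surveys generated from different templates share one
structural/receipt truth, which is what the cross-survey compatibility
exercises require. An optional shared household intercept in ν
(`household_effect_sd`, default 0) induces the intra-household correlation
that motivates clustered standard errors; it is switched on only in
robustness tests.

What the generator does **not** emulate: real indicator wordings and their
idiosyncratic response behaviour, reporting heterogeneity beyond the
gender-specific measurement option, survey weighting pipelines
(design/non-response/calibration weights — weights are consumed as given),
geographic primary-sampling-unit clustering, and panel attrition. Passing
tests therefore demonstrate internal statistical correctness of the
machinery under the model's own assumptions, not robustness to the many
ways real surveys violate them.

## Problem sizes in the test suite

The repeated-fit exercises are sized to document the package's statistical
behaviour at desk scale: parameter recovery and 95%-interval coverage over
25 replicates of n = 4000; two-factor recovery at n = 5000; Wald-test size
over 50 replicate pairs of n = 1000 (band 1–12% around the nominal 5%);
matching balance with a +0.3 SD income-shifted donor pool. The
`scripts/acceptance.py` entry point re-runs the main chain at n ≈
1200–2500 per survey and writes every computed quantity to JSON.

## Known limitations

- Quadrature is prior-adapted, not posterior-adapted; per-person adaptive
  centring would converge much faster per node and is the natural next
  step.
- The likelihood-scaling (Satorra–Bentler-style) correction for test
  statistics under misspecification is not implemented; "robust ML" here
  means ML point estimates plus cluster-sandwich covariance, and model
  comparison uses AIC and Wald tests.
- No Bayesian or limited-information (WLSMV-style) estimation.
- Pinned-parameter fits (`FitOptions.fixed`) support coefficients and
  loadings only, not thresholds or covariance parameters.
- The Hessian is finite-differenced from the analytic score; extremely
  flat directions (e.g. a factor variance under near-zero loadings) rely
  on the regularized fallback.
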