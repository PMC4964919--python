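# distarget

Latent-variable analysis of disability-benefit targeting across household
surveys.

## The problem

Cash benefits for older people with care needs (such as the UK attendance
allowance) are meant to reach those with substantial disability, but surveys
measure disability only through menus of imperfect ordinal indicators —
menus that differ from survey to survey. Single-indicator or count-index
analyses are both arbitrary and attenuated by measurement error, and
analyses based on different surveys may disagree simply because the surveys
sample different people. `distarget` implements, as a reusable and tested
package, the structural-equation approach to this problem: latent
disability measured by many indicators at once, benefit receipt driven by
latent disability, and explicit machinery for asking whether different
surveys tell the same story.

It is aimed at researchers in health economics, epidemiology and social
statistics who work with person-level survey extracts.

## The model

For person *i* with socio-economic covariates **Z**ᵢ, latent disability
**η**ᵢ ∈ ℝ^Q (Q = 1 or 2) follows the structural equation

    η_iq = θ_q' Z_i + ν_iq ,          ν_i ~ N(0, Σ_ν) ,

each ordinal indicator D_ij ∈ {1, …, M_j} arises from an ordered probit
measurement model

    D̃_ij = λ_j' η_i + ε_ij ,  ε_ij ~ N(0,1) ,
    D_ij = m  ⇔  A_{j,m−1} ≤ D̃_ij < A_{j,m} ,

and binary benefit receipt R_i is a probit

    R_i = 1{ β' Z_i + γ' η_i + u_i > 0 } ,  u_i ~ N(0,1) .

All equations are estimated **simultaneously** by marginal maximum
likelihood, integrating η out with Gauss–Hermite quadrature centred at the
structural mean; standard errors are household-cluster-robust sandwich
estimates built from analytic per-person scores. The scale of η is fixed
either by an anchor loading (λ = 1 for a reference mobility item) or by a
unit residual variance; the two normalizations are exactly equivalent
reparameterizations and the package verifies this.

Around the core model the package provides:

- **Cross-survey comparison** — per-coefficient z tests and joint Wald χ²
  tests of coefficient equality between independently fitted surveys.
- **Mahalanobis matching** — greedy one-to-one nearest-neighbour matching
  without replacement under a caliper, pair trimming by extreme income
  differences, and balance diagnostics, used to standardize sample
  composition before re-fitting.
- **Targeting diagnostics** — posterior disability factor scores
  E[η | D, Z], kernel-smoothed receipt-by-score curves and decile tables,
  and receipt-probability profiles for benchmark covariate profiles.
- **Synthetic multi-survey generator** — three survey templates with
  different indicator menus (8 binary items + proxy flag; 12 binary
  ADL/IADL items; binary + six-category ordinal items) over shared SES
  covariates with household clustering, so the whole analysis chain is
  testable without access to restricted survey deposits.

## Worked example

```python
import distarget as dt

cfg = dt.GeneratorConfig(
    survey_template="frs_like",
    n_households=dt.households_for_persons(2000),
    seed=7,
)
data, spec, truth = dt.generate_survey(cfg)
fit = dt.fit_model(data, spec)

print(f"log-likelihood = {fit.loglik:.1f}, AIC = {fit.aic:.1f}")
print(fit.coef_table().loc[[n for n in fit.param_names
                            if n.startswith(("theta:", "gamma:", "sigma2"))]].round(3))

scores = dt.posterior_disability_scores(data, spec, fit.estimates)
curve = dt.targeting_curve(scores[:, 0], data.df["receipt"].to_numpy(), bandwidth=0.4)
print(curve.deciles.round(3).to_string(index=False))
```

Output:

```
log-likelihood = -5737.2, AIC = 11542.4
                      estimate  se_robust      z      p
parameter
theta:1:age_below        0.030      0.032  0.961  0.337
theta:1:age_above        0.085      0.011  7.729  0.000
theta:1:education       -0.387      0.134 -2.891  0.004
theta:1:income_below    -0.402      0.278 -1.447  0.148
theta:1:income_above    -0.146      0.299 -0.489  0.625
theta:1:owner           -0.397      0.132 -3.005  0.003
sigma2_nu                2.903      0.456  6.368  0.000
gamma:1                  0.537      0.058  9.233  0.000
 decile  mean_score  mean_receipt   n
      1      -1.771         0.000 200
      ...
      9       1.823         0.205 200
     10       3.182         0.477 199
```

Disability rises with age (steeper after the knot at 73) and falls with
education, income and outright home ownership; the receipt effect of latent
disability γ is strongly positive. The decile table is the targeting
diagnostic: receipt prevalence climbs from 0% in the least-disabled decile
to 48% in the most-disabled one, the qualitative signature of a benefit
that reaches the disabled.

A command-line interface mirrors the library:
`distarget simulate|fit|compare|match|pipeline --help`.

## Documentation

`docs/methods.md` describes the model, the numerical choices (quadrature,
optimization, sandwich covariance), the synthetic-data design and known
limitations.
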