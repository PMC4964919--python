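"""Measurement/receipt probabilities and the marginal likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import log_ndtr
from scipy.stats import norm

import distarget as dt
from distarget.model import (
    GaussHermite,
    ModelSpecError,
    ParameterError,
    Parameterization,
    SurveyDesign,
    indicator_category_prob,
    loglik_components,
    person_loglik,
    receipt_prob,
    sample_loglik,
)


# ---------------------------------------------------------------------------
# specification invariants
# ---------------------------------------------------------------------------


def test_gender_cannot_enter_structural_equation(frs_spec):
    with pytest.raises(ModelSpecError, match="gender"):
        dt.ModelSpec(
            survey_label="bad",
            n_factors=1,
            indicators=frs_spec.indicators,
            structural_covariates=("age_below", "female"),
            receipt_covariates=("const",),
        )


def test_anchor_must_load_on_its_factor():
    with pytest.raises(ModelSpecError):
        dt.IndicatorSpec(name="x", n_categories=2, loads_on=(0,), anchor_for=1)


# ---------------------------------------------------------------------------
# category and receipt probabilities
# ---------------------------------------------------------------------------


def _unit_binary_spec():
    return dt.ModelSpec(
        survey_label="toy",
        n_factors=1,
        indicators=(dt.IndicatorSpec("item", 2, (0,), anchor_for=0),),
        structural_covariates=("x",),
        receipt_covariates=("const",),
    )


def _unit_binary_params(spec):
    from distarget.model import template_parameter_set

    pset = template_parameter_set(spec)
    pset.loadings["all"][0, 0] = 1.0
    pset.thresholds["all"][0] = np.zeros(1)
    return pset


def test_category_prob_symmetry_and_normal_cdf():
    spec = _unit_binary_spec()
    pset = _unit_binary_params(spec)
    assert indicator_category_prob(spec, pset, "item", 1, np.array([0.0])) == pytest.approx(0.5)
    assert indicator_category_prob(spec, pset, "item", 2, np.array([0.0])) == pytest.approx(0.5)
    # threshold {0}, lambda=1, eta=1 -> P(m=2) = Phi(1)
    assert indicator_category_prob(spec, pset, "item", 2, np.array([1.0])) == pytest.approx(
        0.84134, abs=1e-5
    )


def test_category_prob_rejects_nonmonotone_thresholds():
    spec = dt.ModelSpec(
        survey_label="toy",
        n_factors=1,
        indicators=(dt.IndicatorSpec("item", 4, (0,), anchor_for=0),),
        structural_covariates=("x",),
        receipt_covariates=("const",),
    )
    pset = _unit_binary_params(spec)
    pset.thresholds["all"][0] = np.array([0.0, -1.0, 1.0])
    with pytest.raises(ParameterError, match="thresholds"):
        indicator_category_prob(spec, pset, "item", 1, np.array([0.0]))


@given(
    eta=st.floats(-4, 4),
    lam=st.floats(0.1, 2.0),
    cuts=st.lists(st.floats(-3, 3), min_size=1, max_size=5, unique=True),
)
def test_category_probs_sum_to_one(eta, lam, cuts):
    m_count = len(cuts) + 1
    spec = dt.ModelSpec(
        survey_label="toy",
        n_factors=1,
        indicators=(dt.IndicatorSpec("item", m_count, (0,)),),
        structural_covariates=("x",),
        receipt_covariates=("const",),
        normalization="unit_variance",
    )
    from distarget.model import template_parameter_set

    pset = template_parameter_set(spec)
    pset.loadings["all"][0, 0] = lam
    pset.thresholds["all"][0] = np.sort(np.asarray(cuts))
    total = sum(
        indicator_category_prob(spec, pset, "item", m, np.array([eta]))
        for m in range(1, m_count + 1)
    )
    assert total == pytest.approx(1.0, abs=1e-12)


def test_receipt_prob_examples():
    spec = _unit_binary_spec()
    pset = _unit_binary_params(spec)
    assert receipt_prob(spec, pset, np.array([3.0]), np.array([1.0])) == pytest.approx(0.5)
    pset.gamma = np.array([1.0])
    assert receipt_prob(spec, pset, np.array([2.0]), np.array([0.0])) == pytest.approx(
        0.97725, abs=1e-5
    )
    probs = [receipt_prob(spec, pset, np.array([e]), np.array([0.0])) for e in (-1, 0, 1, 2)]
    assert np.all(np.diff(probs) > 0)


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def test_all_missing_indicators_reduce_to_probit(frs_spec, frs_truth, small_survey):
    """With gamma = 0 and no indicator responses the person likelihood is the
    plain probit likelihood of receipt given covariates."""
    row = small_survey.df.iloc[[0]].copy()
    for name in frs_spec.indicator_names:
        row[name] = np.nan
    pset = frs_truth.copy()
    pset.gamma = np.zeros(1)
    quad = GaussHermite(21, 1)
    ll = person_loglik(row, frs_spec, pset, quad)
    design = SurveyDesign(row, frs_spec)
    idx = float(design.Zr[0] @ pset.beta)
    sign = 2 * int(design.receipt[0]) - 1
    assert ll == pytest.approx(float(log_ndtr(sign * idx)), abs=1e-10)


def test_zero_loadings_factorize(frs_spec, frs_truth, small_survey):
    """lambda = 0 and gamma = 0 make indicators marginal ordered-probit cells
    independent of the latent factor."""
    data = dt.SurveyDataset(small_survey.label, small_survey.df.head(50).copy())
    pset = frs_truth.copy()
    pset.loadings["all"] = np.zeros_like(pset.loadings["all"])
    pset.gamma = np.zeros(1)
    quad = GaussHermite(21, 1)
    ll = sample_loglik(data, frs_spec, pset, quad)
    design = SurveyDesign(data, frs_spec)
    expected = 0.0
    for i in range(design.n):
        for j, ind in enumerate(frs_spec.indicators):
            c = design.codes[i, j]
            if c == 0:
                continue
            thr = pset.thresholds["all"][j]
            up = thr[c - 1] if c <= len(thr) else np.inf
            lo = thr[c - 2] if c >= 2 else -np.inf
            expected += math.log(norm.cdf(up) - norm.cdf(lo))
        sign = 2 * int(design.receipt[i]) - 1
        expected += float(log_ndtr(sign * float(design.Zr[i] @ pset.beta)))
    assert ll == pytest.approx(expected, abs=1e-6)


def test_sample_loglik_additivity_weights_and_empty(frs_spec, frs_truth, small_survey):
    quad = GaussHermite(11, 1)
    head = dt.SurveyDataset("h", small_survey.df.head(40).copy())
    ll1 = sample_loglik(head, frs_spec, frs_truth, quad)
    doubled = dt.SurveyDataset(
        "d", pd.concat([head.df, head.df], ignore_index=True)
    )
    assert sample_loglik(doubled, frs_spec, frs_truth, quad) == pytest.approx(2 * ll1, rel=1e-12)
    weighted = dt.SurveyDataset("w", head.df.assign(weight=2.0))
    assert sample_loglik(weighted, frs_spec, frs_truth, quad) == pytest.approx(2 * ll1, rel=1e-12)
    empty = dt.SurveyDataset("e", head.df.iloc[:0].copy())
    assert sample_loglik(empty, frs_spec, frs_truth, quad) == 0.0


def test_loglik_invariant_to_indicator_order(frs_spec, frs_truth, small_survey):
    row = small_survey.df.iloc[[3]]
    quad = GaussHermite(15, 1)
    base = person_loglik(row, frs_spec, frs_truth, quad)
    perm = np.array([4, 2, 0, 7, 5, 1, 8, 3, 6])
    spec2 = dt.ModelSpec(
        survey_label=frs_spec.survey_label,
        n_factors=1,
        indicators=tuple(frs_spec.indicators[i] for i in perm),
        structural_covariates=frs_spec.structural_covariates,
        receipt_covariates=frs_spec.receipt_covariates,
        splines=frs_spec.splines,
    )
    pset2 = frs_truth.copy()
    pset2.loadings["all"] = frs_truth.loadings["all"][perm]
    pset2.thresholds["all"] = [frs_truth.thresholds["all"][i] for i in perm]
    assert person_loglik(row, spec2, pset2, quad) == pytest.approx(base, abs=1e-12)


def test_quadrature_convergence(frs_spec, frs_truth, small_survey):
    """The node-doubling error shrinks as the rule is refined."""
    data = dt.SurveyDataset("q", small_survey.df.head(100).copy())
    values = {
        k: sample_loglik(data, frs_spec, frs_truth, GaussHermite(k, 1))
        for k in (10, 20, 40, 80, 160)
    }
    gaps = [abs(values[k] - values[2 * k]) for k in (10, 20, 40, 80)]
    assert gaps[0] > gaps[1] > gaps[2] > gaps[3]
    assert gaps[3] < 1e-3


def test_reparameterization_equivalence(frs_spec, frs_truth, small_survey):
    """Anchor-loading and unit-variance parameterizations linked by the
    sigma_nu rescaling give identical likelihoods."""
    data = dt.SurveyDataset("r", small_survey.df.head(80).copy())
    quad = GaussHermite(21, 1)
    ll_anchor = sample_loglik(data, frs_spec, frs_truth, quad)
    spec_unit = dt.make_survey_template("frs_like", normalization="unit_variance")
    s = math.sqrt(frs_truth.sigma2)
    pset_u = frs_truth.copy()
    pset_u.loadings["all"] = frs_truth.loadings["all"] * s
    pset_u.theta = frs_truth.theta / s
    pset_u.gamma = frs_truth.gamma * s
    pset_u.chol = np.eye(1)
    assert sample_loglik(data, spec_unit, pset_u, quad) == pytest.approx(ll_anchor, abs=1e-8)


def test_quadrature_matches_monte_carlo_small(frs_spec, frs_truth, small_survey):
    """Spot-check of the Gauss-Hermite integral against brute-force
    simulation from the latent prior (the full check runs in acceptance)."""
    rng = np.random.default_rng(5)
    design = SurveyDesign(dt.SurveyDataset("m", small_survey.df.head(3).copy()), frs_spec)
    ll_q, _, _ = loglik_components(design, frs_truth, GaussHermite(61, 1))
    n_mc = 200_000
    draws = rng.standard_normal((n_mc, 1)) @ frs_truth.chol.T
    mu = design.Zs @ frs_truth.theta.T
    for i in range(design.n):
        eta = mu[i] + draws
        logf = np.zeros(n_mc)
        for j, ind in enumerate(frs_spec.indicators):
            c = design.codes[i, j]
            if c == 0:
                continue
            v = eta @ frs_truth.loadings["all"][j]
            thr = frs_truth.thresholds["all"][j]
            up = thr[c - 1] if c <= len(thr) else np.inf
            lo = thr[c - 2] if c >= 2 else -np.inf
            logf += np.log(np.clip(norm.cdf(up - v) - norm.cdf(lo - v), 1e-300, 1))
        sign = 2 * int(design.receipt[i]) - 1
        logf += log_ndtr(sign * (design.Zr[i] @ frs_truth.beta + eta @ frs_truth.gamma))
        f = np.exp(logf)
        mc_mean = f.mean()
        mc_se = f.std(ddof=1) / math.sqrt(n_mc)
        assert abs(math.exp(ll_q[i]) - mc_mean) < 3 * mc_se
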