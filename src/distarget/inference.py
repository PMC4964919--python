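"""Cross-survey comparison tests, factor scores, targeting curves, profiles.

Because the surveys are independent samples, equality of a coefficient
subset across two fitted models is tested with the Wald statistic
W = d'(V_a + V_b)^{-1} d ~ chi2(k), d the estimate difference and V the
cluster-robust covariance blocks; per-coefficient z statistics use the
corresponding diagonal terms.  Disability factor scores are posterior means
E[eta | D, Z] under the fitted model, computed by the same Gauss-Hermite
rule as the likelihood; receipt is deliberately not conditioned on, so the
receipt-by-score targeting curve is not mechanically circular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import chi2, norm

from .estimation import FitResult
from .model import GaussHermite, ModelSpec, ParameterSet, SurveyDesign, loglik_components

__all__ = [
    "EqualityTestResult",
    "TargetingCurve",
    "wald_equality_test",
    "posterior_disability_scores",
    "posterior_disability_score",
    "targeting_curve",
    "predict_profile",
]


@dataclass
class EqualityTestResult:
    """Per-coefficient and joint equality tests between two independent fits."""

    table: pd.DataFrame  # difference, se_diff, z, p (and Bonferroni-adjusted p)
    wald: float
    df: int
    p_value: float


def wald_equality_test(
    fit_a: FitResult, fit_b: FitResult, names: list[str], bonferroni: bool = True
) -> EqualityTestResult:
    """Test equality of named coefficients across two independently fitted
    surveys.

    Per-coefficient differences are reported raw (z, p); an optional
    Bonferroni-adjusted p column guards the multiple-comparison caveat.  The
    joint statistic uses the block-diagonal covariance implied by sample
    independence.
    """
    for n in names:
        if n not in fit_a.param_names:
            raise KeyError(f"coefficient {n!r} not in fit {fit_a.spec.survey_label!r}")
        if n not in fit_b.param_names:
            raise KeyError(f"coefficient {n!r} not in fit {fit_b.spec.survey_label!r}")
    est_a, v_a = fit_a.subset(names)
    est_b, v_b = fit_b.subset(names)
    d = est_a - est_b
    v_sum = v_a + v_b
    se = np.sqrt(np.diag(v_sum))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, d / se, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    k = len(names)
    wald = float(d @ np.linalg.solve(v_sum, d)) if k else 0.0
    wald = max(wald, 0.0)
    table = pd.DataFrame(
        {"difference": d, "se_diff": se, "z": z, "p": p},
        index=pd.Index(names, name="coefficient"),
    )
    if bonferroni:
        table["p_bonferroni"] = np.minimum(p * k, 1.0)
    return EqualityTestResult(
        table=table, wald=wald, df=k, p_value=float(chi2.sf(wald, k)) if k else 1.0
    )


def posterior_disability_scores(
    data,
    spec: ModelSpec,
    pset: ParameterSet,
    quad_points: int = 21,
) -> np.ndarray:
    """Posterior mean disability E[eta | D, Z] for every person, (n, Q).

    The posterior is proportional to the indicator likelihood times the
    structural prior N(theta'Z, Sigma_nu); receipt is not conditioned on.
    Persons with no observed indicators receive the prior mean theta'Z.
    """
    design = data if isinstance(data, SurveyDesign) else SurveyDesign(data, spec)
    quad = GaussHermite(quad_points, spec.n_factors)
    _, _, post = loglik_components(design, pset, quad, include_receipt=False)
    pw = post["weights"]
    scores = np.array(post["mu"], dtype=float)
    for g, rows in design.group_rows.items():
        if rows.size == 0:
            continue
        eta = post["eta_by_group"][g]
        scores[rows] = np.einsum("ik,ikq->iq", pw[rows], eta)
    no_obs = (design.codes > 0).sum(axis=1) == 0
    if np.any(no_obs):
        scores[no_obs] = post["mu"][no_obs]
    return scores


def posterior_disability_score(row, spec, pset, quad_points: int = 21) -> np.ndarray:
    """Posterior disability score of a single person record (Q-vector)."""
    df = row if isinstance(row, pd.DataFrame) else pd.DataFrame([row])
    return posterior_disability_scores(df, spec, pset, quad_points)[0]


@dataclass
class TargetingCurve:
    """Kernel-smoothed receipt rate along the disability-score axis."""

    curve: pd.DataFrame  # score, receipt_rate
    deciles: pd.DataFrame  # decile, mean_score, mean_receipt, n
    bandwidth: float


def targeting_curve(
    scores: np.ndarray,
    receipt: np.ndarray,
    bandwidth: float = 0.4,
    n_grid: int = 101,
) -> TargetingCurve:
    """Local linear regression of receipt on the disability score.

    Gaussian kernel at the given bandwidth over an even grid spanning the
    1st-99th percentile of the scores, plus decile-mean receipt rates.
    """
    scores = np.asarray(scores, dtype=float)
    receipt = np.asarray(receipt, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if scores.size < 20:
        raise ValueError("need at least 20 observations for a stable smoother")
    lo, hi = np.percentile(scores, [1.0, 99.0])
    grid = np.linspace(lo, hi, n_grid)
    fitted = np.empty(n_grid)
    for i, g in enumerate(grid):
        u = (scores - g) / bandwidth
        w = np.exp(-0.5 * u * u)
        x = scores - g
        s0, s1, s2 = w.sum(), (w * x).sum(), (w * x * x).sum()
        t0, t1 = (w * receipt).sum(), (w * x * receipt).sum()
        denom = s0 * s2 - s1 * s1
        if denom <= 1e-12 * max(s0 * s2, 1e-300):
            fitted[i] = t0 / s0 if s0 > 0 else np.nan
        else:
            fitted[i] = (s2 * t0 - s1 * t1) / denom
    fitted = np.clip(fitted, 0.0, 1.0)

    order = np.argsort(scores, kind="stable")
    bins = np.array_split(order, 10)
    deciles = pd.DataFrame(
        {
            "decile": np.arange(1, 11),
            "mean_score": [scores[b].mean() for b in bins],
            "mean_receipt": [receipt[b].mean() for b in bins],
            "n": [len(b) for b in bins],
        }
    )
    return TargetingCurve(
        curve=pd.DataFrame({"score": grid, "receipt_rate": fitted}),
        deciles=deciles,
        bandwidth=bandwidth,
    )


def plot_targeting_curve(curve: TargetingCurve, ax=None, label: str | None = None):
    """Render a targeting curve (smoothed line plus decile points).

    Returns the matplotlib axes; importing matplotlib is deferred so the
    plotting dependency is only touched when a figure is requested.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.curve["score"], curve.curve["receipt_rate"], label=label)
    ax.scatter(
        curve.deciles["mean_score"], curve.deciles["mean_receipt"], s=18, zorder=3
    )
    ax.set_xlabel("posterior disability score")
    ax.set_ylabel("receipt rate")
    ax.set_ylim(-0.02, 1.02)
    if label:
        ax.legend()
    return ax


def predict_profile(
    profile: dict[str, float],
    eta_grid: np.ndarray,
    spec: ModelSpec,
    pset: ParameterSet,
    eta_mean: float = 0.0,
    eta_sd: float | None = None,
    factor: int = 0,
) -> np.ndarray:
    """Receipt probabilities for a benchmark covariate profile along a grid
    of disability values given in standard-deviation units.

    ``eta_grid`` is rescaled to the latent scale as ``eta_mean + eta_sd *
    grid`` before entering the receipt probit; by default ``eta_sd`` is the
    residual SD sqrt(sigma2_nu) of the scored factor, and callers comparing
    population profiles should pass the total SD of the fitted scores.
    """
    z = np.array(
        [
            1.0 if name == "const" else float(profile[name])
            for name in spec.receipt_covariates
        ]
    )
    if eta_sd is None:
        eta_sd = float(np.sqrt(pset.sigma[factor, factor]))
    eta_values = eta_mean + eta_sd * np.asarray(eta_grid, dtype=float)
    idx = float(pset.beta @ z) + pset.gamma[factor] * eta_values
    return ndtr(idx)
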