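"""Latent-variable (MIMIC) model of disability and benefit receipt.

The model has three blocks.  A person's latent disability ``eta`` (one or two
factors) is driven by socio-economic covariates,

    eta_q = theta_q' Z + nu_q,          nu ~ N(0, Sigma_nu),

and is reflected in a set of survey-specific ordinal/binary indicators through
an ordered-probit measurement model,

    D~_j = lambda_j' eta + eps_j,       eps_j ~ N(0, 1),
    D_j = m  <=>  A_{j,m-1} <= D~_j < A_{j,m},

with strictly increasing thresholds ``A`` (A_0 = -inf, A_M = +inf) and the
indicator intercept fixed at 0.  Benefit receipt is a probit,

    R = 1{ beta' Z + gamma' eta + u > 0 },    u ~ N(0, 1).

All equations are estimated jointly; the marginal likelihood of the observed
(D, R) integrates ``eta`` out by Gauss-Hermite quadrature centred at the
structural mean ``theta' Z`` and scaled by ``chol(Sigma_nu)``.

Scale and location identification: either one "anchor" loading per factor is
fixed at 1 (``anchor_loading``) or the residual variance of each factor is
fixed at 1 (``unit_variance``); indicator intercepts are absorbed into the
free thresholds; the structural equation carries no intercept while the
receipt equation does (the ``const`` covariate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp, ndtr

__all__ = [
    "IndicatorSpec",
    "ModelSpec",
    "ParameterSet",
    "Parameterization",
    "GaussHermite",
    "SurveyDesign",
    "ModelSpecError",
    "ParameterError",
    "indicator_category_prob",
    "receipt_prob",
    "person_loglik",
    "sample_loglik",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)


class ModelSpecError(ValueError):
    """Invalid model specification (factors, indicators, covariate roles)."""


class ParameterError(ValueError):
    """Invalid parameter values (non-monotone thresholds, non-PD covariance)."""


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndicatorSpec:
    """One survey indicator.

    Parameters
    ----------
    name
        Column name in the person table.
    n_categories
        Number of ordered response categories ``M_j`` (2 for binary items;
        binary code 2 means "has difficulty").
    loads_on
        Factors (0-based) the indicator loads on; cross-loadings allowed.
    anchor_for
        Factor whose scale this indicator sets (loading fixed at 1) under the
        ``anchor_loading`` normalization.
    is_proxy_flag
        Marks a proxy-response flag used as an additional indicator.
    """

    name: str
    n_categories: int = 2
    loads_on: tuple[int, ...] = (0,)
    anchor_for: int | None = None
    is_proxy_flag: bool = False

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ModelSpecError(f"indicator {self.name!r}: n_categories must be >= 2")
        if not self.loads_on:
            raise ModelSpecError(f"indicator {self.name!r}: loads_on must be non-empty")
        if self.anchor_for is not None and self.anchor_for not in self.loads_on:
            raise ModelSpecError(
                f"indicator {self.name!r}: anchor factor {self.anchor_for} "
                "is not among its loadings"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description for one survey."""

    survey_label: str
    n_factors: int
    indicators: tuple[IndicatorSpec, ...]
    structural_covariates: tuple[str, ...]
    receipt_covariates: tuple[str, ...]
    normalization: str = "anchor_loading"
    gender_specific_measurement: bool = False
    splines: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_factors not in (1, 2):
            raise ModelSpecError("n_factors must be 1 or 2")
        if self.normalization not in ("anchor_loading", "unit_variance"):
            raise ModelSpecError(f"unknown normalization {self.normalization!r}")
        names = [ind.name for ind in self.indicators]
        if len(set(names)) != len(names):
            raise ModelSpecError("duplicate indicator names")
        for ind in self.indicators:
            if any(q < 0 or q >= self.n_factors for q in ind.loads_on):
                raise ModelSpecError(f"indicator {ind.name!r} loads on unknown factor")
        # Gender acts through gender-specific measurement parameters, so the
        # female dummy may not appear among the structural covariates.
        if "female" in self.structural_covariates or "gender" in self.structural_covariates:
            raise ModelSpecError("gender must be excluded from the structural covariates")
        if self.normalization == "anchor_loading":
            for q in range(self.n_factors):
                anchors = [ind for ind in self.indicators if ind.anchor_for == q]
                if len(anchors) != 1:
                    raise ModelSpecError(
                        f"anchor_loading normalization needs exactly one anchor "
                        f"for factor {q + 1}; found {len(anchors)}"
                    )

    @property
    def groups(self) -> tuple[str, ...]:
        """Measurement parameter groups ('all', or per-gender)."""
        if self.gender_specific_measurement:
            return ("male", "female")
        return ("all",)

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(ind.name for ind in self.indicators)

    def indicator(self, name: str) -> IndicatorSpec:
        for ind in self.indicators:
            if ind.name == name:
                return ind
        raise KeyError(name)

    def anchor_name(self, q: int) -> str | None:
        for ind in self.indicators:
            if ind.anchor_for == q:
                return ind.name
        return None


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All model parameters in structured form.

    ``loadings[g]`` is a ``(J, Q)`` array (zeros off the declared loading
    pattern), ``thresholds[g]`` a list of ``(M_j - 1,)`` arrays, one per
    indicator.  ``theta`` is ``(Q, S)`` over the structural covariates,
    ``chol`` the lower-triangular Cholesky factor of ``Sigma_nu``; ``beta``
    covers the receipt covariates and ``gamma`` the factor effects on receipt.
    """

    loadings: dict[str, np.ndarray]
    thresholds: dict[str, list[np.ndarray]]
    theta: np.ndarray
    chol: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        """Residual covariance Sigma_nu of the latent factors."""
        return self.chol @ self.chol.T

    @property
    def sigma2(self) -> float:
        """Scalar residual variance (one-factor models)."""
        if self.chol.shape != (1, 1):
            raise ValueError("sigma2 is defined for one-factor models only")
        return float(self.chol[0, 0] ** 2)

    @property
    def factor_correlation(self) -> float:
        """Residual correlation of the two factors (two-factor models)."""
        s = self.sigma
        if s.shape != (2, 2):
            raise ValueError("factor_correlation requires two factors")
        return float(s[0, 1] / math.sqrt(s[0, 0] * s[1, 1]))

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            loadings={g: v.copy() for g, v in self.loadings.items()},
            thresholds={g: [t.copy() for t in v] for g, v in self.thresholds.items()},
            theta=self.theta.copy(),
            chol=self.chol.copy(),
            beta=self.beta.copy(),
            gamma=self.gamma.copy(),
        )

    def validate(self, spec: ModelSpec) -> None:
        for g in spec.groups:
            for j, ind in enumerate(spec.indicators):
                thr = self.thresholds[g][j]
                if len(thr) != ind.n_categories - 1:
                    raise ParameterError(f"indicator {ind.name!r}: wrong threshold count")
                if np.any(np.diff(thr) <= 0):
                    raise ParameterError(f"indicator {ind.name!r}: thresholds not increasing")
        if np.any(np.diag(self.chol) <= 0):
            raise ParameterError("Sigma_nu is not positive definite")


def template_parameter_set(spec: ModelSpec, n_structural: int | None = None) -> ParameterSet:
    """A valid starting structure: unit loadings on the declared pattern,
    evenly spaced thresholds, zero coefficients, identity factor covariance."""
    q = spec.n_factors
    s = len(spec.structural_covariates) if n_structural is None else n_structural
    loadings: dict[str, np.ndarray] = {}
    thresholds: dict[str, list[np.ndarray]] = {}
    for g in spec.groups:
        lam = np.zeros((len(spec.indicators), q))
        thr: list[np.ndarray] = []
        for j, ind in enumerate(spec.indicators):
            for f in ind.loads_on:
                lam[j, f] = 1.0
            m = ind.n_categories
            thr.append(np.linspace(-1.0, 1.0, m - 1) if m > 2 else np.zeros(1))
        loadings[g] = lam
        thresholds[g] = thr
    return ParameterSet(
        loadings=loadings,
        thresholds=thresholds,
        theta=np.zeros((q, s)),
        chol=np.eye(q),
        beta=np.zeros(len(spec.receipt_covariates)),
        gamma=np.zeros(q),
    )


# ---------------------------------------------------------------------------
# Flat parameter vector <-> structured parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Entry:
    name: str
    kind: str  # loading | threshold | theta | beta | gamma | sigma2 | chol_diag | chol_off | rho
    loc: tuple


class Parameterization:
    """Canonical bijection between free parameters and a real vector.

    The canonical order is: measurement (by indicator, then gender group),
    structural coefficients, factor covariance, receipt coefficients.  Anchor
    loadings (under ``anchor_loading``) and unit factor variances (under
    ``unit_variance``) are fixed, not free.  ``fixed`` pins further named
    parameters at given values (coefficients and loadings only; thresholds and
    covariance parameters cannot be pinned).

    An internal unconstrained reparameterization is provided for optimization:
    thresholds become (first threshold, log-increments), variances and
    Cholesky diagonals become logs, the two-factor ``unit_variance``
    correlation becomes its atanh.
    """

    def __init__(self, spec: ModelSpec, fixed: dict[str, float] | None = None):
        self.spec = spec
        self.fixed = dict(fixed or {})
        entries: list[_Entry] = []
        anchored = spec.normalization == "anchor_loading"
        for g in spec.groups:
            for j, ind in enumerate(spec.indicators):
                for q in ind.loads_on:
                    if anchored and ind.anchor_for == q:
                        continue  # fixed at 1
                    entries.append(
                        _Entry(f"loading:{g}:{ind.name}:{q + 1}", "loading", (g, j, q))
                    )
                for m in range(ind.n_categories - 1):
                    entries.append(
                        _Entry(f"threshold:{g}:{ind.name}:{m + 1}", "threshold", (g, j, m))
                    )
        for q in range(spec.n_factors):
            for s, cov in enumerate(spec.structural_covariates):
                entries.append(_Entry(f"theta:{q + 1}:{cov}", "theta", (q, s)))
        if anchored:
            if spec.n_factors == 1:
                entries.append(_Entry("sigma2_nu", "sigma2", (0, 0)))
            else:
                entries.append(_Entry("chol:1:1", "chol_diag", (0, 0)))
                entries.append(_Entry("chol:2:1", "chol_off", (1, 0)))
                entries.append(_Entry("chol:2:2", "chol_diag", (1, 1)))
        elif spec.n_factors == 2:
            entries.append(_Entry("rho_nu", "rho", (1, 0)))
        for r, cov in enumerate(spec.receipt_covariates):
            entries.append(_Entry(f"beta:{cov}", "beta", (r,)))
        for q in range(spec.n_factors):
            entries.append(_Entry(f"gamma:{q + 1}", "gamma", (q,)))

        known = {e.name for e in entries}
        for name in self.fixed:
            if name not in known:
                raise KeyError(f"cannot fix unknown parameter {name!r}")
            kind = next(e.kind for e in entries if e.name == name)
            if kind not in ("loading", "theta", "beta", "gamma"):
                raise ValueError(f"parameter {name!r} of kind {kind!r} cannot be pinned")
        self.entries = [e for e in entries if e.name not in self.fixed]
        self._threshold_blocks = self._find_threshold_blocks()

    # -- layout ------------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def n_free(self) -> int:
        return len(self.entries)

    def _find_threshold_blocks(self) -> list[tuple[int, int]]:
        blocks = []
        i = 0
        while i < len(self.entries):
            if self.entries[i].kind == "threshold":
                g, j, _ = self.entries[i].loc
                start = i
                while (
                    i < len(self.entries)
                    and self.entries[i].kind == "threshold"
                    and self.entries[i].loc[:2] == (g, j)
                ):
                    i += 1
                blocks.append((start, i - start))
            else:
                i += 1
        return blocks

    # -- structured <-> external flat vector -------------------------------

    def flatten(self, pset: ParameterSet) -> np.ndarray:
        x = np.empty(self.n_free)
        for i, e in enumerate(self.entries):
            x[i] = self._get(pset, e)
        return x

    def _get(self, pset: ParameterSet, e: _Entry) -> float:
        if e.kind == "loading":
            g, j, q = e.loc
            return pset.loadings[g][j, q]
        if e.kind == "threshold":
            g, j, m = e.loc
            return pset.thresholds[g][j][m]
        if e.kind == "theta":
            return pset.theta[e.loc]
        if e.kind == "sigma2":
            return pset.chol[0, 0] ** 2
        if e.kind in ("chol_diag", "chol_off"):
            return pset.chol[e.loc]
        if e.kind == "rho":
            return pset.chol[1, 0]
        if e.kind == "beta":
            return pset.beta[e.loc[0]]
        return pset.gamma[e.loc[0]]

    def unflatten(self, x: np.ndarray, base: ParameterSet | None = None) -> ParameterSet:
        spec = self.spec
        pset = (base or template_parameter_set(spec)).copy()
        if spec.normalization == "anchor_loading":
            for g in spec.groups:
                for j, ind in enumerate(spec.indicators):
                    if ind.anchor_for is not None:
                        pset.loadings[g][j, ind.anchor_for] = 1.0
        else:
            pset.chol = np.eye(spec.n_factors)
        values = dict(zip(self.names, x))
        values.update(self.fixed)
        all_entries = self.entries + [
            e for e in self._fixed_entries() if e.name in self.fixed
        ]
        for e in all_entries:
            v = values[e.name]
            if e.kind == "loading":
                g, j, q = e.loc
                pset.loadings[g][j, q] = v
            elif e.kind == "threshold":
                g, j, m = e.loc
                pset.thresholds[g][j][m] = v
            elif e.kind == "theta":
                pset.theta[e.loc] = v
            elif e.kind == "sigma2":
                pset.chol = np.array([[math.sqrt(max(v, 1e-12))]])
            elif e.kind in ("chol_diag", "chol_off"):
                pset.chol[e.loc] = v
            elif e.kind == "rho":
                pset.chol = np.array([[1.0, 0.0], [v, math.sqrt(max(1 - v * v, 1e-12))]])
            elif e.kind == "beta":
                pset.beta[e.loc[0]] = v
            else:
                pset.gamma[e.loc[0]] = v
        return pset

    def _fixed_entries(self) -> list[_Entry]:
        out = []
        for name in self.fixed:
            parts = name.split(":")
            if name.startswith("loading:"):
                g, ind_name, q = parts[1], parts[2], int(parts[3]) - 1
                j = self.spec.indicator_names.index(ind_name)
                out.append(_Entry(name, "loading", (g, j, q)))
            elif name.startswith("theta:"):
                q = int(parts[1]) - 1
                s = self.spec.structural_covariates.index(parts[2])
                out.append(_Entry(name, "theta", (q, s)))
            elif name.startswith("beta:"):
                out.append(_Entry(name, "beta", (self.spec.receipt_covariates.index(parts[1]),)))
            elif name.startswith("gamma:"):
                out.append(_Entry(name, "gamma", (int(parts[1]) - 1,)))
        return out

    # -- external <-> internal (unconstrained) ------------------------------

    def to_internal(self, x: np.ndarray) -> np.ndarray:
        y = np.array(x, dtype=float)
        for i, e in enumerate(self.entries):
            if e.kind in ("sigma2", "chol_diag"):
                y[i] = math.log(x[i])
            elif e.kind == "rho":
                y[i] = math.atanh(np.clip(x[i], -0.999999, 0.999999))
        for start, length in self._threshold_blocks:
            a = np.asarray(x[start : start + length])
            y[start] = a[0]
            if length > 1:
                y[start + 1 : start + length] = np.log(np.diff(a))
        return y

    def from_internal(self, y: np.ndarray) -> np.ndarray:
        x = np.array(y, dtype=float)
        for i, e in enumerate(self.entries):
            if e.kind in ("sigma2", "chol_diag"):
                x[i] = math.exp(y[i])
            elif e.kind == "rho":
                x[i] = math.tanh(y[i])
        for start, length in self._threshold_blocks:
            x[start] = y[start]
            if length > 1:
                x[start + 1 : start + length] = y[start] + np.cumsum(
                    np.exp(y[start + 1 : start + length])
                )
        return x

    def grad_to_internal(self, y: np.ndarray, grad_ext: np.ndarray) -> np.ndarray:
        """Chain rule: gradient w.r.t. external params -> internal params."""
        g = np.array(grad_ext, dtype=float)
        x = self.from_internal(y)
        for i, e in enumerate(self.entries):
            if e.kind in ("sigma2", "chol_diag"):
                g[i] = grad_ext[i] * x[i]
            elif e.kind == "rho":
                g[i] = grad_ext[i] * (1.0 - x[i] ** 2)
        for start, length in self._threshold_blocks:
            ge = np.asarray(grad_ext[start : start + length])
            g[start] = ge.sum()
            for m in range(1, length):
                g[start + m] = math.exp(y[start + m]) * ge[m:].sum()
        return g


# ---------------------------------------------------------------------------
# Quadrature
# ---------------------------------------------------------------------------


class GaussHermite:
    """Tensor-product Gauss-Hermite rule for Gaussian expectations.

    For eta ~ N(mu, L L') the integral of f is approximated by
    sum_k w_k f(mu + sqrt(2) L x_k) with physicists' nodes x_k and
    normalized log-weights ``logw``.
    """

    def __init__(self, n_points: int, n_dim: int):
        if n_points < 1:
            raise ValueError("need at least one quadrature node per dimension")
        x, w = np.polynomial.hermite.hermgauss(n_points)
        logw1 = np.log(w) - 0.5 * math.log(math.pi)
        if n_dim == 1:
            self.nodes = x[:, None]
            self.logw = logw1
        else:
            grids = np.meshgrid(*([x] * n_dim), indexing="ij")
            self.nodes = np.stack([g.ravel() for g in grids], axis=1)
            lw = np.meshgrid(*([logw1] * n_dim), indexing="ij")
            self.logw = sum(g.ravel() for g in lw)
        self.n_points = n_points
        self.n_dim = n_dim

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


# ---------------------------------------------------------------------------
# Design arrays
# ---------------------------------------------------------------------------


class SurveyDesign:
    """Numeric arrays extracted from a survey dataset for one model spec.

    Derived receipt covariates: ``const`` is a column of ones and ``female``
    an indicator of gender == 'female'; all other covariate names must be
    columns of the person table.  Indicator codes are stored 1..M_j with 0
    marking a missing response.
    """

    def __init__(self, data, spec: ModelSpec):
        df = data.df if hasattr(data, "df") else data
        self.spec = spec
        self.n = len(df)
        self.Zs = df[list(spec.structural_covariates)].to_numpy(dtype=float)
        self.Zr = np.column_stack(
            [self._receipt_column(df, name) for name in spec.receipt_covariates]
        ) if spec.receipt_covariates else np.empty((self.n, 0))
        codes = np.zeros((self.n, len(spec.indicators)), dtype=np.int64)
        for j, ind in enumerate(spec.indicators):
            col = pd.to_numeric(df[ind.name], errors="coerce").to_numpy(dtype=float)
            c = np.where(np.isnan(col), 0, col).astype(np.int64)
            codes[:, j] = c
        self.codes = codes
        self.receipt = df["receipt"].to_numpy(dtype=np.int64)
        self.weights = (
            df["weight"].to_numpy(dtype=float) if "weight" in df else np.ones(self.n)
        )
        gender = df["gender"].astype(str).to_numpy() if "gender" in df else None
        if spec.gender_specific_measurement:
            if gender is None:
                raise ModelSpecError("gender-specific measurement requires a gender column")
            self.group_rows = {
                "male": np.flatnonzero(gender == "male"),
                "female": np.flatnonzero(gender == "female"),
            }
        else:
            self.group_rows = {"all": np.arange(self.n)}
        hh = df["household_id"] if "household_id" in df else pd.Series(np.arange(self.n))
        self.household = pd.factorize(hh)[0]

    @staticmethod
    def _receipt_column(df: pd.DataFrame, name: str) -> np.ndarray:
        if name == "const":
            return np.ones(len(df))
        if name == "female" and "female" not in df:
            return (df["gender"].astype(str) == "female").to_numpy(dtype=float)
        return df[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Likelihood core
# ---------------------------------------------------------------------------


def _cell_logprob(u_up: np.ndarray, u_lo: np.ndarray):
    """log P, phi(u_up), phi(u_lo), P for an ordered-probit cell.

    ``u_up``/``u_lo`` are the standardized upper/lower cut residuals
    (A_m - lambda'eta); at the extreme categories one of them is +/-inf.
    """
    p_up = ndtr(u_up)
    p_lo = ndtr(u_lo)
    p = p_up - p_lo
    # mirror for upper-tail cells, where the direct difference cancels
    far = (u_up + u_lo) > 0
    if np.any(far):
        p = np.where(far, ndtr(-u_lo) - ndtr(-u_up), p)
    p = np.clip(p, 1e-300, 1.0)
    with np.errstate(over="ignore"):
        pdf_up = np.where(np.isinf(u_up), 0.0, np.exp(-0.5 * np.square(u_up)) / math.sqrt(2 * math.pi))
        pdf_lo = np.where(np.isinf(u_lo), 0.0, np.exp(-0.5 * np.square(u_lo)) / math.sqrt(2 * math.pi))
    return np.log(p), pdf_up, pdf_lo, p


def loglik_components(
    design: SurveyDesign,
    pset: ParameterSet,
    quad: GaussHermite,
    include_receipt: bool = True,
    want_score: bool = False,
    pmz: Parameterization | None = None,
):
    """Per-person marginal log-likelihood and (optionally) analytic scores.

    Returns ``(ll, scores, post)`` where ``ll`` is ``(n,)``, ``scores`` is
    ``(n, P)`` over ``pmz``'s free parameters (or None), and ``post`` holds
    the posterior node weights and node values of eta for factor scoring.
    Missing indicator responses are omitted from the likelihood product.
    """
    spec = design.spec
    pset.validate(spec)
    n, q_dim = design.n, spec.n_factors
    n_nodes = quad.n_nodes
    mu = design.Zs @ pset.theta.T  # (n, Q)
    shift = _SQRT2 * quad.nodes @ pset.chol.T  # (K, Q)
    logint = np.tile(quad.logw, (n, 1))

    # cached pieces for the score pass
    cache_ind = []  # (group, rows, j, g_v, d_up, d_lo)
    eta_by_group: dict[str, np.ndarray] = {}
    g_r_by_group: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    for g, rows in design.group_rows.items():
        if rows.size == 0:
            continue
        eta = mu[rows, None, :] + shift[None, :, :]  # (ng, K, Q)
        eta_by_group[g] = eta
        lam_g = pset.loadings[g]
        thr_g = pset.thresholds[g]
        for j, ind in enumerate(spec.indicators):
            c = design.codes[rows, j]
            obs = c > 0
            if not np.any(obs):
                continue
            v = eta @ lam_g[j]  # (ng, K)
            thr = thr_g[j]
            up_t = np.append(thr, np.inf)[np.maximum(c, 1) - 1]
            lo_t = np.append(-np.inf, thr)[np.maximum(c, 1) - 1]
            u_up = up_t[:, None] - v
            u_lo = lo_t[:, None] - v
            logp, pdf_up, pdf_lo, p = _cell_logprob(u_up, u_lo)
            logp[~obs] = 0.0
            logint[rows] += logp
            if want_score:
                d_up = np.where(obs[:, None], pdf_up / p, 0.0)
                d_lo = np.where(obs[:, None], pdf_lo / p, 0.0)
                cache_ind.append((g, rows, j, d_lo - d_up, d_up, d_lo, c))
        if include_receipt:
            sign = (2 * design.receipt[rows] - 1).astype(float)
            idx = (design.Zr[rows] @ pset.beta)[:, None] + eta @ pset.gamma
            su = sign[:, None] * idx
            lr = log_ndtr(su)
            logint[rows] += lr
            if want_score:
                log_pdf = -0.5 * np.square(su) - _LOG_SQRT_2PI
                g_r = sign[:, None] * np.exp(log_pdf - lr)
                g_r_by_group[g] = (rows, g_r)

    ll = logsumexp(logint, axis=1)
    post_w = np.exp(logint - ll[:, None])  # (n, K)

    scores = None
    if want_score:
        if pmz is None:
            pmz = Parameterization(spec)
        scores = _assemble_scores(
            design, pset, quad, pmz, post_w, cache_ind, eta_by_group, g_r_by_group
        )
    post = {"weights": post_w, "eta_by_group": eta_by_group, "mu": mu}
    return ll, scores, post


def _assemble_scores(design, pset, quad, pmz, post_w, cache_ind, eta_by_group, g_r_by_group):
    spec = design.spec
    n, q_dim = design.n, spec.n_factors
    J = len(spec.indicators)
    s_load = {g: np.zeros((n, J, q_dim)) for g in design.group_rows}
    s_thr = {
        g: [np.zeros((n, ind.n_categories - 1)) for ind in spec.indicators]
        for g in design.group_rows
    }
    # dll/d(mu_q) accumulator per group, for theta and chol scores
    g_mu = {g: None for g in design.group_rows}

    for g, rows, j, g_v, d_up, d_lo, c in cache_ind:
        pw = post_w[rows]
        eta = eta_by_group[g]
        lam_j = pset.loadings[g][j]
        # loadings
        for q in spec.indicators[j].loads_on:
            s_load[g][rows, j, q] = np.sum(pw * g_v * eta[:, :, q], axis=1)
        # thresholds: code m has upper cut m (if m < M), lower cut m-1 (if m > 1)
        m_codes = c
        w_up = np.sum(pw * d_up, axis=1)
        w_lo = np.sum(pw * d_lo, axis=1)
        n_thr = spec.indicators[j].n_categories - 1
        for m in range(1, spec.indicators[j].n_categories + 1):
            sel = m_codes == m
            if not np.any(sel):
                continue
            if m <= n_thr:
                s_thr[g][j][rows[sel], m - 1] += w_up[sel]
            if m >= 2:
                s_thr[g][j][rows[sel], m - 2] -= w_lo[sel]
        # accumulate dll/d(v_j) * lambda_jq into g_mu below via G
        gm = g_mu[g]
        if gm is None:
            gm = np.zeros(eta.shape)  # (ng, K, Q)
            g_mu[g] = gm
        for q in spec.indicators[j].loads_on:
            gm[:, :, q] += g_v * lam_j[q]

    s_beta = np.zeros((n, len(spec.receipt_covariates)))
    s_gamma = np.zeros((n, q_dim))
    for g, (rows, g_r) in g_r_by_group.items():
        pw = post_w[rows]
        eta = eta_by_group[g]
        s_idx = np.sum(pw * g_r, axis=1)
        s_beta[rows] = s_idx[:, None] * design.Zr[rows]
        for q in range(q_dim):
            s_gamma[rows, q] = np.sum(pw * g_r * eta[:, :, q], axis=1)
        gm = g_mu[g]
        if gm is None:
            gm = np.zeros(eta.shape)
            g_mu[g] = gm
        gm += g_r[:, :, None] * pset.gamma[None, None, :]

    # theta / chol scores from dll/d eta at nodes
    s_mu = np.zeros((n, q_dim))
    s_chol = np.zeros((n, q_dim, q_dim))
    for g, rows in design.group_rows.items():
        gm = g_mu[g]
        if gm is None or rows.size == 0:
            continue
        pw = post_w[rows]
        s_mu[rows] = np.einsum("ik,ikq->iq", pw, gm)
        # d eta_a / d L_ab = sqrt(2) x_b
        s_chol[rows] = _SQRT2 * np.einsum("ik,ika,kb->iab", pw, gm, quad.nodes)

    # project onto the free-parameter layout
    out = np.zeros((n, pmz.n_free))
    for i, e in enumerate(pmz.entries):
        if e.kind == "loading":
            g, j, q = e.loc
            out[:, i] = s_load[g][:, j, q]
        elif e.kind == "threshold":
            g, j, m = e.loc
            out[:, i] = s_thr[g][j][:, m]
        elif e.kind == "theta":
            q, s = e.loc
            out[:, i] = s_mu[:, q] * design.Zs[:, s]
        elif e.kind == "sigma2":
            out[:, i] = s_chol[:, 0, 0] / (2.0 * pset.chol[0, 0])
        elif e.kind in ("chol_diag", "chol_off"):
            out[:, i] = s_chol[:, e.loc[0], e.loc[1]]
        elif e.kind == "rho":
            rho = pset.chol[1, 0]
            root = math.sqrt(max(1.0 - rho * rho, 1e-12))
            out[:, i] = s_chol[:, 1, 0] - s_chol[:, 1, 1] * (rho / root)
        elif e.kind == "beta":
            out[:, i] = s_beta[:, e.loc[0]]
        else:
            out[:, i] = s_gamma[:, e.loc[0]]
    return out


# ---------------------------------------------------------------------------
# Public probability / likelihood operations
# ---------------------------------------------------------------------------


def indicator_category_prob(
    spec: ModelSpec,
    pset: ParameterSet,
    indicator: str,
    m: int,
    eta: np.ndarray,
    group: str | None = None,
) -> float:
    """P(D_j = m | eta) = Phi(A_jm - lambda_j'eta) - Phi(A_j,m-1 - lambda_j'eta)."""
    g = group or spec.groups[0]
    j = spec.indicator_names.index(indicator)
    ind = spec.indicators[j]
    if not 1 <= m <= ind.n_categories:
        raise ValueError(f"category {m} outside 1..{ind.n_categories}")
    thr = pset.thresholds[g][j]
    if np.any(np.diff(thr) <= 0):
        raise ParameterError(f"indicator {indicator!r}: thresholds not increasing")
    v = float(np.dot(pset.loadings[g][j], np.atleast_1d(eta)))
    up = thr[m - 1] if m <= len(thr) else np.inf
    lo = thr[m - 2] if m >= 2 else -np.inf
    return float(ndtr(up - v) - ndtr(lo - v))


def receipt_prob(spec: ModelSpec, pset: ParameterSet, eta: np.ndarray, z: np.ndarray) -> float:
    """P(R = 1 | eta, Z) = Phi(beta'Z + gamma'eta)."""
    idx = float(np.dot(pset.beta, np.asarray(z, dtype=float))) + float(
        np.dot(pset.gamma, np.atleast_1d(eta))
    )
    return float(ndtr(idx))


def person_loglik(row, spec: ModelSpec, pset: ParameterSet, quad: GaussHermite) -> float:
    """Marginal log-likelihood of one person's (D, R) given Z."""
    df = row if isinstance(row, pd.DataFrame) else pd.DataFrame([row])
    design = SurveyDesign(df, spec)
    ll, _, _ = loglik_components(design, pset, quad)
    return float(ll[0])


def sample_loglik(data, spec: ModelSpec, pset: ParameterSet, quad: GaussHermite) -> float:
    """Weighted sample log-likelihood sum_i w_i * loglik_i."""
    design = data if isinstance(data, SurveyDesign) else SurveyDesign(data, spec)
    if design.n == 0:
        return 0.0
    ll, _, _ = loglik_components(design, pset, quad)
    return float(np.dot(design.weights, ll))
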