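"""Mahalanobis one-to-one nearest-neighbour matching without replacement.

Used to standardize sample composition before re-fitting the model: each
base-survey respondent is matched to the nearest unused donor-survey
respondent in Mahalanobis distance over the shared SES variables, subject to
a caliper; with tight calipers this is equivalent in practice to exact
matching on binary variables.  Balance is diagnosed with standardized mean
differences and unequal-variance t-tests, and pairs with extreme within-pair
differences on a chosen variable (typically income) can be trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

__all__ = [
    "MatchResult",
    "pooled_covariance",
    "mahalanobis_distance",
    "match_samples",
    "trim_pairs",
    "balance_tests",
]


class SingularMetricError(ValueError):
    """The matching-variable covariance is singular (collinear variables)."""


@dataclass
class MatchResult:
    """Matched pairs with distances and diagnostics."""

    pairs: pd.DataFrame  # base_id, donor_id, distance, base_idx, donor_idx
    caliper: float
    variables: list[str]
    unmatched_base: list
    balance: pd.DataFrame | None = None
    trim_rule: tuple[str, float] | None = None

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def assert_valid(self) -> None:
        donors = self.pairs["donor_idx"]
        if donors.duplicated().any():
            raise AssertionError("a donor was reused (matching is without replacement)")
        if self.pairs["base_idx"].duplicated().any():
            raise AssertionError("duplicate base rows in the pairing")
        if (self.pairs["distance"] > self.caliper + 1e-12).any():
            raise AssertionError("a pair exceeds the caliper")


def _matching_matrix(data, variables: list[str]) -> np.ndarray:
    df = data.df if hasattr(data, "df") else data
    cols = []
    for v in variables:
        if v == "female" and "female" not in df:
            cols.append((df["gender"].astype(str) == "female").to_numpy(dtype=float))
        else:
            cols.append(df[v].to_numpy(dtype=float))
    return np.column_stack(cols)


def pooled_covariance(base_x: np.ndarray, donor_x: np.ndarray, variables=None) -> np.ndarray:
    """Sample covariance of the row-stacked matching variables.

    Raises :class:`SingularMetricError` naming the offending variables when
    the stacked covariance is singular.
    """
    stacked = np.vstack([np.atleast_2d(base_x), np.atleast_2d(donor_x)])
    if stacked.shape[0] < 2:
        raise ValueError("need at least two rows to form a covariance")
    cov = np.cov(stacked, rowvar=False)
    cov = np.atleast_2d(cov)
    names = list(variables) if variables is not None else [
        f"x{i + 1}" for i in range(cov.shape[0])
    ]
    zero_var = [names[i] for i in range(cov.shape[0]) if cov[i, i] <= 1e-12]
    if zero_var:
        raise SingularMetricError(f"constant matching variables: {', '.join(zero_var)}")
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        raise SingularMetricError(f"collinear matching variables among: {', '.join(names)}")
    return cov


def mahalanobis_distance(x: np.ndarray, y: np.ndarray, s: np.ndarray) -> float:
    """sqrt((x - y)' S^{-1} (x - y)); S must be positive definite."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    try:
        l = np.linalg.cholesky(np.atleast_2d(s))
    except np.linalg.LinAlgError as exc:
        raise SingularMetricError("metric matrix is not positive definite") from exc
    z = np.linalg.solve(l, d)
    return float(np.sqrt(z @ z))


def match_samples(
    base,
    donor,
    variables: list[str],
    caliper: float,
    shuffle_seed: int | None = None,
) -> MatchResult:
    """Greedy one-to-one nearest-neighbour matching without replacement.

    Base rows are processed in input order (or a seeded shuffle); each takes
    the nearest unused donor within the caliper, ties broken by lowest donor
    row index.  Deterministic given the inputs.
    """
    if caliper <= 0:
        raise ValueError("caliper must be positive")
    xb = _matching_matrix(base, variables)
    xd = _matching_matrix(donor, variables)
    base_df = base.df if hasattr(base, "df") else base
    donor_df = donor.df if hasattr(donor, "df") else donor
    base_ids = base_df["person_id"].to_numpy() if "person_id" in base_df else np.arange(len(base_df))
    donor_ids = donor_df["person_id"].to_numpy() if "person_id" in donor_df else np.arange(len(donor_df))

    if xd.shape[0] == 0:
        import warnings

        warnings.warn("empty donor pool: no base rows matched", RuntimeWarning, stacklevel=2)
        return MatchResult(
            pairs=pd.DataFrame(
                columns=["base_id", "donor_id", "distance", "base_idx", "donor_idx"]
            ),
            caliper=caliper,
            variables=list(variables),
            unmatched_base=list(base_ids),
        )

    cov = pooled_covariance(xb, xd, variables)
    l = np.linalg.cholesky(cov)
    # whiten once; Mahalanobis distance becomes Euclidean distance
    wb = np.linalg.solve(l, xb.T).T
    wd = np.linalg.solve(l, xd.T).T

    order = np.arange(len(wb))
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(order)

    used = np.zeros(len(wd), dtype=bool)
    rows = []
    unmatched = []
    for i in order:
        d2 = np.sum((wd - wb[i]) ** 2, axis=1)
        d2[used] = np.inf
        j = int(np.argmin(d2))
        dist = float(np.sqrt(d2[j]))
        if dist <= caliper:
            used[j] = True
            rows.append((base_ids[i], donor_ids[j], dist, int(i), j))
        else:
            unmatched.append(base_ids[i])
    pairs = pd.DataFrame(
        rows, columns=["base_id", "donor_id", "distance", "base_idx", "donor_idx"]
    )
    result = MatchResult(
        pairs=pairs, caliper=caliper, variables=list(variables), unmatched_base=unmatched
    )
    result.assert_valid()
    return result


def trim_pairs(result: MatchResult, base, donor, variable: str, top_pct: float) -> MatchResult:
    """Drop the pairs with the largest within-pair differences on ``variable``.

    Ceiling semantics: with n pairs, the ceil(n * top_pct / 100) largest
    absolute differences are targeted, and a pair is dropped only when its
    difference is strictly above the largest retained one — so fully tied
    differences are never trimmed.
    """
    if not 0.0 < top_pct < 100.0:
        raise ValueError("top_pct must be in (0, 100)")
    base_df = base.df if hasattr(base, "df") else base
    donor_df = donor.df if hasattr(donor, "df") else donor
    if variable not in base_df or variable not in donor_df:
        raise KeyError(variable)
    if result.pairs.empty:
        return result
    vb = base_df[variable].to_numpy(dtype=float)[result.pairs["base_idx"]]
    vd = donor_df[variable].to_numpy(dtype=float)[result.pairs["donor_idx"]]
    diffs = np.abs(vb - vd)
    n = len(diffs)
    k = int(np.ceil(n * top_pct / 100.0))
    ordered = np.sort(diffs)
    threshold = ordered[n - k - 1] if k < n else -np.inf
    keep = diffs <= threshold
    trimmed = replace(
        result,
        pairs=result.pairs[keep].reset_index(drop=True),
        trim_rule=(variable, top_pct),
    )
    trimmed.assert_valid()
    return trimmed


def balance_tests(result: MatchResult, base, donor, variables: list[str]) -> MatchResult:
    """Pre/post-match means, standardized differences and Welch t-tests.

    Standardized differences divide the mean gap by the pooled pre-match SD;
    t statistics compare the matched base and donor samples.  A constant
    variable yields a zero standardized difference by convention.
    """
    if result.pairs.empty:
        raise ValueError("cannot diagnose balance for an empty match result")
    xb = _matching_matrix(base, variables)
    xd = _matching_matrix(donor, variables)
    bi = result.pairs["base_idx"].to_numpy()
    di = result.pairs["donor_idx"].to_numpy()
    rows = []
    for k, v in enumerate(variables):
        pre_sd = np.sqrt(0.5 * (xb[:, k].var(ddof=1) + xd[:, k].var(ddof=1)))
        mb_pre, md_pre = xb[:, k].mean(), xd[:, k].mean()
        mb_post, md_post = xb[bi, k].mean(), xd[di, k].mean()
        if pre_sd > 0:
            smd_pre = (mb_pre - md_pre) / pre_sd
            smd_post = (mb_post - md_post) / pre_sd
        else:
            smd_pre = smd_post = 0.0
        if np.var(xb[bi, k]) + np.var(xd[di, k]) > 0:
            t, p = ttest_ind(xb[bi, k], xd[di, k], equal_var=False)
        else:
            t, p = 0.0, 1.0
        rows.append(
            {
                "variable": v,
                "mean_base_pre": mb_pre,
                "mean_donor_pre": md_pre,
                "mean_base_post": mb_post,
                "mean_donor_post": md_post,
                "smd_pre": smd_pre,
                "smd_post": smd_post,
                "t": float(t),
                "p": float(p),
            }
        )
    result.balance = pd.DataFrame(rows)
    return result
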