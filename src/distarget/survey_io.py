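"""Survey data schema, readers/writers, covariate derivation and pipeline.

A survey extract is a delimited person table (one row per respondent) with
columns ``person_id``, ``household_id``, ``gender``, ``receipt``, optional
``weight``, the declared indicator columns (ordinal codes 1..M_j, blank when
missing) and the raw SES covariates.  Spline covariates are derived on load:
each source column ``x`` with knot ``k`` yields ``x_below = min(x, k)`` and
``x_above = max(x - k, 0)``, so that ``x_below + x_above = x``.  The model
configuration is a YAML file declaring factors, indicators, covariate roles,
normalization and spline knots.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import IndicatorSpec, ModelSpec

__all__ = [
    "SchemaError",
    "ValidationError",
    "PipelineOrderError",
    "SplineBasis",
    "SurveyDataset",
    "build_spline_basis",
    "add_derived_covariates",
    "load_survey",
    "write_survey",
    "load_model_spec",
    "save_model_spec",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_ID_COLUMNS = ("person_id", "household_id", "gender", "receipt")


class SchemaError(ValueError):
    """A declared column is missing from the person table."""


class ValidationError(ValueError):
    """A value violates the schema (e.g. indicator code out of range)."""


class PipelineOrderError(RuntimeError):
    """A pipeline stage was requested before its prerequisite stage."""


@dataclass(frozen=True)
class SplineBasis:
    """Piecewise-linear basis of x at one knot: (min(x, knot), max(x-knot, 0))."""

    knot: float
    below: float
    above: float


def build_spline_basis(x: float, knot: float) -> SplineBasis:
    if not np.isfinite(knot):
        raise ValueError("spline knot must be finite")
    return SplineBasis(knot=knot, below=min(x, knot), above=max(x - knot, 0.0))


def add_derived_covariates(df: pd.DataFrame, splines: dict[str, float]) -> pd.DataFrame:
    """Add spline columns and the female dummy in place (and return df)."""
    for source, knot in splines.items():
        x = df[source].to_numpy(dtype=float)
        base = source.replace("logincome", "income").replace("log_income", "income")
        df[f"{base}_below"] = np.minimum(x, knot)
        df[f"{base}_above"] = np.maximum(x - knot, 0.0)
    if "gender" in df and "female" not in df:
        df["female"] = (df["gender"].astype(str) == "female").astype(float)
    return df


@dataclass
class SurveyDataset:
    """Validated person-level survey extract."""

    label: str
    df: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_households(self) -> int:
        return int(self.df["household_id"].nunique())

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(self.label, self.df.copy())


def _validate(df: pd.DataFrame, spec: ModelSpec, label: str) -> pd.DataFrame:
    for col in _ID_COLUMNS:
        if col not in df:
            raise SchemaError(f"{label}: missing required column {col!r}")
    for ind in spec.indicators:
        if ind.name not in df:
            raise SchemaError(f"{label}: missing indicator column {ind.name!r}")
    raw_covs = set(spec.splines) | {
        c
        for c in set(spec.structural_covariates) | set(spec.receipt_covariates)
        if c not in ("const", "female") and not c.endswith("_below") and not c.endswith("_above")
    }
    for col in raw_covs:
        if col not in df:
            raise SchemaError(f"{label}: missing covariate column {col!r}")

    if df["receipt"].isna().any():
        n_drop = int(df["receipt"].isna().sum())
        logger.info("%s: dropped %d rows with missing receipt", label, n_drop)
        df = df[df["receipt"].notna()].copy()
    ind_names = list(spec.indicator_names)
    ind_block = df[ind_names].apply(pd.to_numeric, errors="coerce")
    all_missing = ind_block.isna().all(axis=1)
    if all_missing.any():
        logger.info(
            "%s: dropped %d rows with all indicators missing", label, int(all_missing.sum())
        )
        df = df[~all_missing].copy()
        ind_block = ind_block[~all_missing]
    for ind in spec.indicators:
        col = ind_block[ind.name]
        obs = col.dropna()
        bad = obs[(obs < 1) | (obs > ind.n_categories) | (obs != obs.round())]
        if len(bad):
            rid = df.loc[bad.index[0], "person_id"]
            raise ValidationError(
                f"{label}: indicator {ind.name!r} code {bad.iloc[0]!r} outside "
                f"1..{ind.n_categories} (person {rid})"
            )
    if "weight" not in df:
        df = df.copy()
        df["weight"] = 1.0
    elif (df["weight"] <= 0).any():
        raise ValidationError(f"{label}: weights must be positive")
    return df


def load_survey(table_path, spec: ModelSpec, label: str | None = None) -> SurveyDataset:
    """Read and validate a delimited person table against a model spec.

    Rows with missing receipt or with every indicator missing are dropped
    (counts logged); rows with some missing indicators are retained and
    handled by likelihood omission.
    """
    path = Path(table_path)
    df = pd.read_csv(path, sep=None, engine="python")
    name = label or spec.survey_label or path.stem
    df = _validate(df, spec, name)
    add_derived_covariates(df, spec.splines)
    return SurveyDataset(label=name, df=df.reset_index(drop=True))


def write_survey(data: SurveyDataset, path) -> None:
    data.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model configuration (YAML)
# ---------------------------------------------------------------------------


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "survey": spec.survey_label,
        "factors": spec.n_factors,
        "normalization": spec.normalization,
        "gender_specific_measurement": spec.gender_specific_measurement,
        "indicators": [
            {
                "name": ind.name,
                "categories": ind.n_categories,
                "loads_on": [q + 1 for q in ind.loads_on],
                **({"anchor_for": ind.anchor_for + 1} if ind.anchor_for is not None else {}),
                **({"proxy_flag": True} if ind.is_proxy_flag else {}),
            }
            for ind in spec.indicators
        ],
        "splines": dict(spec.splines),
        "structural_covariates": list(spec.structural_covariates),
        "receipt_covariates": list(spec.receipt_covariates),
    }


def spec_from_dict(d: dict) -> ModelSpec:
    indicators = tuple(
        IndicatorSpec(
            name=item["name"],
            n_categories=int(item.get("categories", 2)),
            loads_on=tuple(q - 1 for q in item.get("loads_on", [1])),
            anchor_for=(item["anchor_for"] - 1) if "anchor_for" in item else None,
            is_proxy_flag=bool(item.get("proxy_flag", False)),
        )
        for item in d["indicators"]
    )
    return ModelSpec(
        survey_label=d.get("survey", "survey"),
        n_factors=int(d.get("factors", 1)),
        indicators=indicators,
        structural_covariates=tuple(d["structural_covariates"]),
        receipt_covariates=tuple(d["receipt_covariates"]),
        normalization=d.get("normalization", "anchor_loading"),
        gender_specific_measurement=bool(d.get("gender_specific_measurement", False)),
        splines={k: float(v) for k, v in d.get("splines", {}).items()},
    )


def load_model_spec(path) -> ModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def save_model_spec(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config, out_dir) -> dict:
    """Run the configured stages and write report tables.

    ``config`` is a YAML path or an already-parsed mapping with keys:

    - ``seed``: master seed for synthetic generation;
    - ``surveys``: list of ``{label, table, config}`` (file inputs) or
      ``{label, synthetic: {template, n_households, ...}}`` blocks;
    - ``stages``: subset of ``[fit, compare, match, matched_refit,
      targeting]`` in any order (prerequisites enforced);
    - optional ``fit``, ``match``, ``targeting`` option blocks.

    Outputs per-survey coefficient tables, pairwise equality-test tables,
    matched-sample results and targeting-curve data as CSV plus a JSON run
    metadata file; byte-identical across reruns with the same config.
    """
    from . import estimation, inference, matching as matching_mod
    from .synthetic import GeneratorConfig, generate_survey

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ["fit"]))
    known = {"fit", "compare", "match", "matched_refit", "targeting"}
    for st in stages:
        if st not in known:
            raise ValueError(f"unknown pipeline stage {st!r}")
    needs = {
        "compare": "fit",
        "targeting": "fit",
        "matched_refit": "match",
    }
    for st, pre in needs.items():
        if st in stages and pre not in stages:
            raise PipelineOrderError(f"stage {st!r} requires stage {pre!r}")

    seed = int(config.get("seed", 0))
    fit_block = config.get("fit", {})
    quad_points = int(fit_block.get("quadrature_points", 21))

    datasets: dict[str, SurveyDataset] = {}
    specs: dict[str, ModelSpec] = {}
    for k, block in enumerate(config["surveys"]):
        label = block.get("label", f"survey{k + 1}")
        if "synthetic" in block:
            from .synthetic import make_survey_template

            syn = dict(block["synthetic"])
            template = syn.pop("template", "frs_like")
            gen = GeneratorConfig(
                survey_template=template, seed=seed + k, **syn
            )
            data, spec, _ = generate_survey(gen)
            data.label = label
        else:
            spec = load_model_spec(block["config"])
            data = load_survey(block["table"], spec, label=label)
        datasets[label] = data
        specs[label] = spec

    meta = {"seed": seed, "stages": stages, "surveys": {}}
    fits: dict[str, estimation.FitResult] = {}
    if "fit" in stages:
        for label, data in datasets.items():
            fit = estimation.fit_model(
                data, specs[label], estimation.FitOptions(quadrature_points=quad_points)
            )
            fits[label] = fit
            fit.coef_table().to_csv(out / f"fit_{label}.csv")
            meta["surveys"][label] = {
                "n_persons": fit.n_persons,
                "n_households": fit.n_households,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "converged": fit.converged,
            }

    labels = list(datasets)
    if "compare" in stages:
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                common = [
                    n
                    for n in fits[a].param_names
                    if n in fits[b].param_names
                    and (n.startswith("theta:") or n.startswith("beta:") or n.startswith("gamma:"))
                ]
                res = inference.wald_equality_test(fits[a], fits[b], common)
                res.table.to_csv(out / f"compare_{a}_vs_{b}.csv")
                rows.append(
                    {
                        "pair": f"{a}-{b}",
                        "wald": res.wald,
                        "df": res.df,
                        "p": res.p_value,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "compare_joint.csv", index=False)

    match_results = {}
    if "match" in stages:
        mblock = config.get("match", {})
        variables = mblock.get(
            "variables", ["age", "female", "education", "partner", "owner", "logincome"]
        )
        caliper = float(mblock.get("caliper", 0.1))
        base_label = mblock.get("base", labels[0])
        for other in labels:
            if other == base_label:
                continue
            res = matching_mod.match_samples(
                datasets[base_label], datasets[other], variables, caliper
            )
            res = matching_mod.balance_tests(
                res, datasets[base_label], datasets[other], variables
            )
            res.pairs.to_csv(out / f"match_{base_label}_{other}_pairs.csv", index=False)
            res.balance.to_csv(out / f"match_{base_label}_{other}_balance.csv", index=False)
            match_results[other] = res

    if "matched_refit" in stages:
        for other, res in match_results.items():
            matched = SurveyDataset(
                label=f"{other}_matched",
                df=datasets[other].df.iloc[res.pairs["donor_idx"].to_numpy()].reset_index(drop=True),
            )
            fit = estimation.fit_model(
                matched, specs[other], estimation.FitOptions(quadrature_points=quad_points)
            )
            fit.coef_table().to_csv(out / f"fit_{other}_matched.csv")

    if "targeting" in stages:
        tblock = config.get("targeting", {})
        bandwidth = float(tblock.get("bandwidth", 0.4))
        for label, data in datasets.items():
            scores = inference.posterior_disability_scores(
                data, specs[label], fits[label].estimates, quad_points=quad_points
            )
            curve = inference.targeting_curve(
                scores[:, 0], data.df["receipt"].to_numpy(), bandwidth=bandwidth
            )
            curve.curve.to_csv(out / f"targeting_{label}_curve.csv", index=False)
            curve.deciles.to_csv(out / f"targeting_{label}_deciles.csv", index=False)

    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return meta
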