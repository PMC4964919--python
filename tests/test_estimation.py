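"""Completeness, starting values, ML fitting and the cluster sandwich."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import distarget as dt
from distarget.estimation import (
    IdentificationError,
    check_completeness,
    cluster_robust_vcov,
    starting_values,
)
from distarget.model import GaussHermite, Parameterization, SurveyDesign, loglik_components


def _spec_with_pattern(pattern, normalization="unit_variance"):
    q = len(pattern[0])
    indicators = tuple(
        dt.IndicatorSpec(f"i{j}", 2, tuple(k for k, v in enumerate(row) if v))
        for j, row in enumerate(pattern)
    )
    return dt.ModelSpec(
        survey_label="toy",
        n_factors=q,
        indicators=indicators,
        structural_covariates=("x",),
        receipt_covariates=("const",),
        normalization=normalization,
    )


class TestCompleteness:
    def test_single_factor_complete(self):
        assert check_completeness(_spec_with_pattern([(1,), (1,)])).complete

    def test_unspanned_factor_detected(self):
        res = check_completeness(_spec_with_pattern([(1, 0), (1, 0), (1, 0)]))
        assert not res.complete
        assert res.offending_factor == 2

    def test_cross_loading_pattern_complete(self):
        res = check_completeness(
            _spec_with_pattern([(1, 0), (1, 0), (0, 1), (0, 1), (1, 1)])
        )
        assert res.complete and res.rank == 2

    def test_fit_refuses_incomplete_spec(self, small_survey):
        spec = dt.make_survey_template("frs_like")
        bad = dt.ModelSpec(
            survey_label="bad",
            n_factors=2,
            indicators=tuple(
                dt.IndicatorSpec(i.name, i.n_categories, (0,), anchor_for=i.anchor_for)
                for i in spec.indicators
            ),
            structural_covariates=spec.structural_covariates,
            receipt_covariates=spec.receipt_covariates,
            normalization="unit_variance",
            splines=spec.splines,
        )
        with pytest.raises(IdentificationError):
            dt.fit_model(small_survey, bad)


def _single_item_spec(n_categories=2):
    return dt.ModelSpec(
        survey_label="toy",
        n_factors=1,
        indicators=(dt.IndicatorSpec("item", n_categories, (0,)),),
        structural_covariates=("x",),
        receipt_covariates=("const",),
        normalization="unit_variance",
    )


class TestStartingValues:
    def _dataset(self, codes, spec):
        n = len(codes)
        df = pd.DataFrame(
            {
                "person_id": [f"p{i}" for i in range(n)],
                "household_id": [f"h{i}" for i in range(n)],
                "gender": "female",
                "receipt": 0,
                "x": 0.0,
                "item": codes,
            }
        )
        return dt.SurveyDataset("s", df)

    def test_even_split_gives_zero_threshold(self):
        spec = _single_item_spec()
        data = self._dataset([1] * 50 + [2] * 50, spec)
        sv = starting_values(data, spec)
        assert sv.thresholds["all"][0][0] == pytest.approx(0.0, abs=1e-12)

    def test_cumulative_frequency_maps_through_probit(self):
        spec = _single_item_spec()
        data = self._dataset([1] * 8413 + [2] * 1587, spec)
        sv = starting_values(data, spec)
        assert sv.thresholds["all"][0][0] == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_indicator_clipped_with_warning(self, caplog):
        spec = _single_item_spec()
        data = self._dataset([1] * 30, spec)
        with caplog.at_level("WARNING"):
            sv = starting_values(data, spec)
        assert sv.thresholds["all"][0][0] == pytest.approx(norm.ppf(0.999))
        assert any("empty category" in m for m in caplog.messages)


class TestFit:
    def test_factorized_fit_matches_independent_oracles(self, small_survey):
        """Pinning all loadings and gamma at zero decouples the equations:
        thresholds saturate the marginal multinomials and beta is a plain
        probit, so the joint loglik must equal the sum of the separate MLEs."""
        statsmodels = pytest.importorskip("statsmodels.api")
        spec = dt.make_survey_template("frs_like", normalization="unit_variance")
        data = dt.SurveyDataset("f", small_survey.df.head(400).copy())
        fixed = {f"loading:all:{n}:1": 0.0 for n in spec.indicator_names}
        fixed["gamma:1"] = 0.0
        fit = dt.fit_model(
            data, spec, dt.FitOptions(quadrature_points=5, fixed=fixed, gtol=1e-9,
                                      compute_vcov=False)
        )
        design = SurveyDesign(data, spec)
        expected = 0.0
        for j, ind in enumerate(spec.indicators):
            c = design.codes[:, j]
            c = c[c > 0]
            counts = np.bincount(c, minlength=ind.n_categories + 1)[1:]
            counts = counts[counts > 0]
            expected += float(np.sum(counts * np.log(counts / c.size)))
        # rescale the non-constant columns for statsmodels' optimizer; the
        # probit log-likelihood is invariant to this reparameterization
        zr = design.Zr.copy()
        scale = np.where(zr.std(axis=0) > 0, zr.std(axis=0), 1.0)
        center = np.where(zr.std(axis=0) > 0, zr.mean(axis=0), 0.0)
        probit = statsmodels.Probit(design.receipt, (zr - center) / scale).fit(
            disp=0, method="newton", maxiter=100
        )
        expected += float(probit.llf)
        assert fit.loglik == pytest.approx(expected, abs=1e-6)

    def test_refit_from_solution_takes_no_steps(self, small_fit, small_survey, frs_spec):
        refit = dt.fit_model(
            small_survey,
            frs_spec,
            dt.FitOptions(quadrature_points=11, start=small_fit.estimates, compute_vcov=False),
        )
        assert refit.iterations <= 1
        assert refit.loglik == pytest.approx(small_fit.loglik, abs=1e-6)

    def test_aic_identity(self, small_fit):
        assert small_fit.aic == pytest.approx(
            -2 * small_fit.loglik + 2 * small_fit.n_free, rel=1e-12
        )

    def test_coef_table_shape(self, small_fit):
        tab = small_fit.coef_table()
        assert list(tab.columns) == ["estimate", "se_robust", "z", "p"]
        assert len(tab) == small_fit.n_free
        assert np.all(tab["se_robust"] > 0)


class TestClusterRobustVcov:
    def test_singleton_households_equal_heteroskedastic_sandwich(
        self, small_survey, frs_spec, small_fit
    ):
        """With one person per household the clustered meat is the plain
        outer-product-of-scores meat."""
        df = small_survey.df.copy()
        df["household_id"] = df["person_id"]  # break households apart
        singles = dt.SurveyDataset("s", df)
        v_cluster = cluster_robust_vcov(small_fit, singles)

        design = SurveyDesign(singles, frs_spec)
        pmz = Parameterization(frs_spec)
        quad = GaussHermite(small_fit.quadrature_points, 1)
        _, scores, _ = loglik_components(
            design, small_fit.estimates, quad, want_score=True, pmz=pmz
        )
        g = design.n
        meat_hc = scores.T @ scores * g / (g - 1)
        meat_cl = np.zeros_like(meat_hc)
        hh = design.household
        sums = np.zeros((hh.max() + 1, scores.shape[1]))
        np.add.at(sums, hh, scores)
        meat_cl = sums.T @ sums * g / (g - 1)
        assert np.allclose(meat_hc, meat_cl, rtol=1e-10)
        assert v_cluster.shape == (small_fit.n_free, small_fit.n_free)
        assert np.allclose(v_cluster, v_cluster.T)

    def test_duplicated_households_inflate_ses(self, small_survey, frs_spec, small_fit):
        """Cloning every person into a 2-member household of identical twins
        doubles the information nominally but not effectively; clustered SEs
        must exceed the singleton-clustered ones."""
        df = small_survey.df.head(400).copy()
        twin = df.copy()
        twin["person_id"] = twin["person_id"] + "_t"
        both = pd.concat([df, twin], ignore_index=True)
        both["household_id"] = np.tile(df["person_id"].to_numpy(), 2)
        clustered = dt.SurveyDataset("c", both)
        solo = both.copy()
        solo["household_id"] = solo["person_id"]
        singles = dt.SurveyDataset("s", solo)
        v_cl = cluster_robust_vcov(small_fit, clustered)
        v_sg = cluster_robust_vcov(small_fit, singles)
        assert np.all(np.diag(v_cl) > np.diag(v_sg))

    def test_meat_person_loop_equals_household_groupby(self, small_survey, frs_spec, small_fit):
        design = SurveyDesign(small_survey, frs_spec)
        pmz = Parameterization(frs_spec)
        quad = GaussHermite(small_fit.quadrature_points, 1)
        _, scores, _ = loglik_components(
            design, small_fit.estimates, quad, want_score=True, pmz=pmz
        )
        hh = design.household
        sums = np.zeros((hh.max() + 1, scores.shape[1]))
        np.add.at(sums, hh, scores)
        meat_vec = sums.T @ sums
        grouped = (
            pd.DataFrame(scores).groupby(hh).sum().to_numpy()
        )
        meat_grp = grouped.T @ grouped
        assert np.allclose(meat_vec, meat_grp, rtol=1e-12)


def test_household_effect_motivates_clustering(frs_spec):
    """A shared household intercept in nu induces intra-household correlation;
    clustered SEs should then exceed the naive singleton ones for most
    parameters."""
    cfg = dt.GeneratorConfig(
        n_households=500, couple_fraction=1.0, household_effect_sd=1.2, seed=9
    )
    data, spec, truth = dt.generate_survey(cfg)
    fit = dt.fit_model(data, spec, dt.FitOptions(quadrature_points=11))
    df = data.df.copy()
    df["household_id"] = df["person_id"]
    v_single = cluster_robust_vcov(fit, dt.SurveyDataset("s", df))
    ratio = np.diag(fit.vcov_robust) / np.diag(v_single)
    assert np.median(ratio) > 1.0
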