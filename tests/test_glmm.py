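"""Design construction, mixed-model fitting, LRTs and predictions."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import batpass as bp
from batpass.design import DESIGN_COLUMNS, ModelSpec, NightRecord, build_design
from batpass.glmm import (
    TERM_DROPS,
    _laplace_loglik,
    marginal_loglik_quadrature,
    nb1_logpmf,
    overdispersion_ratio,
    rnb1,
)
from batpass.studydata import highway_study_betas

from conftest import toy_records


def survey_records(seed=0, sigma=0.0, phi=1.0, beta=None, small=True):
    if beta is None:
        beta = tuple(highway_study_betas()["all"])
    cfg_kw = dict(seed=seed)
    if small:
        cfg_kw.update(
            site_transects=(("DOED", 2), ("HAYW", 1), ("SAPA", 2)),
            total_nights=45, n_calendar_nights=12, n_light_points=2,
        )
    model = bp.TrueModel(beta=tuple(beta), sigma_night=sigma,
                         sigma_transect=sigma, phi=phi)
    return bp.simulate_survey(
        bp.SurveyConfig(**cfg_kw), model, emit_streams=False
    ).records


class TestDesignMatrix:
    def test_full_design_has_14_columns_in_order(self):
        df = survey_records(seed=1)
        design = build_design(df, ModelSpec())
        assert design.X.shape == (len(df), 14)
        assert design.columns == DESIGN_COLUMNS

    def test_reference_row_maps_to_intercept_alone(self):
        rec = NightRecord(site="HAYW", transect="T", dist_road=300,
                          night_id="n", year=2010, temp_max=24.0,
                          light_100=False, count=0)
        design = build_design([rec], ModelSpec())
        x = design.X[0]
        # 300 m + 24 C zero the distance and temperature columns
        assert x[0] == 1.0
        np.testing.assert_array_equal(x[1:6], 0.0)

    def test_contrast_codes(self):
        recs = [
            NightRecord(site=s, transect="T", dist_road=d, night_id="n",
                        year=y, temp_max=27.0, light_100=l, count=0)
            for s, d, y, l in [
                ("SAPA", 100, 2010, False),
                ("DOED", 0, 2011, True),
                ("HAYW", 300, 2010, False),
            ]
        ]
        X = build_design(recs, ModelSpec()).X
        # site sum contrasts: SAPA=(1,0), DOED=(0,1), HAYW=(-1,-1)
        np.testing.assert_array_equal(X[:, 6], [1, 0, -1])
        np.testing.assert_array_equal(X[:, 7], [0, 1, -1])
        # year: 2010 adds, 2011 subtracts
        np.testing.assert_array_equal(X[:, 12], [1, -1, 1])
        # light: lit points subtract the coefficient
        np.testing.assert_array_equal(X[:, 13], [1, -1, 1])
        # treatment coding for distance, temperature centered at 24
        np.testing.assert_array_equal(X[:, 1], [1, 0, 0])
        np.testing.assert_array_equal(X[:, 2], [0, 1, 0])
        np.testing.assert_allclose(X[:, 3], 3.0)
        # interactions are products
        np.testing.assert_allclose(X[:, 4], X[:, 1] * X[:, 3])
        np.testing.assert_allclose(X[:, 9], X[:, 2] * X[:, 6])

    def test_sum_contrast_columns_balance(self):
        rows = []
        for s in ("DOED", "HAYW", "SAPA"):
            for y in (2010, 2011):
                for l in (False, True):
                    rows.append(
                        NightRecord(site=s, transect="T", dist_road=300,
                                    night_id="n", year=y, temp_max=24.0,
                                    light_100=l, count=0)
                    )
        X = build_design(rows, ModelSpec()).X
        for col in (6, 7, 12, 13):
            assert X[:, col].sum() == 0.0

    def test_unseen_levels_rejected(self):
        df = survey_records(seed=1).copy()
        df.loc[df.index[0], "site"] = "NOPE"
        with pytest.raises(ValueError, match="site"):
            build_design(df, ModelSpec())
        with pytest.raises(ValueError):
            NightRecord(site="DOED", transect="T", dist_road=50,
                        night_id="n", year=2010, temp_max=20.0,
                        light_100=False)


class TestFittingOracles:
    def test_intercept_only_closed_form(self):
        df = toy_records(counts=[7] * 18)
        spec = ModelSpec(columns=("intercept",), family="poisson")
        fit = bp.fit_poisson_glmm(df, spec, include_night=False,
                                  include_transect=False)
        assert fit.beta[0] == pytest.approx(np.log(7), abs=1e-4)

    def test_sigma_zero_poisson_matches_statsmodels(self):
        df = survey_records(seed=2)
        spec = ModelSpec()
        fit = bp.fit_poisson_glmm(df, spec, include_night=False,
                                  include_transect=False)
        X = build_design(df, spec).X
        oracle = sm.GLM(df["count"].to_numpy(), X,
                        family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, oracle.params, atol=2e-4)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-5)

    def test_sigma_zero_nb1_matches_statsmodels(self):
        df = survey_records(seed=3, phi=3.0)
        spec = ModelSpec()
        fit = bp.fit_nb1_glmm(df, spec, include_night=False,
                              include_transect=False)
        X = build_design(df, spec).X
        oracle = sm.NegativeBinomialP(
            df["count"].to_numpy(), X, p=1
        ).fit(disp=0, maxiter=200)
        np.testing.assert_allclose(fit.beta, oracle.params[:-1], atol=5e-3)
        assert fit.phi == pytest.approx(1.0 + oracle.params[-1], rel=0.01)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-3)

    def test_laplace_matches_quadrature_on_toys(self):
        df = toy_records(n_nights=3, seed=4)
        spec = ModelSpec(
            columns=("intercept", "dist_road_100", "dist_road_0",
                     "temp_max", "year", "light")
        )
        design = build_design(df, spec)
        y = design.y
        beta = np.zeros(6)
        beta[0] = np.log(30)
        for family in ("poisson", "nb1"):
            for sn, st in [(0.1, 0.1), (0.3, 0.2)]:
                lap = _laplace_loglik(beta, sn, st, 2.0, design, y, family)
                quad = marginal_loglik_quadrature(
                    beta, sn, st, 2.0, design, y, family, order=11
                )
                assert lap == pytest.approx(quad, abs=0.02)

    def test_laplace_sigma_zero_limit_is_exact_loglik(self):
        df = toy_records(seed=5)
        design = build_design(df, ModelSpec(columns=("intercept",)))
        beta = np.array([np.log(30.0)])
        ll = _laplace_loglik(beta, None, None, 1.0, design, design.y,
                             "poisson")
        exact = stats.poisson.logpmf(
            design.y, np.exp(design.X @ beta)
        ).sum()
        assert ll == pytest.approx(exact, abs=1e-10)

    def test_nb1_loglik_tends_to_poisson_as_phi_to_one(self):
        df = toy_records(seed=6)
        design = build_design(df, ModelSpec(columns=("intercept",)))
        beta = np.array([np.log(30.0)])
        y = design.y
        ll_pois = _laplace_loglik(beta, 0.2, 0.2, 1.0, design, y, "poisson")
        ll_nb1 = _laplace_loglik(beta, 0.2, 0.2, 1.0 + 1e-6, design, y, "nb1")
        assert ll_nb1 == pytest.approx(ll_pois, abs=1e-4)
        # the pmf itself converges too
        np.testing.assert_allclose(
            nb1_logpmf(y, 30.0, 1.0 + 1e-8),
            stats.poisson.logpmf(y, 30.0),
            atol=1e-5,
        )

    def test_poisson_beta_recovery_sigma_zero(self):
        truth = highway_study_betas()["all"].to_numpy()
        df = survey_records(seed=7, sigma=0.0, phi=1.0, small=False)
        fit = bp.fit_poisson_glmm(df, include_night=False,
                                  include_transect=False)
        # Poisson counts at study scale pin the main coefficients tightly
        assert fit.beta[0] == pytest.approx(truth[0], abs=0.1)
        assert fit.beta[2] == pytest.approx(truth[2], abs=0.15)

    def test_degenerate_grouping_shrinks_sigmas(self):
        rng = np.random.default_rng(8)
        rows = [
            dict(site="DOED", transect="T1", dist_road=d, night_id="n1",
                 year=2010, temp_max=24.0, light_100=False,
                 count=int(rng.poisson(20)))
            for d in (0, 100, 300) for _ in range(8)
        ]
        spec = ModelSpec(
            columns=("intercept", "dist_road_100", "dist_road_0")
        )
        fit = bp.fit_poisson_glmm(pd.DataFrame(rows), spec)
        assert fit.sigma_night < 0.1
        assert fit.sigma_transect < 0.1


class TestDispersionDiagnostics:
    def test_perfect_fit_gives_zero_ratio(self):
        df = toy_records(counts=[9] * 18)
        spec = ModelSpec(columns=("intercept",), family="poisson")
        fit = bp.fit_poisson_glmm(df, spec, include_night=False,
                                  include_transect=False)
        assert overdispersion_ratio(fit) == pytest.approx(0.0, abs=1e-4)

    def test_ratio_tracks_nb1_dispersion(self):
        # Poisson fit on NB1 counts: Pearson ratio estimates phi
        rng = np.random.default_rng(7)
        for phi, tol in ((1.0, 0.15), (4.0, 0.6)):
            df = toy_records(
                n_nights=80,
                counts=rnb1(np.full(480, 25.0), phi, rng).tolist(),
            )
            spec = ModelSpec(columns=("intercept",), family="poisson")
            fit = bp.fit_poisson_glmm(df, spec, include_night=False,
                                      include_transect=False)
            assert overdispersion_ratio(fit) == pytest.approx(phi, abs=tol)

    def test_no_residual_dof_is_an_error(self):
        df = toy_records(n_nights=1).iloc[:1]
        spec = ModelSpec(columns=("intercept",), family="poisson")
        fit = bp.fit_poisson_glmm(df, spec, include_night=False,
                                  include_transect=False)
        with pytest.raises(ValueError, match="degrees of freedom"):
            overdispersion_ratio(fit)


class TestLikelihoodRatioTests:
    @pytest.mark.parametrize(
        "term, df_expected",
        [
            ("dist_road", 8),       # 2 direct + 2 temp + 4 site interactions
            ("temp_max", 3),
            ("dist_road:temp_max", 2),
            ("site", 6),
            ("dist_road:site", 4),
            ("year", 1),
            ("light", 1),
        ],
    )
    def test_reduction_rules_column_accounting(self, term, df_expected):
        assert len(TERM_DROPS[term]) == df_expected
        assert set(TERM_DROPS[term]) <= set(DESIGN_COLUMNS)

    def test_one_df_test_behaves(self):
        df = survey_records(seed=10, phi=2.0)
        fit = bp.fit_nb1_glmm(df, include_night=False, include_transect=False)
        # refit is reproducible, so a model tested against itself is null
        same = bp.fit_nb1_glmm(df, include_night=False,
                               include_transect=False)
        assert abs(same.loglik - fit.loglik) < 1e-6
        res = bp.lrt(fit, bp.fit_nb1_glmm(
            df, drop_columns=("light",), include_night=False,
            include_transect=False), term="light")
        assert res.df == 1
        assert res.statistic >= 0.0
        assert 0.0 <= res.p_value <= 1.0

    def test_strong_effect_detected(self):
        # data carry a large distance effect: the 8-df LRT must reject
        df = survey_records(seed=11, phi=2.0)
        full = bp.fit_nb1_glmm(df, include_night=False,
                               include_transect=False)
        res = bp.lrt_term(df, term="dist_road", full=full,
                          include_night=False, include_transect=False)
        assert res.df == 8
        assert res.p_value < 0.01
        assert res.stars == "**"

    def test_non_nested_rejected(self):
        df = survey_records(seed=12)
        a = bp.fit_nb1_glmm(df, drop_columns=("year",),
                            include_night=False, include_transect=False)
        b = bp.fit_nb1_glmm(df, drop_columns=("light",),
                            include_night=False, include_transect=False)
        with pytest.raises(ValueError, match="not nested"):
            bp.lrt(a, b)


class TestPredictions:
    def test_zero_beta_predicts_one_pass(self):
        beta = np.zeros(14)
        for dist in (0, 100, 300):
            assert bp.predict_activity(beta, dist) == 1.0

    def test_level_arithmetic_follows_contrasts(self):
        betas = highway_study_betas()["all"]
        b = betas.to_numpy()
        base = bp.predict_activity(b, 300)
        assert base == pytest.approx(np.exp(betas["intercept"]))
        # San Pablo Bay adds site1; Don Edwards adds site2; Hayward
        # subtracts both
        assert bp.predict_activity(b, 300, site="SAPA") == pytest.approx(
            np.exp(betas["intercept"] + betas["site1"])
        )
        assert bp.predict_activity(b, 300, site="DOED") == pytest.approx(
            np.exp(betas["intercept"] + betas["site2"])
        )
        assert bp.predict_activity(b, 300, site="HAYW") == pytest.approx(
            np.exp(betas["intercept"] - betas["site1"] - betas["site2"])
        )
        # 2010 adds year, 2011 subtracts; lit points subtract light
        assert bp.predict_activity(b, 300, year=2010) == pytest.approx(
            np.exp(betas["intercept"] + betas["year"])
        )
        assert bp.predict_activity(b, 300, light=True) == pytest.approx(
            np.exp(betas["intercept"] - betas["light"])
        )
        # distance levels add their coefficients and interactions
        assert bp.predict_activity(b, 0, site="SAPA") == pytest.approx(
            np.exp(betas["intercept"] + betas["dist_road_0"]
                   + betas["site1"] + betas["dist_road_0:site1"])
        )
        # temperature enters centered
        assert bp.predict_activity(b, 300, temp_c=30.0) == pytest.approx(
            np.exp(betas["intercept"] + 6 * betas["temp_max"])
        )

    def test_unknown_levels_rejected(self):
        beta = np.zeros(14)
        with pytest.raises(ValueError):
            bp.predict_activity(beta, 200)
        with pytest.raises(ValueError):
            bp.predict_activity(beta, 0, site="XX")

    def test_road_effect_ratio(self):
        b = highway_study_betas()["all"].to_numpy()
        ratio = bp.predict_activity(b, 300) / bp.predict_activity(b, 0)
        # roadside activity is about half the 300 m level
        assert ratio == pytest.approx(np.exp(0.6853), rel=1e-12)
        assert 1.8 < ratio < 2.2


class TestFitAllModels:
    def test_species_inclusion_rules(self):
        df = survey_records(seed=13, phi=2.0)
        sparse = df.copy()
        sparse["count"] = (sparse["count"] > df["count"].median()).astype(int)
        responses = {"all": df, "RARE": sparse, "MYXX": df}
        fits, coef, lrt_table, excluded = bp.fit_all_models(
            responses, min_passes=500, excluded_species=("MYXX",),
            terms=("year",), include_night=False, include_transect=False,
        )
        assert "all" in fits
        assert "RARE" in excluded and "500" in excluded["RARE"]
        assert excluded["MYXX"] == "on exclusion list"
        assert set(lrt_table["response"]) == set(fits)
        assert coef.shape[0] == 14


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript unavailable")
def test_nb1_glmm_matches_glmmtmb(tmp_path):
    """Independent cross-check of the crossed-effects NB1 fit against
    glmmTMB's nbinom1 family with identical contrasts."""
    truth = bp.TrueModel(beta=tuple(highway_study_betas()["all"]),
                         sigma_night=0.3, sigma_transect=0.3, phi=3.0)
    sv = bp.simulate_survey(bp.SurveyConfig(seed=1000), truth,
                            emit_streams=False)
    fit = bp.fit_nb1_glmm(sv.records)
    csv = tmp_path / "d.csv"
    sv.records.assign(temp_c=sv.records.temp_max - 24,
                      y=sv.records["count"]).to_csv(csv, index=False)
    rscript = f"""
    suppressMessages(library(glmmTMB))
    d <- read.csv("{csv}")
    d$dist_road <- relevel(factor(d$dist_road), ref="300")
    d$site <- factor(d$site, levels=c("DOED","HAYW","SAPA"))
    d$yearf <- factor(d$year, levels=c(2010,2011))
    d$light <- factor(d$light_100, levels=c("False","True"))
    contrasts(d$site) <- matrix(c(0,-1,1, 1,-1,0), ncol=2,
        dimnames=list(c("DOED","HAYW","SAPA"), c("s1","s2")))
    contrasts(d$yearf) <- matrix(c(1,-1), ncol=1,
        dimnames=list(c("2010","2011"), "y"))
    contrasts(d$light) <- matrix(c(1,-1), ncol=1,
        dimnames=list(c("False","True"), "l"))
    m <- glmmTMB(y ~ dist_road*temp_c + dist_road*site + yearf + light
                 + (1|night_id) + (1|transect), family=nbinom1, data=d)
    co <- summary(m)$coefficients$cond[,1]
    cat(co["(Intercept)"], co["dist_road0"], co["dist_road100"],
        as.numeric(logLik(m)), 1+sigma(m), "\\n")
    """
    out = subprocess.run(
        ["Rscript", "-"], input=rscript, capture_output=True, text=True,
        timeout=300,
    )
    assert out.returncode == 0, out.stderr
    vals = [float(x) for x in out.stdout.split()[-5:]]
    r_int, r_d0, r_d100, r_ll, r_phi = vals
    c = fit.coef()
    assert c["intercept"] == pytest.approx(r_int, abs=5e-3)
    assert c["dist_road_0"] == pytest.approx(r_d0, abs=5e-3)
    assert c["dist_road_100"] == pytest.approx(r_d100, abs=5e-3)
    assert fit.loglik == pytest.approx(r_ll, abs=5e-3)
    assert fit.phi == pytest.approx(r_phi, abs=0.05)
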