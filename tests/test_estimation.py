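"""Likelihood machinery: joint density, Laplace quality, LRT, SCM, bootstrap."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

import lactpk as lp
from lactpk.estimation import (
    CovariateEffect,
    FitSettings,
    _Engine,
    _dofv_threshold,
)
from lactpk.pk_model import MGL_TO_NGML


def _one_subject_table(seed=0, n_obs=6):
    rng = np.random.default_rng(seed)
    times = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 4.0])
    matrices = ["plasma"] * 5 + ["milk"]
    dv = rng.uniform(50, 900, n_obs)
    return pd.DataFrame({
        "ID": 1, "ARM": "q24", "GROUP": "morning", "VISIT": 1,
        "MATRIX": matrices, "TIME": times[:n_obs], "DV": dv,
        "BLQ": 0, "MDV": 0, "DOSE": 300.0, "TAU": 24.0, "LLOQ": 5.0,
        "WT": 64.0, "AGE": 30.0, "BMI": 24.8, "CRCL": 134.6,
        "VDAY": 13.0, "IWT": 3.6,
    })


def _naive_joint_neg2ll(table, model, eta):
    """Independent reference implementation: plain loops + scipy.stats."""
    params = lp.individual_params(model.theta, eta)
    ll = 0.0
    for _, r in table.iterrows():
        reg = lp.DoseRegimen(r["DOSE"], r["TAU"])
        fn = lp.milk_conc if r["MATRIX"] == "milk" else lp.plasma_conc
        pred_mgl = fn(params, reg, r["TIME"]) / MGL_TO_NGML
        sigma = model.sigma_milk if r["MATRIX"] == "milk" else model.sigma_plasma
        sd = max(pred_mgl * sigma, 1e-6)
        ll += stats.norm.logpdf(r["DV"] / MGL_TO_NGML, pred_mgl, sd)
    ll += stats.multivariate_normal.logpdf(eta, np.zeros(3), model.omega)
    return -2.0 * ll


class TestJointDensity:
    @pytest.mark.parametrize("draw", range(4))
    def test_matches_naive_reference_implementation(self, ref_model, draw):
        rng = np.random.default_rng(50 + draw)
        table = _one_subject_table(seed=draw)
        eta = rng.normal(0, 0.4, 3)
        got = lp.individual_joint_neg2ll(table, ref_model, eta)
        want = _naive_joint_neg2ll(table, ref_model, eta)
        assert got == pytest.approx(want, abs=1e-9)

    def test_zero_omega_marginal_equals_fixed_effect_loglik(self, small_study,
                                                            ref_model):
        m0 = lp.PopulationModel(ref_model.theta, np.zeros((3, 3)),
                                ref_model.sigma_plasma, ref_model.sigma_milk)
        ofv = lp.marginal_neg2ll(small_study, m0)
        want = _fixed_effect_neg2ll(small_study, m0)
        assert ofv == pytest.approx(want, abs=1e-9)

    def test_huge_residual_variance_makes_mode_ignore_the_data(self, ref_model):
        # as sigma -> infinity the observations stop informing eta: the
        # conditional mode becomes a function of the prior and variance
        # structure only, so scaling the data tenfold must not move it
        big = lp.PopulationModel(ref_model.theta, ref_model.omega, 1e4, 1e4)
        table = _one_subject_table()
        eng_a = _Engine(table, big, FitSettings())
        eng_a.objective(eng_a.pack_init())
        scaled = table.assign(DV=table["DV"] * 10.0)
        eng_b = _Engine(scaled, big, FitSettings())
        eng_b.objective(eng_b.pack_init())
        assert np.allclose(eng_a.eta, eng_b.eta, atol=1e-3)


def _fixed_effect_neg2ll(table, model):
    tot = 0.0
    mat = table[(table["MATRIX"].isin(("plasma", "milk"))) & (table["MDV"] == 0)
                & (table["BLQ"] == 0)]
    for _, r in mat.iterrows():
        reg = lp.DoseRegimen(r["DOSE"], r["TAU"])
        fn = lp.milk_conc if r["MATRIX"] == "milk" else lp.plasma_conc
        pred = fn(model.theta, reg, r["TIME"]) / MGL_TO_NGML
        sigma = model.sigma_milk if r["MATRIX"] == "milk" else model.sigma_plasma
        sd = max(pred * sigma, 1e-6)
        tot += -2.0 * stats.norm.logpdf(r["DV"] / MGL_TO_NGML, pred, sd)
    return tot


class TestLaplaceQuality:
    def test_one_eta_toy_agrees_with_gauss_hermite(self, ref_model):
        """Laplace OFV within 0.1 of 32-node adaptive quadrature."""
        table = _one_subject_table(seed=3)
        m1 = lp.PopulationModel.from_cv(ref_model.theta, 0.209, 1e-10, 1e-10,
                                        0.0, 0.383, 0.305)
        st = FitSettings(iiv_on=("CL",), corr_clvc=False)
        ofv_lap = lp.marginal_neg2ll(table, m1, st)

        eng = _Engine(table, m1, st)
        th, Om, sp, sm, b = eng.unpack(eng.pack_init())

        def joint(e):
            return eng.joint_neg2ll(th, Om, sp, sm, b, np.array([[e]]))[0]

        from scipy.optimize import minimize_scalar

        mode = minimize_scalar(joint, bounds=(-3, 3), method="bounded",
                               options={"xatol": 1e-10}).x
        h = 1e-5
        curv = (joint(mode + h) - 2 * joint(mode) + joint(mode - h)) / h**2
        scale = np.sqrt(2.0 / curv)
        nodes, wts = np.polynomial.hermite.hermgauss(32)
        vals = np.array([joint(mode + np.sqrt(2) * scale * z) for z in nodes])
        log_terms = -0.5 * vals + np.log(wts) + nodes**2 + np.log(np.sqrt(2) * scale)
        ofv_agh = -2.0 * logsumexp(log_terms)
        assert ofv_lap == pytest.approx(ofv_agh, abs=0.1)

    def test_ofv_minimised_near_generating_parameters(self, default_study,
                                                      ref_model):
        at_truth = lp.marginal_neg2ll(default_study, ref_model)
        for factor in (0.5, 1.5):
            shifted = lp.PopulationModel(
                ref_model.theta.replace(cl=ref_model.theta.cl * factor),
                ref_model.omega, ref_model.sigma_plasma, ref_model.sigma_milk)
            assert lp.marginal_neg2ll(default_study, shifted) > at_truth

    def test_foce_variant_runs_and_matches_laplace_roughly(self, small_study,
                                                           ref_model):
        lap = lp.marginal_neg2ll(small_study, ref_model)
        foce = lp.marginal_neg2ll(small_study, ref_model,
                                  FitSettings(approximation="foce"))
        assert np.isfinite(foce)
        assert abs(foce - lap) < 0.05 * abs(lap) + 10.0

    def test_censored_likelihood_m3_uses_blq_records(self, small_study, ref_model):
        censored = lp.censor_blq(small_study, 200.0, 200.0)
        m1 = lp.marginal_neg2ll(censored, ref_model, FitSettings(blq="M1"))
        m3 = lp.marginal_neg2ll(censored, ref_model, FitSettings(blq="M3"))
        assert np.isfinite(m3) and m3 > m1  # extra (negative-log) terms


class TestLikelihoodRatioTest:
    def test_conventional_threshold_is_significant_at_boundary(self):
        res = lp.lrt(100.0, 96.16, df=1)
        assert res.delta_ofv == pytest.approx(3.84)
        assert res.p_value == pytest.approx(0.05, abs=0.001)
        assert res.significant

    def test_no_improvement_gives_p_one(self):
        assert lp.lrt(50.0, 50.0, df=1).p_value == 1.0

    def test_chi2_oracle_at_one_percent(self):
        res = lp.lrt(10.0, 3.37, df=1)
        assert res.p_value == pytest.approx(stats.chi2.sf(6.63, 1), rel=1e-12)
        assert res.p_value == pytest.approx(0.01, abs=0.0005)

    def test_negative_delta_warns_and_is_not_significant(self):
        res = lp.lrt(10.0, 12.0, df=1)
        assert res.p_value == 1.0 and not res.significant
        assert res.warning is not None

    def test_thresholds_match_chi2_quantiles(self):
        assert _dofv_threshold(0.05, 1) == 3.84
        assert _dofv_threshold(0.01, 1) == 6.63
        assert _dofv_threshold(0.05, 2) == pytest.approx(5.99, abs=0.01)


def _plasma_only_study(seed, n=12, beta_crcl=0.0):
    """Small one-visit plasma-only study for covariate-search tests.

    When `beta_crcl` is nonzero the data are regenerated from scratch
    with a true power covariate relation CL_i = theta_CL * (CRCL/med)^beta
    on top of the log-normal random effect.
    """
    design = lp.StudyDesign(n_q12=0, n_q24=n, n_morning=n, missingness=0.0)
    theta = lp.StructuralParams(1.87, 19.4, 184.0, 0.245, 1.77)
    model = lp.PopulationModel.from_cv(theta, 0.209, 1e-4, 1e-4, 0.0, 0.25, 0.25)
    tab = lp.simulate_study(design, model, seed=seed)
    tab = tab[(tab["MATRIX"] == "plasma") & (tab["VISIT"] == 1)].reset_index(drop=True)
    if beta_crcl:
        rng = np.random.default_rng(77_000 + seed)
        med = tab.groupby("ID")["CRCL"].first().median()
        for sid, rows in tab.groupby("ID"):
            crcl = rows["CRCL"].iloc[0]
            cl_i = theta.cl * (crcl / med) ** beta_crcl * np.exp(rng.normal(0, 0.209))
            p_i = theta.replace(cl=cl_i)
            reg = lp.DoseRegimen(rows["DOSE"].iloc[0], rows["TAU"].iloc[0])
            pred = lp.plasma_conc(p_i, reg, rows["TIME"].to_numpy())
            tab.loc[rows.index, "DV"] = np.maximum(
                pred * (1 + 0.25 * rng.standard_normal(len(rows))), 0.0)
    return tab


_SCM_SETTINGS = FitSettings(iiv_on=("CL",), corr_clvc=False,
                            fix_theta=frozenset({"Kcb", "Rcb"}))
_SCM_MODEL = lp.PopulationModel.from_cv(
    lp.StructuralParams(1.87, 19.4, 184.0, 0.245, 1.77),
    0.209, 1e-4, 1e-4, 0.0, 0.25, 0.25)


class TestStepwiseCovariateModelling:
    def test_candidate_without_iiv_is_a_configuration_error(self, small_study,
                                                            ref_model):
        with pytest.raises(lp.ParameterError):
            lp.scm(small_study, [CovariateEffect("Vc", "WT", "power")],
                   ref_model, FitSettings(iiv_on=("CL",), corr_clvc=False))

    def test_strong_crcl_effect_on_cl_is_detected(self):
        # n=40 mothers: the covariate explains enough of the CL variance
        # for the forward-inclusion threshold with margin
        tab = _plasma_only_study(seed=31, n=40, beta_crcl=0.75)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = lp.scm(tab, [CovariateEffect("CL", "CRCL", "power")],
                         _SCM_MODEL, _SCM_SETTINGS)
        assert [(e.covariate, e.parameter) for e in res.selected] == [("CRCL", "CL")]
        # the narrow CRCL range makes beta noisy (SE ~ 0.25); sign and
        # broad magnitude are the meaningful checks here
        beta = res.selected[0].coefficient
        assert 0.2 < beta < 2.0
        assert (res.trace["decision"] == "included").any()
        assert (res.trace["decision"] == "retained").any()

    def test_null_data_keeps_base_model(self):
        tab = _plasma_only_study(seed=32, beta_crcl=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = lp.scm(tab, [CovariateEffect("CL", "CRCL", "power")],
                         _SCM_MODEL, _SCM_SETTINGS)
        assert res.selected == ()


class TestBootstrap:
    def test_default_resample_count_is_one_thousand(self):
        import inspect

        sig = inspect.signature(lp.bootstrap)
        assert sig.parameters["n_resamples"].default == 1000

    def test_cloned_subjects_reproduce_point_estimates(self):
        one = _plasma_only_study(seed=33, n=1)
        clones = pd.concat(
            [one.assign(ID=i + 1) for i in range(6)], ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            point = lp.fit_model(clones, _SCM_MODEL, _SCM_SETTINGS)
            bs = lp.bootstrap(clones, _SCM_MODEL, n_resamples=3, seed=1,
                              settings=_SCM_SETTINGS)
        assert bs.n_failed == 0
        for par in ("CL", "Vc"):
            assert bs.table.loc[par, "median"] == pytest.approx(
                point.estimates[par], rel=1e-4)


class TestStandardErrors:
    def test_rse_reported_on_small_fit(self):
        from dataclasses import replace

        tab = _plasma_only_study(seed=34)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = lp.fit_model(tab, _SCM_MODEL,
                               replace(_SCM_SETTINGS, compute_se=True))
        assert fit.se_status == "ok"
        assert all(np.isfinite(v) for v in fit.rse.values())
        assert 0.5 < fit.rse["CL"] < 50.0
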