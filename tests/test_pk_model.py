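"""Closed-form structural model against independent oracles and identities."""

import numpy as np
import pytest
from scipy.integrate import quad

import lactpk as lp
from lactpk.pk_model import MGL_TO_NGML, conc_mgl

Q24 = lp.Q24_300
Q12 = lp.Q12_150


def _random_params(rng):
    """Log-uniform draw within one decade around the typical values."""
    base = np.array([1.87, 19.4, 184.0, 0.245, 1.77])
    vals = base * np.exp(rng.uniform(-np.log(10) / 2, np.log(10) / 2, 5))
    return lp.StructuralParams(*vals)


class TestClosedFormVsODE:
    @pytest.mark.parametrize("draw", range(5))
    def test_single_dose_matches_ode_oracle(self, draw):
        rng = np.random.default_rng(100 + draw)
        p = _random_params(rng)
        reg = lp.DoseRegimen(300.0, 24.0, steady_state=False, n_doses=1)
        t = np.linspace(0.05, 72.0, 120)
        ode = lp.integrate_odes(p, reg, t)
        cp = lp.plasma_conc(p, reg, t)
        cm = lp.milk_conc(p, reg, t)
        # relative 1e-6 with an absolute floor at 1e-8 of the peak (the ODE
        # oracle's own accuracy limits the deep washout tail)
        ref_p = np.maximum(ode["plasma"], 1e-8 * ode["plasma"].max())
        ref_m = np.maximum(ode["milk"], 1e-8 * ode["milk"].max())
        assert np.max(np.abs(cp - ode["plasma"]) / ref_p) < 1e-6
        assert np.max(np.abs(cm - ode["milk"]) / ref_m) < 1e-6

    def test_steady_state_superposition_matches_dose_train(self, typical_params):
        # after 20 q24h doses the last-interval profile is at steady state
        reg_train = lp.DoseRegimen(300.0, 24.0, steady_state=False, n_doses=20)
        toff = np.linspace(0.1, 23.9, 48)
        ode = lp.integrate_odes(typical_params, reg_train, 19 * 24.0 + toff)
        cp = lp.plasma_conc(typical_params, Q24, toff)
        cm = lp.milk_conc(typical_params, Q24, toff)
        assert np.max(np.abs(cp - ode["plasma"]) / ode["plasma"]) < 1e-3
        assert np.max(np.abs(cm - ode["milk"]) / ode["milk"]) < 1e-3

    def test_absorption_rate_equal_to_elimination_rate_is_handled(self):
        p = lp.StructuralParams(19.4 / 184.0, 19.4, 184.0, 0.245, 1.77)
        reg = lp.DoseRegimen(300.0, 24.0, steady_state=False)
        t = np.linspace(0.1, 48.0, 60)
        ode = lp.integrate_odes(p, reg, t)
        cp = lp.plasma_conc(p, reg, t)
        assert np.max(np.abs(cp - ode["plasma"]) / np.maximum(ode["plasma"], 1e-9)) < 1e-4

    def test_initial_condition_and_conservation(self, typical_params):
        reg = lp.DoseRegimen(300.0, 24.0, steady_state=False)
        out = lp.integrate_odes(typical_params, reg, np.array([0.0]))
        assert out["plasma"][0] == 0.0 and out["milk"][0] == 0.0


class TestSteadyStateIdentities:
    @pytest.mark.parametrize("reg", [Q24, Q12], ids=["q24", "q12"])
    @pytest.mark.parametrize("kcb", [0.01, 0.245, 10.0])
    def test_milk_to_plasma_auc_ratio_equals_rcb(self, typical_params, reg, kcb):
        p = typical_params.replace(kcb=kcb)
        auc_p = quad(lambda t: lp.plasma_conc(p, reg, t), 0, reg.tau, limit=300)[0]
        auc_m = quad(lambda t: lp.milk_conc(p, reg, t), 0, reg.tau, limit=300)[0]
        assert auc_m / auc_p == pytest.approx(p.rcb, rel=1e-6)

    def test_average_concentration_is_dose_over_cl_tau(self, typical_params):
        # independent of Ka and Vc
        for ka, vc in [(1.87, 184.0), (0.4, 60.0), (8.0, 400.0)]:
            p = typical_params.replace(ka=ka, vc=vc)
            auc = quad(lambda t: lp.plasma_conc(p, Q24, t), 0, 24, limit=300)[0]
            expect = Q24.dose / p.cl / 24.0 * MGL_TO_NGML
            assert auc / 24.0 == pytest.approx(expect, rel=1e-6)
        assert expect == pytest.approx(644.3, abs=0.05)

    def test_analytic_auc_agrees_with_quadrature(self, typical_params):
        for matrix, fn in (("plasma", lp.plasma_conc), ("milk", lp.milk_conc)):
            auc_q = quad(lambda t: fn(typical_params, Q24, t), 0, 24, limit=300)[0]
            assert lp.auc_tau_ss(typical_params, Q24, matrix) == pytest.approx(
                auc_q, rel=1e-6)


class TestShapeProperties:
    def test_time_of_maximum_matches_analytic_formula(self, typical_params):
        reg = lp.DoseRegimen(300.0, 24.0, steady_state=False)
        t = np.linspace(0.0, 12.0, 24001)
        c = lp.plasma_conc(typical_params, reg, t)
        ke = typical_params.ke
        tmax = np.log(typical_params.ka / ke) / (typical_params.ka - ke)
        assert t[np.argmax(c)] == pytest.approx(tmax, abs=1e-3)
        assert tmax == pytest.approx(1.63, abs=0.01)

    def test_milk_peaks_later_than_plasma(self, typical_params):
        t = np.linspace(0.0, 24.0, 4801)
        for kcb in (0.05, 0.245, 2.0, 50.0):
            p = typical_params.replace(kcb=kcb)
            tp = t[np.argmax(lp.plasma_conc(p, Q24, t))]
            tm = t[np.argmax(lp.milk_conc(p, Q24, t))]
            assert tm > tp

    def test_fast_equilibration_limit_tracks_plasma(self, typical_params):
        p = typical_params.replace(kcb=1e6)
        t = np.linspace(0.5, 23.5, 24)
        cm = lp.milk_conc(p, Q24, t)
        cp = lp.plasma_conc(p, Q24, t)
        assert np.allclose(cm, p.rcb * cp, rtol=1e-3)

    def test_milk_concentration_increases_with_rcb(self, typical_params):
        t = np.linspace(0.5, 23.5, 24)
        prev = lp.milk_conc(typical_params.replace(rcb=0.5), Q24, t)
        for rcb in (1.0, 1.77, 3.0):
            cur = lp.milk_conc(typical_params.replace(rcb=rcb), Q24, t)
            assert np.all(cur > prev)
            prev = cur

    def test_zero_dose_gives_zero_concentration(self, typical_params):
        reg = lp.DoseRegimen(0.0, 24.0)
        t = np.array([0.0, 1.0, 12.0])
        assert np.all(lp.plasma_conc(typical_params, reg, t) == 0.0)
        assert np.all(lp.milk_conc(typical_params, reg, t) == 0.0)


class TestRandomEffectsAndError:
    def test_zero_eta_returns_typical_values(self, typical_params):
        p = lp.individual_params(typical_params, np.zeros(3))
        assert p == typical_params

    def test_exponential_model_arithmetic(self, typical_params):
        p = lp.individual_params(typical_params, np.array([np.log(2), 0.0, 0.0]))
        assert p.cl == pytest.approx(38.8)
        assert p.vc == typical_params.vc and p.ka == typical_params.ka

    def test_sampled_cv_of_clearance_matches_iiv(self, ref_model):
        rng = np.random.default_rng(42)
        etas = ref_model.draw_etas(100_000, rng)
        cl = 19.4 * np.exp(etas[:, 0])
        cv = np.std(cl) / np.mean(cl)
        assert cv == pytest.approx(0.209, rel=0.02)

    def test_residual_error_moments_and_truncation(self):
        rng = np.random.default_rng(7)
        eps = rng.standard_normal(100_000)
        obs, blq = lp.apply_residual_error(100.0, "plasma", 0.383, eps)
        kept = obs[~blq] / 100.0 - 1.0
        # CV of accepted draws approximates sigma (truncation loses <0.5%)
        assert np.std(obs / 100.0) == pytest.approx(0.383, rel=0.03)
        assert np.all(obs >= 0)
        obs0, _ = lp.apply_residual_error(50.0, "milk", 0.0, eps)
        assert np.all(obs0 == 50.0)
        obsz, _ = lp.apply_residual_error(0.0, "plasma", 0.5, eps)
        assert np.all(obsz == 0.0)

    def test_unknown_matrix_rejected(self):
        with pytest.raises(lp.DataError):
            lp.apply_residual_error(1.0, "urine", 0.3, 0.0)

    @pytest.mark.parametrize("field", ["ka", "cl", "vc", "kcb", "rcb"])
    def test_nonpositive_parameters_rejected(self, field):
        kw = dict(ka=1.87, cl=19.4, vc=184.0, kcb=0.245, rcb=1.77)
        kw[field] = 0.0
        with pytest.raises(lp.ParameterError):
            lp.StructuralParams(**kw)

    def test_rcb_correlation_constraint_enforced(self):
        om = np.eye(3) * 0.04
        om[0, 2] = om[2, 0] = 0.01
        with pytest.raises(lp.ParameterError):
            lp.PopulationModel(lp.StructuralParams(1.87, 19.4, 184, 0.245, 1.77),
                               om, 0.3, 0.3)
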