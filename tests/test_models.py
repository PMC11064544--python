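"""Core model layer: covariate construction, steady-state closed forms,
residual error and variance transforms."""

import dataclasses
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from dlpk.models import (
    CovariateTerm,
    DoseRegimen,
    IndividualParameters,
    apply_residual_error,
    build_individual_params,
    covariate_effect_percent,
    css_one_compartment,
    css_two_compartment,
    iiv_percent_cv,
    load_model,
    percent_cv_to_omega2,
    save_model,
)


class TestIndividualParameterConstruction:
    def test_reference_subject_recovers_structural_values(self, dtg):
        p = build_individual_params(dtg.fixed, {"weight": 79, "bilirubin": 8, "ethnicity": 0})
        assert p.cl == pytest.approx(0.858)
        assert p.v2 == pytest.approx(16.7)
        assert p.ka == pytest.approx(2.15)

    def test_ethnicity_multiplier_on_clearance(self, dtg):
        p = build_individual_params(dtg.fixed, {"weight": 79, "bilirubin": 8, "ethnicity": 1})
        assert p.cl == pytest.approx(0.858 * 0.844)

    def test_lamivudine_reference_subject(self, ltc):
        p = build_individual_params(ltc.fixed, {"weight": 70, "egfr": 99, "race_black": 0})
        assert p.cl == pytest.approx(19.6)
        assert p.v2 == pytest.approx(105.0)
        assert p.v3 == pytest.approx(105.0)  # peripheral volume tied to central
        assert p.q == pytest.approx(2.97)

    def test_linear_allometry_on_central_volume(self, ltc):
        p = build_individual_params(ltc.fixed, {"weight": 153, "egfr": 99, "race_black": 0})
        assert p.v2 == pytest.approx(105.0 * 153 / 70)

    def test_eta_enters_exponentially(self, dtg):
        p = build_individual_params(
            dtg.fixed, {"weight": 79, "bilirubin": 8, "ethnicity": 0}, eta=[0.3, -0.2]
        )
        assert p.cl == pytest.approx(0.858 * np.exp(0.3))
        assert p.ruv_scale == pytest.approx(np.exp(-0.2))

    def test_unknown_covariate_and_nonpositive_value_raise(self, dtg):
        with pytest.raises(KeyError):
            build_individual_params(dtg.fixed, {"weight": 79, "ethnicity": 0})
        with pytest.raises(ValueError):
            build_individual_params(dtg.fixed, {"weight": -1, "bilirubin": 8, "ethnicity": 0})


class TestSteadyStateClosedForms:
    def test_one_compartment_auc_equals_dose_over_clearance(self, dtg):
        p = build_individual_params(dtg.fixed, {"weight": 79, "bilirubin": 8, "ethnicity": 0})
        auc = quad(lambda t: css_one_compartment(p, dtg.regimen, t), 0, 24, limit=200)[0]
        assert auc == pytest.approx(50 / 0.858, rel=1e-6)

    def test_two_compartment_auc_equals_dose_over_clearance(self, ltc):
        p = build_individual_params(ltc.fixed, {"weight": 70, "egfr": 99, "race_black": 0})
        auc = quad(lambda t: css_two_compartment(p, ltc.regimen, t), 0, 24, limit=400)[0]
        assert auc == pytest.approx(300 / 19.6, rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        cl=st.floats(0.1, 30.0),
        v=st.floats(5.0, 300.0),
        ka=st.floats(0.05, 8.0),
        t=st.floats(0.0, 24.0),
    )
    def test_periodicity_and_positivity(self, cl, v, ka, t):
        p = IndividualParameters(cl=cl, v2=v, ka=ka)
        reg = DoseRegimen(50.0, 24.0)
        c0 = css_one_compartment(p, reg, 0.0)
        ctau = css_one_compartment(p, reg, 24.0)
        assert ctau == pytest.approx(c0, rel=1e-9)
        c = css_one_compartment(p, reg, t)
        assert c >= 0
        # strictly positive whenever the trough is representable in floats
        if (cl / v) * 24.0 < 30 and ka * 24.0 < 30:
            assert c > 0

    def test_two_compartment_periodicity(self, ltc):
        p = build_individual_params(ltc.fixed, {"weight": 70, "egfr": 99, "race_black": 0})
        assert css_two_compartment(p, ltc.regimen, 0.0) == pytest.approx(
            css_two_compartment(p, ltc.regimen, 24.0), rel=1e-9
        )

    def test_two_compartment_matches_ode_to_periodicity(self, ltc):
        """Closed form vs a stiff ODE oracle integrated over 30 dosing intervals."""
        p = build_individual_params(ltc.fixed, {"weight": 70, "egfr": 99, "race_black": 0})
        k10, k23, k32 = p.cl / p.v2, p.q / p.v2, p.q / p.v3

        def rhs(t, y):
            a, c, per = y
            return [-p.ka * a, p.ka * a - (k10 + k23) * c + k32 * per, k23 * c - k32 * per]

        y = np.zeros(3)
        for _ in range(30):
            y[0] += 300.0
            y = solve_ivp(rhs, (0, 24), y, rtol=1e-11, atol=1e-13, method="LSODA").y[:, -1]
        y[0] += 300.0
        sol = solve_ivp(rhs, (0, 24), y, rtol=1e-11, atol=1e-13, method="LSODA", dense_output=True)
        grid = np.array([0.5, 1, 2, 3, 4, 6, 8, 12, 18, 24])
        ode = sol.sol(grid)[1] / p.v2
        closed = css_two_compartment(p, ltc.regimen, grid)
        assert np.max(np.abs(closed - ode) / ode) < 1e-6

    def test_one_compartment_matches_ode_to_periodicity(self, dtg):
        p = build_individual_params(dtg.fixed, {"weight": 79, "bilirubin": 8, "ethnicity": 0})
        k = p.cl / p.v2

        def rhs(t, y):
            return [-p.ka * y[0], p.ka * y[0] - k * y[1]]

        y = np.zeros(2)
        for _ in range(25):
            y[0] += 50.0
            y = solve_ivp(rhs, (0, 24), y, rtol=1e-11, atol=1e-13, method="LSODA").y[:, -1]
        y[0] += 50.0
        sol = solve_ivp(rhs, (0, 24), y, rtol=1e-11, atol=1e-13, method="LSODA", dense_output=True)
        grid = np.array([0.5, 1, 2, 4, 8, 16, 24])
        ode = sol.sol(grid)[1] / p.v2
        closed = css_one_compartment(p, dtg.regimen, grid)
        assert np.max(np.abs(closed - ode) / ode) < 1e-6

    def test_large_ka_converges_to_bolus_profile(self):
        p = IndividualParameters(cl=0.858, v2=16.7, ka=1e6)
        reg = DoseRegimen(50.0, 24.0)
        k = p.cl / p.v2
        t = np.array([1.0, 6.0, 12.0, 24.0])
        bolus = 50.0 / 16.7 * np.exp(-k * t) / (1 - np.exp(-k * 24.0))
        assert css_one_compartment(p, reg, t) == pytest.approx(bolus, rel=1e-4)

    def test_degenerate_ka_equals_k_uses_confluent_limit(self):
        reg = DoseRegimen(50.0, 24.0)
        k = 0.858 / 16.7
        exact = css_one_compartment(IndividualParameters(cl=0.858, v2=16.7, ka=k), reg, 5.0)
        near = css_one_compartment(
            IndividualParameters(cl=0.858, v2=16.7, ka=k * (1 + 1e-6)), reg, 5.0
        )
        assert np.isfinite(exact)
        assert exact == pytest.approx(near, rel=1e-5)

    def test_vanishing_intercompartmental_clearance_collapses_to_one_compartment(self):
        reg = DoseRegimen(300.0, 24.0)
        t = np.array([0.0, 1.0, 3.0, 12.0, 24.0])
        two = css_two_compartment(
            IndividualParameters(cl=19.6, v2=105.0, ka=2.3, v3=50.0, q=1e-15), reg, t
        )
        one = css_one_compartment(IndividualParameters(cl=19.6, v2=105.0, ka=2.3), reg, t)
        assert two == pytest.approx(one, rel=1e-6)


class TestResidualErrorModel:
    def test_zero_epsilon_returns_prediction(self):
        assert apply_residual_error(3.7, 0.341, 1.0, 0.0) == 3.7

    def test_direct_formula(self):
        assert apply_residual_error(1.0, 0.341, 1.0, 1.0) == pytest.approx(1.341)

    def test_monte_carlo_relative_sd(self):
        rng = np.random.default_rng(5)
        eps = rng.standard_normal(100_000)
        y = apply_residual_error(np.full_like(eps, 2.0), 0.341, 1.3, eps)
        assert np.std(y / 2.0) == pytest.approx(0.341 * 1.3, rel=0.02)

    def test_negative_values_are_retained(self):
        assert apply_residual_error(1.0, 0.341, 1.0, -5.0) < 0


class TestVarianceTransforms:
    @pytest.mark.parametrize(
        "omega2, cv",
        [(0.0682, 26.6), (0.0567, 24.2), (0.0883, 30.4), (0.158, 41.4), (0.247, 52.9)],
    )
    def test_percent_cv_matches_published_values(self, omega2, cv):
        assert round(iiv_percent_cv(omega2), 1) == cv

    def test_zero_variance_gives_zero_cv(self):
        assert iiv_percent_cv(0.0) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(omega2=st.floats(0.0, 4.0))
    def test_round_trip(self, omega2):
        assert percent_cv_to_omega2(iiv_percent_cv(omega2)) == pytest.approx(omega2, abs=1e-12)

    def test_negative_variance_raises(self):
        with pytest.raises(ValueError):
            iiv_percent_cv(-0.1)


class TestCovariateEffects:
    def test_low_bilirubin_raises_clearance(self):
        assert covariate_effect_percent("power", 2.0, 8.0, -0.153) == pytest.approx(23.6, abs=0.05)

    def test_categorical_ratio(self):
        assert covariate_effect_percent("categorical", exponent_or_ratio=0.844) == pytest.approx(-15.6)

    def test_reference_value_gives_zero(self):
        assert covariate_effect_percent("power", 8.0, 8.0, -0.153) == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(b1=st.floats(2.0, 34.0), b2=st.floats(2.0, 34.0), w1=st.floats(50.0, 153.0), w2=st.floats(50.0, 153.0))
    def test_clearance_monotone_in_bilirubin_and_weight(self, dtg, b1, b2, w1, w2):
        """CL/F strictly decreasing in bilirubin, strictly increasing in weight."""
        def cl(w, b):
            return build_individual_params(dtg.fixed, {"weight": w, "bilirubin": b, "ethnicity": 0}).cl

        if b1 != b2:
            lo, hi = sorted((b1, b2))
            assert cl(79.0, lo) > cl(79.0, hi)
        if w1 != w2:
            lo, hi = sorted((w1, w2))
            assert cl(lo, 8.0) < cl(hi, 8.0)

    def test_lamivudine_clearance_increasing_in_egfr(self, ltc):
        def cl(e):
            return build_individual_params(ltc.fixed, {"weight": 70, "egfr": e, "race_black": 0}).cl

        assert cl(44.0) < cl(99.0) < cl(147.0)


class TestModelLibraryIO:
    def test_model_yaml_round_trip(self, ltc, tmp_path):
        path = tmp_path / "m.yaml"
        save_model(ltc, path)
        again = load_model(str(path))
        assert again == ltc

    def test_aliases(self, dtg):
        assert load_model("dtg") == dtg
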