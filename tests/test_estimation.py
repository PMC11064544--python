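"""NLME estimation: objective function, fitting, covariate selection and
bootstrap. Simulation sizes are scaled to keep the suite fast while leaving
the statistical checks meaningful."""

import dataclasses
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from dlpk.estimation import (
    bootstrap,
    covariate_search,
    fit,
    ofv,
    selection_thresholds,
)
from dlpk.models import CovariateTerm, RandomEffectsSpec, typical_params, load_model
from dlpk.population import PopulationSpec, simulate_population


def _no_iiv(model, prop_sd):
    return dataclasses.replace(
        model,
        fixed=replace(model.fixed, prop_error_sd=prop_sd),
        random=RandomEffectsSpec(eta_order=("cl", "ruv"), omega2={"cl": 0.0, "ruv": 0.0}),
    )


def _one_eta(model, omega2_cl):
    """Reduced configuration with a single eta on CL/F (no eta on the
    residual magnitude) — used for the cheap likelihood-ratio calibrations."""
    return dataclasses.replace(
        model,
        random=RandomEffectsSpec(eta_order=("cl", "ruv"), omega2={"cl": omega2_cl, "ruv": 0.0}),
    )


class TestObjectiveFunction:
    def test_selection_thresholds_match_chi_square_quantiles(self):
        fwd, bwd = selection_thresholds()
        assert round(fwd, 2) == 6.63
        assert round(bwd, 2) == 10.83

    def test_zero_iiv_collapses_to_weighted_least_squares(self, dtg):
        """With all omega2 = 0 the OFV is the plain fixed-effects
        -2 log-likelihood, computable directly."""
        model = _no_iiv(dtg, 0.341)
        ds = simulate_population(model, PopulationSpec(n_subjects=8, n_intensive=8), seed=3)
        obs = ds[ds.EVID == 0]
        typ = typical_params(model.fixed, obs)
        from dlpk.models import _css1_kernel

        f = _css1_kernel(50.0, 24.0, typ["cl"], typ["v2"], typ["ka"], obs["TIME"].to_numpy())
        sig = 0.341 * f
        direct = float(np.sum(np.log(2 * np.pi * sig**2) + ((obs["DV"] - f) / sig) ** 2))
        assert ofv(ds, model) == pytest.approx(direct, rel=1e-10)

    def test_true_parameters_beat_perturbed(self, dtg, dtg_rich_data):
        pert = dtg.with_fixed(replace(dtg.fixed, cl_pop=0.858 * 1.5))
        assert ofv(dtg_rich_data, dtg) < ofv(dtg_rich_data, pert)

    def test_null_covariate_term_leaves_ofv_unchanged(self, dtg, dtg_rich_data):
        term = CovariateTerm(target="cl", covariate="age", form="power", value=0.0, reference=40.0)
        extended = dtg.with_fixed(
            replace(dtg.fixed, covariate_terms=dtg.fixed.covariate_terms + (term,))
        )
        assert ofv(dtg_rich_data, extended) == pytest.approx(ofv(dtg_rich_data, dtg), abs=1e-6)

    def test_all_blq_subject_rejected(self, dtg):
        ds = simulate_population(dtg, PopulationSpec(n_subjects=4, n_intensive=4), seed=1)
        ds.loc[ds.ID == 1, "BLQ"] = 1
        with pytest.raises(ValueError):
            ofv(ds, dtg)


class TestFit:
    def test_noise_free_data_recovers_thetas_exactly(self, dtg):
        quiet = _no_iiv(dtg, 1e-6)
        ds = simulate_population(quiet, PopulationSpec(n_subjects=12, n_intensive=12), seed=3)
        fr = fit(ds, quiet, free=["theta.cl", "theta.v2", "theta.ka"], n_starts=1)
        assert fr.converged
        assert fr.params["theta.cl"] == pytest.approx(0.858, rel=1e-3)
        assert fr.params["theta.v2"] == pytest.approx(16.7, rel=1e-3)
        assert fr.params["theta.ka"] == pytest.approx(2.15, rel=1e-3)

    def test_rich_design_recovery_within_design_precision(self, dtg_rich_fit):
        fr = dtg_rich_fit
        assert fr.converged
        assert fr.params["theta.cl"] == pytest.approx(0.858, rel=0.10)
        assert fr.params["theta.v2"] == pytest.approx(16.7, rel=0.10)
        assert fr.params["sigma.prop"] == pytest.approx(0.341, rel=0.10)

    def test_standard_errors_reported(self, dtg_rich_fit):
        rse = dtg_rich_fit.rse_percent
        assert 0 < rse["theta.cl"] < 25
        assert 0 < rse["theta.v2"] < 25

    def test_nested_model_ofv_never_higher(self, dtg, dtg_rich_data):
        """Freeing an extra parameter cannot worsen the optimized OFV
        beyond optimizer tolerance."""
        base = fit(dtg_rich_data, dtg, free=["theta.cl", "omega2.cl", "sigma.prop"], n_starts=1)
        richer_start = base.model
        richer = fit(
            dtg_rich_data,
            richer_start,
            free=["theta.cl", "theta.v2", "omega2.cl", "sigma.prop"],
            n_starts=1,
        )
        assert richer.ofv <= base.ofv + 0.1

    def test_lamivudine_two_compartment_fit_converges(self, ltc):
        ds = simulate_population(ltc, PopulationSpec(n_subjects=40, n_intensive=15), seed=8)
        fr = fit(
            ds,
            ltc,
            free=["theta.cl", "theta.v2", "theta.q", "theta.ka", "omega2.cl", "sigma.prop"],
            n_starts=1,
        )
        assert fr.converged
        assert fr.params["theta.cl"] == pytest.approx(19.6, rel=0.15)

    def test_estimator_bias_shrinks_with_sample_size(self, dtg):
        errs = {}
        for n in (25, 100):
            e = []
            for s in (1, 2):
                ds = simulate_population(dtg, PopulationSpec(n_subjects=n, n_intensive=n), seed=100 + s)
                fr = fit(ds, dtg, free=["theta.cl", "omega2.cl", "sigma.prop"], n_starts=1)
                e.append(abs(np.log(fr.params["theta.cl"] / 0.858)))
            errs[n] = np.mean(e)
        assert errs[100] < errs[25] or errs[100] < 0.03


class TestLikelihoodRatioCalibration:
    def test_null_delta_ofv_is_chi_square_one_df(self, dtg):
        """Adding a spurious 1-d.f. covariate to null data gives Delta-OFV
        distributed as chi-square(1): Q-Q slope near 1, forward
        false-acceptance rate near the 1% nominal level."""
        gen = _one_eta(dtg, 0.0682)
        cand = CovariateTerm(target="cl", covariate="age", form="power", value=0.0, reference=40.0)
        free_base = ["theta.cl", "omega2.cl", "sigma.prop"]
        spec = PopulationSpec(n_subjects=30, n_intensive=30)
        dofvs = []
        for rep in range(80):
            ds = simulate_population(gen, spec, seed=5000 + rep)
            base = fit(ds, gen, free=free_base, n_starts=1, maxiter=100)
            ext_model = gen.with_fixed(
                replace(gen.fixed, covariate_terms=gen.fixed.covariate_terms + (cand,))
            )
            ext = fit(ds, ext_model, free=free_base + ["beta.cl:age"], n_starts=1, maxiter=100)
            dofvs.append(max(base.ofv - ext.ofv, 0.0))
        dofvs = np.sort(dofvs)
        theo = stats.chi2.ppf((np.arange(1, 81) - 0.5) / 80, df=1)
        slope = float(np.sum(theo * dofvs) / np.sum(theo * theo))
        assert 0.85 <= slope <= 1.15
        fwd, _ = selection_thresholds()
        assert np.mean(dofvs >= fwd) <= 4 / 80


class TestCovariateSearch:
    def test_empty_candidate_set_returns_base_model(self, dtg):
        ds = simulate_population(dtg, PopulationSpec(n_subjects=20, n_intensive=20), seed=2)
        res = covariate_search(ds, dtg, [], n_starts=1, maxiter=60)
        assert res.retained == []
        assert res.final_model.fixed == dtg.fixed

    def test_strong_simulated_effect_recovered_with_estimate(self, dtg):
        """A large synthetic CL/F category effect (ratio 0.5) is found by the
        forward/backward search and its ratio re-estimated accurately."""
        strong = dtg.with_fixed(
            replace(
                dtg.fixed,
                covariate_terms=tuple(
                    replace(t, value=0.5) if t.covariate == "ethnicity" else t
                    for t in dtg.fixed.covariate_terms
                ),
            )
        )
        base = dtg.with_fixed(
            replace(
                dtg.fixed,
                covariate_terms=tuple(t for t in dtg.fixed.covariate_terms if t.covariate != "ethnicity"),
            )
        )
        cand = CovariateTerm(target="cl", covariate="ethnicity", form="categorical", value=1.0)
        ds = simulate_population(strong, PopulationSpec(n_subjects=60, n_intensive=20), seed=31)
        res = covariate_search(ds, base, [cand], n_starts=1, maxiter=150)
        assert res.retained == ["cl:ethnicity"]
        est = next(
            t.value for t in res.final_model.fixed.covariate_terms if t.covariate == "ethnicity"
        )
        assert est == pytest.approx(0.5, rel=0.2)


class TestBootstrap:
    def test_median_close_to_point_estimate(self, dtg):
        gen = _one_eta(dtg, 0.0682)
        ds = simulate_population(gen, PopulationSpec(n_subjects=30, n_intensive=30), seed=12)
        free = ["theta.cl", "omega2.cl", "sigma.prop"]
        point = fit(ds, gen, free=free, n_starts=1)
        res = bootstrap(ds, gen, n_replicates=20, seed=1, free=free, maxiter=100)
        assert res.fraction_converged >= 0.9
        assert res.median["theta.cl"] == pytest.approx(point.params["theta.cl"], rel=0.05)
        assert res.ci_lower["theta.cl"] <= res.median["theta.cl"] <= res.ci_upper["theta.cl"]

    def test_identical_seed_reproduces_percentiles(self, dtg):
        gen = _one_eta(dtg, 0.0682)
        ds = simulate_population(gen, PopulationSpec(n_subjects=10, n_intensive=10), seed=12)
        free = ["theta.cl", "sigma.prop"]
        a = bootstrap(ds, gen, n_replicates=4, seed=7, free=free, maxiter=60)
        b = bootstrap(ds, gen, n_replicates=4, seed=7, free=free, maxiter=60)
        assert a.median == b.median and a.ci_lower == b.ci_lower

    def test_single_subject_rejected(self, dtg):
        ds = simulate_population(dtg, PopulationSpec(n_subjects=1, n_intensive=1), seed=1)
        with pytest.raises(ValueError):
            bootstrap(ds, dtg, n_replicates=5)
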