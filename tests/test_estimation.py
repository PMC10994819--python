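"""Laplace objective, model fitting, covariate search, food test, bootstrap."""

import dataclasses
import math

import numpy as np
import pytest

from pospk import estimation, synthesis
from pospk._engine import CovariateRelation
from pospk.model import DoseEvent, Observation, Subject, StudyDataset
from pospk.params import final_model_parameters


def _toy_subject(pop, conc_by_time, weight=28.6, sid=1):
    s = Subject(
        id=sid, weight=weight, age=10.0, sex="M", race="White",
        ethnicity="Not Hispanic", egfr=100.0,
    )
    s.doses.append(DoseEvent(time=0.0, amount=150.0, route="iv", infusion_duration=1.5))
    for t, c in conc_by_time:
        s.observations.append(
            Observation(time=t, concentration=c, blq_flag=False, missing_flag=False)
        )
    return s


class TestObjective:
    def test_no_iiv_ofv_is_sum_of_scalar_log_densities(self, truth):
        """With all variances zero the marginal is the residual density alone."""
        from pospk.model import concentration_profile, individual_from_population

        pop = dataclasses.replace(
            truth, omega2_cl=0.0, omega2_vc=0.0, omega_sd_f1_logit=0.0
        )
        times = [1.5, 4.0, 12.0]
        ind = individual_from_population(pop, 28.6)
        pred = concentration_profile(ind, [DoseEvent(0.0, 150.0, "iv", 1.5)], times)
        obs = pred * np.exp([0.2, -0.1, 0.35])
        ds = StudyDataset(
            subjects=[_toy_subject(pop, list(zip(times, obs)))], lloq=0.0
        )
        ofv = estimation.laplace_ofv(pop, ds)
        sig2 = pop.sigma_log**2
        r = np.log(obs) - np.log(pred)
        expected = float(np.sum(np.log(2 * np.pi * sig2) + r**2 / sig2))
        assert ofv == pytest.approx(expected, abs=1e-6)

    def test_joint_neg2ll_matches_density_sum(self, truth):
        """Brute-force sum of scalar normal log-densities on a toy subject."""
        from pospk.model import concentration_profile, individual_from_population

        eta = (0.25, -0.1, 0.3)
        times = [1.5, 6.0, 24.0]
        ind = individual_from_population(truth, 28.6, eta)
        pred = concentration_profile(ind, [DoseEvent(0.0, 150.0, "iv", 1.5)], times)
        obs = pred * np.exp([0.1, -0.2, 0.05])
        subj = _toy_subject(truth, list(zip(times, obs)))
        got = estimation.subject_joint_neg2ll(truth, subj, eta)
        sig2 = truth.sigma_log**2
        r = np.log(obs) - np.log(pred)
        expected = float(np.sum(np.log(2 * np.pi * sig2) + r**2 / sig2))
        om = truth.omega_matrix()
        e = np.array(eta)
        act = np.diag(om) > 0
        oi = np.linalg.inv(om[np.ix_(act, act)])
        expected += float(
            np.log(np.linalg.det(2 * np.pi * om[np.ix_(act, act)]))
            + e[act] @ oi @ e[act]
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_laplace_matches_exact_marginal_in_conjugate_case(self):
        """Near-bolus IV with tiny sampling times makes the log prediction
        linear in the single active random effect; the Laplace approximation
        is then exact and must match the closed-form normal-normal marginal."""
        omega2, sigma = 0.09, 0.15
        pop = dataclasses.replace(
            final_model_parameters(),
            omega2_cl=0.0, omega2_vc=omega2, omega_sd_f1_logit=0.0, sigma_log=sigma,
        )
        rng = np.random.default_rng(5)
        tinf, tobs = 1e-9, np.array([1e-8, 2e-8, 3e-8])
        subs = []
        for i in range(12):
            vc = pop.vc_typ * math.exp(rng.normal(0, math.sqrt(omega2)))
            y = (100.0 / vc * 1000.0) * np.exp(rng.normal(0, sigma, tobs.size))
            s = Subject(id=i + 1, weight=pop.wt_ref, age=10.0, sex="M", race="White",
                        ethnicity="Not Hispanic", egfr=100.0)
            s.doses.append(DoseEvent(0.0, 100.0, "iv", tinf))
            for t, c in zip(tobs, y):
                s.observations.append(
                    Observation(float(t + tinf), float(c), False, False)
                )
            subs.append(s)
        ds = StudyDataset(subjects=subs, lloq=0.0)
        ofv = estimation.laplace_ofv(pop, ds)
        mu0 = math.log(100.0 / pop.vc_typ * 1000.0)
        exact = 0.0
        for s in subs:
            yl = np.log([o.concentration for o in s.observations])
            n = yl.size
            cov = sigma**2 * np.eye(n) + omega2 * np.ones((n, n))
            r = yl - mu0
            exact += n * np.log(2 * np.pi) + np.linalg.slogdet(cov)[1]
            exact += r @ np.linalg.solve(cov, r)
        assert abs(ofv - exact) < 1e-6


class TestFitModel:
    def test_fit_recovers_small_study(self, small_fit, truth):
        assert small_fit.converged
        assert math.isfinite(small_fit.ofv)
        e = small_fit.estimates
        # n = 20 subjects: loose sampling-error bounds around the truth
        assert e.cl_typ == pytest.approx(truth.cl_typ, rel=0.35)
        assert e.vc_typ == pytest.approx(truth.vc_typ, rel=0.35)
        assert 0.3 < e.f1_typ < 1.0

    def test_fit_improves_on_init(self, small_dataset, truth, small_fit):
        init = dataclasses.replace(truth, cl_typ=3.0, vc_typ=80.0)
        assert small_fit.ofv <= estimation.laplace_ofv(init, small_dataset) + 1e-6

    def test_reported_inference_contract(self, small_dataset, truth):
        fit = estimation.fit_model(small_dataset, truth, compute_se=True, maxiter=60)
        assert fit.se is not None and all(v >= 0 for v in fit.se.values())
        assert all(v >= 0 for v in fit.rse_pct.values())
        for v in fit.shrinkage_pct.values():
            assert -1e-6 <= v <= 100.0 + 1e-6
        rep = fit.reported()
        assert rep["iiv_cl_cv_pct"] == pytest.approx(
            100.0 * math.sqrt(fit.estimates.omega2_cl), rel=1e-9
        )

    def test_fixed_rho_respected(self, small_fit):
        assert "rho_cl_vc" in small_fit.fixed
        assert small_fit.estimates.rho_cl_vc == 0.0

    def test_deterministic(self, small_dataset, truth):
        a = estimation.fit_model(small_dataset, truth, compute_se=False, maxiter=25)
        b = estimation.fit_model(small_dataset, truth, compute_se=False, maxiter=25)
        assert a.ofv == b.ofv
        assert a.estimates == b.estimates


class TestCovariateSearch:
    def test_strong_planted_effect_is_retained(self, truth):
        """Simulate a strong sex effect on CL and check the search keeps it."""
        design = synthesis.StudyDesign(cohort_levels=(6.0,), cohort_sizes=(40,))
        ds = synthesis.generate_study_dataset(design, truth, seed=21)
        scale = math.exp(-0.7)  # concentrations ~ 1/CL: emulate CL x e^0.7 in males
        ds = StudyDataset(
            subjects=[
                synthesis.replace_observations(
                    s,
                    [dataclasses.replace(o, concentration=o.concentration * scale)
                     for o in s.observations],
                )
                if s.sex == "M"
                else s
                for s in ds.subjects
            ],
            lloq=ds.lloq,
        )
        ds, _ = synthesis.apply_preparation_rules(ds)
        ds = synthesis.impute_covariates(ds)
        base = estimation.fit_model(ds, truth, compute_se=False)
        res = estimation.stepwise_covariate_search(
            ds, base, [CovariateRelation("sex", "cl", "categorical")],
            compute_se=False,
        )
        assert [r.covariate for r in res.selected] == ["sex"]
        assert res.ledger  # every decision recorded
        forward = [e for e in res.ledger if e["phase"] == "forward"]
        assert forward and forward[0]["delta_ofv"] >= estimation.CHI2_FORWARD

    def test_search_thresholds(self):
        assert estimation.CHI2_FORWARD == pytest.approx(6.635, abs=1e-3)
        assert estimation.CHI2_BACKWARD == pytest.approx(10.828, abs=1e-3)


class TestFoodEffect:
    def test_planted_food_effect_detected(self, truth):
        # a logit shift has little leverage where F1 saturates near 1, so the
        # power check generates from a mid-range bioavailability
        gen = dataclasses.replace(truth, f1_typ=0.4, omega_sd_f1_logit=0.4)
        design = synthesis.StudyDesign(
            cohort_levels=(6.0,), cohort_sizes=(40,),
            switch_fraction=1.0, inpatient_fraction=1.0,
            food_logit_shift=math.log(3.0),
        )
        ds = synthesis.generate_study_dataset(design, gen, seed=37)
        ds, _ = synthesis.apply_preparation_rules(ds)
        ds = synthesis.impute_covariates(ds)
        base = estimation.fit_model(ds, gen, compute_se=False)
        res = estimation.food_effect_test(ds, base, categorization="two")
        assert res["decision"] == "included"
        assert res["delta_ofv"] >= estimation.CHI2_FORWARD
        assert set(res["eta_f1_by_category"]) >= {"fed"}

    def test_null_food_effect_not_included(self, small_dataset, small_fit):
        res = estimation.food_effect_test(small_dataset, small_fit, categorization="two")
        if res["delta_ofv"] is not None:
            assert res["decision"] == "not included"


class TestBootstrap:
    def test_identity_resample_reproduces_estimates(self, small_dataset, small_fit):
        boot = estimation.bootstrap(
            small_dataset, small_fit, n_reps=2, seed=1, identity_resample=True,
            compute_se=False,
        )
        got = boot["percentiles"]["cl_typ"]["50%"]
        assert got == pytest.approx(small_fit.estimates.cl_typ, rel=1e-4)

    def test_percentile_summary_structure(self, small_dataset, small_fit):
        boot = estimation.bootstrap(
            small_dataset, small_fit, n_reps=3, seed=2, compute_se=False
        )
        assert boot["n_fitted"] >= 1
        assert 0.0 <= boot["converged_fraction"] <= 1.0
        for key in ("cl_typ", "vc_typ", "f1_typ"):
            p = boot["percentiles"][key]
            assert p["2.5%"] <= p["50%"] <= p["97.5%"]
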