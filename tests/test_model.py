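"""Structural model, parameter model and exposure metrics."""

import dataclasses
import math

import numpy as np
import pytest

from pospk.model import (
    DoseEvent,
    concentration_profile,
    dose_for_weight,
    exposure_metrics,
    f1_population_interval,
    individual_from_population,
)
from pospk.params import PopulationParameters, final_model_parameters


def iv(time, amount, tinf=1.5):
    return DoseEvent(time=time, amount=amount, route="iv", infusion_duration=tinf)


def oral(time, amount, route="pfs"):
    return DoseEvent(time=time, amount=amount, route=route, infusion_duration=0.0)


class TestIndividualFromPopulation:
    def test_identity_at_reference(self, truth):
        ind = individual_from_population(truth, truth.wt_ref)
        assert ind.cl_i == pytest.approx(4.71)
        assert ind.vc_i == pytest.approx(112.0)
        assert ind.f1_i == pytest.approx(0.826)
        assert ind.ka_i == pytest.approx(0.212)

    def test_allometric_power_law_at_70kg(self, truth):
        ind = individual_from_population(truth, 70.0)
        assert ind.cl_i == pytest.approx(4.71 * (70 / 28.6) ** 0.624, rel=1e-12)
        assert ind.cl_i == pytest.approx(8.23, abs=0.01)
        assert ind.vc_i == pytest.approx(112.0 * (70 / 28.6) ** 0.971, rel=1e-12)

    def test_logit_bioavailability_shift(self, truth):
        ind = individual_from_population(truth, truth.wt_ref, eta=(0.0, 0.0, -2.02))
        expected = 1.0 / (1.0 + math.exp(-(math.log(0.826 / 0.174) - 2.02)))
        assert ind.f1_i == pytest.approx(expected, rel=1e-9)
        assert ind.f1_i == pytest.approx(0.386, abs=0.002)

    def test_eta_acts_multiplicatively(self, truth):
        base = individual_from_population(truth, 20.0)
        bumped = individual_from_population(truth, 20.0, eta=(0.3, -0.2, 0.0))
        assert bumped.cl_i == pytest.approx(base.cl_i * math.exp(0.3), rel=1e-12)
        assert bumped.vc_i == pytest.approx(base.vc_i * math.exp(-0.2), rel=1e-12)

    def test_monotone_in_weight(self, truth):
        cls = [individual_from_population(truth, w).cl_i for w in (10, 20, 40, 80)]
        assert all(a < b for a, b in zip(cls, cls[1:]))

    def test_f1_bounded_for_extreme_eta(self, truth):
        for eta_f in (-50.0, 50.0):
            ind = individual_from_population(truth, 30.0, eta=(0, 0, eta_f))
            assert 0.0 < ind.f1_i < 1.0

    def test_nonpositive_weight_rejected(self, truth):
        with pytest.raises(ValueError):
            individual_from_population(truth, 0.0)
        with pytest.raises(ValueError):
            individual_from_population(truth, -5.0)


class TestConcentrationProfile:
    def test_iv_end_of_infusion_value(self, truth):
        ind = individual_from_population(truth, truth.wt_ref)
        (c,) = concentration_profile(ind, [iv(0.0, 300.0)], [1.5])
        rate, k = 300.0 / 1.5, 4.71 / 112.0
        expected = (rate / 4.71) * (1 - math.exp(-k * 1.5)) * 1000.0
        assert c == pytest.approx(expected, rel=1e-9)
        assert c == pytest.approx(2596.0, abs=1.0)

    def test_oral_single_dose_value(self, truth):
        ind = individual_from_population(truth, truth.wt_ref)
        (c,) = concentration_profile(ind, [oral(0.0, 100.0)], [6.0])
        ka, k, f = 0.212, 4.71 / 112.0, 0.826
        expected = f * 100.0 * ka / (112.0 * (ka - k))
        expected *= math.exp(-k * 6.0) - math.exp(-ka * 6.0)
        assert c == pytest.approx(expected * 1000.0, rel=1e-9)
        assert c == pytest.approx(457.0, abs=1.0)

    def test_no_doses_no_drug(self, truth):
        ind = individual_from_population(truth, 30.0)
        assert np.all(concentration_profile(ind, [], [0.0, 5.0, 100.0]) == 0.0)

    def test_superposition_and_linearity(self, truth):
        ind = individual_from_population(truth, 30.0)
        times = np.linspace(0.0, 72.0, 25)
        d1, d2 = iv(0.0, 150.0), oral(24.0, 90.0)
        both = concentration_profile(ind, [d1, d2], times)
        summed = concentration_profile(ind, [d1], times) + concentration_profile(
            ind, [d2], times
        )
        np.testing.assert_allclose(both, summed, rtol=1e-12)
        doubled = concentration_profile(
            ind,
            [dataclasses.replace(d1, amount=300.0), dataclasses.replace(d2, amount=180.0)],
            times,
        )
        np.testing.assert_allclose(doubled, 2.0 * both, rtol=1e-12)

    def test_ka_equals_k_limit_continuous(self, truth):
        k = 4.71 / 112.0
        at_limit = dataclasses.replace(truth, ka=k)
        nearby = dataclasses.replace(truth, ka=k * (1 + 1e-6))
        ind0 = individual_from_population(at_limit, truth.wt_ref)
        ind1 = individual_from_population(nearby, truth.wt_ref)
        times = [1.0, 6.0, 12.0, 24.0]
        c0 = concentration_profile(ind0, [oral(0.0, 100.0)], times)
        c1 = concentration_profile(ind1, [oral(0.0, 100.0)], times)
        np.testing.assert_allclose(c1, c0, rtol=1e-5)

    def test_negative_times_rejected(self, truth):
        ind = individual_from_population(truth, 30.0)
        with pytest.raises(ValueError):
            concentration_profile(ind, [iv(0.0, 100.0)], [-1.0, 2.0])


class TestExposureMetrics:
    @staticmethod
    def _steady_state_doses(make, n_days=30):
        return [make(24.0 * d) for d in range(n_days)]

    def test_iv_steady_state_identity(self, truth):
        ind = individual_from_population(truth, truth.wt_ref)
        doses = self._steady_state_doses(lambda t: iv(t, 171.6))
        m = exposure_metrics(ind, doses, interval_start=24.0 * 29, tau=24.0)
        assert m.cavg == pytest.approx(171.6 / (4.71 * 24.0) * 1000.0, rel=1e-3)
        assert m.cavg == pytest.approx(1518.0, abs=2.0)
        assert m.cavg >= m.cmin > 0.0

    def test_oral_steady_state_identity(self, truth):
        ind = individual_from_population(truth, truth.wt_ref)
        doses = self._steady_state_doses(lambda t: oral(t, 171.6))
        m = exposure_metrics(ind, doses, interval_start=24.0 * 29, tau=24.0)
        assert m.cavg == pytest.approx(0.826 * 171.6 / (4.71 * 24.0) * 1000.0, rel=1e-3)
        assert m.cavg == pytest.approx(1254.0, abs=2.0)

    def test_cavg_matches_trapezoid(self, truth):
        ind = individual_from_population(truth, 20.0, eta=(0.1, -0.1, 0.4))
        doses = [iv(0.0, 120.0), oral(24.0, 120.0), oral(48.0, 120.0)]
        m = exposure_metrics(ind, doses, interval_start=48.0, tau=24.0)
        grid = np.linspace(48.0, 72.0, 20001)
        conc = concentration_profile(ind, doses, grid)
        assert m.cavg == pytest.approx(np.trapezoid(conc, grid) / 24.0, rel=1e-4)
        assert m.cmin == pytest.approx(conc[-1], rel=1e-9)

    def test_interval_before_first_dose_rejected(self, truth):
        ind = individual_from_population(truth, 30.0)
        with pytest.raises(ValueError):
            exposure_metrics(ind, [iv(10.0, 100.0)], interval_start=0.0, tau=24.0)


class TestDoseForWeight:
    def test_below_cap(self):
        assert dose_for_weight(16.0, 6.0) == pytest.approx(96.0)

    def test_cap_engaged(self):
        assert dose_for_weight(60.0, 6.0) == pytest.approx(300.0)
        assert dose_for_weight(40.0, 7.5) == pytest.approx(300.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dose_for_weight(-1.0, 6.0)
        with pytest.raises(ValueError):
            dose_for_weight(16.0, 0.0)


class TestF1PopulationInterval:
    def test_printed_interval(self):
        lo, hi = f1_population_interval(0.826, 2.02, 0.95)
        assert lo == pytest.approx(0.083, abs=5e-4)
        assert hi == pytest.approx(0.996, abs=5e-4)

    def test_degenerate_sd(self):
        lo, hi = f1_population_interval(0.7, 1e-12, 0.95)
        assert lo == pytest.approx(0.7, abs=1e-9)
        assert hi == pytest.approx(0.7, abs=1e-9)


class TestPopulationParameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            dataclasses.replace(final_model_parameters(), cl_typ=-1.0)
        with pytest.raises(ValueError):
            dataclasses.replace(final_model_parameters(), f1_typ=1.2)
        with pytest.raises(ValueError):
            dataclasses.replace(final_model_parameters(), rho_cl_vc=1.5)

    def test_omega_matrix_is_psd_with_correlation(self):
        p = final_model_parameters(rho_cl_vc=0.6)
        om = p.omega_matrix()
        assert np.all(np.linalg.eigvalsh(om) >= 0.0)
        assert om[0, 1] == pytest.approx(
            0.6 * math.sqrt(p.omega2_cl * p.omega2_vc), rel=1e-12
        )

    def test_json_roundtrip(self, tmp_path, truth):
        path = tmp_path / "params.json"
        truth.to_json(path)
        back = PopulationParameters.from_json(path)
        assert back == truth
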