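"""Virtual populations, study-design emulation and data-preparation rules."""

import copy
import dataclasses
import math

import numpy as np
import pytest

from pospk import io, synthesis
from pospk.model import Observation
from pospk.params import final_model_parameters


class TestVirtualPopulation:
    def test_study_population_medians(self):
        pop = synthesis.generate_virtual_population(
            synthesis.study_population_spec(2000, 2000), 101
        )
        young = pop[pop.age < 7]
        old = pop[pop.age >= 7]
        assert young.weight.median() == pytest.approx(16.0, abs=1.5)
        assert old.weight.median() == pytest.approx(45.4, abs=4.0)

    def test_truncation_and_age_bands(self):
        pop = synthesis.generate_virtual_population(
            synthesis.study_population_spec(1000, 1000), 7
        )
        young = pop[pop.age < 7]
        old = pop[pop.age >= 7]
        assert young.age.between(2, 7).all() and old.age.between(7, 18).all()
        assert young.weight.between(10.2, 41.7).all()
        assert old.weight.between(18.2, 102.0).all()

    def test_adolescents_rarely_below_40kg(self):
        pop = synthesis.generate_virtual_population(
            synthesis.adolescent_population_spec(5000), 23
        )
        assert (pop.weight < 40.0).mean() < 0.05

    def test_deterministic_under_seed(self):
        spec = synthesis.study_population_spec(200, 200)
        a = synthesis.generate_virtual_population(spec, 5)
        b = synthesis.generate_virtual_population(spec, 5)
        assert a.equals(b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            synthesis.study_population_spec(0, 100)


@pytest.fixture(scope="module")
def dataset(truth):
    return synthesis.generate_study_dataset(synthesis.StudyDesign(), truth, seed=42)


class TestGenerateStudyDataset:
    def test_design_counts(self, dataset):
        assert len(dataset.subjects) == 114
        levels = sorted(
            {round(s.doses[0].amount / s.weight, 1) for s in dataset.subjects
             if s.doses[0].amount < 300.0}
        )
        assert levels == [3.5, 4.5, 6.0]

    def test_day1_loading_and_qd_schedule(self, dataset):
        for s in dataset.subjects[:10]:
            iv_times = sorted(d.time for d in s.doses if d.route == "iv")
            assert iv_times[:2] == [0.0, 12.0]  # BID on day 1
            # QD days 2-10 -> doses at 24h spacing through t = 216 h
            assert iv_times[2:] == [24.0 * d for d in range(1, 10)]

    def test_switchers_get_oral_after_day_10(self, dataset):
        switchers = [s for s in dataset.subjects if s.has_oral_doses]
        frac = len(switchers) / len(dataset.subjects)
        assert 0.35 < frac < 0.7  # about 60/114 in the emulated design
        for s in switchers[:10]:
            oral_times = [d.time for d in s.doses if d.is_oral]
            assert min(oral_times) >= 240.0
            assert all(d.route == "pfs" for d in s.doses if d.is_oral)

    def test_dose_cap(self, dataset):
        assert all(d.amount <= 300.0 for s in dataset.subjects for d in s.doses)
        heavy = [s for s in dataset.subjects if s.weight > 70.0]
        assert any(d.amount == 300.0 for s in heavy for d in s.doses)

    def test_noise_free_limit_matches_typical_predictions(self, truth):
        from pospk.model import concentration_profile, individual_from_population

        quiet = dataclasses.replace(
            truth, omega2_cl=0.0, omega2_vc=0.0, omega_sd_f1_logit=0.0, sigma_log=0.0
        )
        design = synthesis.StudyDesign(cohort_levels=(6.0,), cohort_sizes=(5,))
        ds = synthesis.generate_study_dataset(design, quiet, seed=9)
        for s in ds.subjects:
            ind = individual_from_population(quiet, s.weight)
            times = [o.time for o in s.observations]
            pred = concentration_profile(ind, s.doses, times)
            obs = np.array([o.concentration for o in s.observations])
            np.testing.assert_allclose(obs, pred, rtol=1e-9)

    def test_determinism_byte_identical(self, truth, tmp_path):
        design = synthesis.StudyDesign(cohort_levels=(4.5,), cohort_sizes=(8,))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        io.write_dataset(synthesis.generate_study_dataset(design, truth, seed=77), p1)
        io.write_dataset(synthesis.generate_study_dataset(design, truth, seed=77), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_blq_flags_respect_lloq(self, dataset):
        for s in dataset.subjects:
            for o in s.observations:
                if not o.missing_flag and not math.isnan(o.concentration):
                    assert o.blq_flag == (o.concentration < dataset.lloq)


class TestPreparationRules:
    def test_exclusion_categories_counted(self, truth):
        design = synthesis.StudyDesign(cohort_levels=(6.0,), cohort_sizes=(6,))
        ds = synthesis.generate_study_dataset(design, truth, seed=31)
        ds = copy.deepcopy(ds)
        s = ds.subjects[0]
        t0 = s.observations[0].time
        s.observations.append(
            Observation(time=t0, concentration=123.0, blq_flag=False, missing_flag=False)
        )
        s.observations.append(
            Observation(time=math.nan, concentration=50.0, blq_flag=False, missing_flag=True)
        )
        s.observations.append(
            Observation(time=2.0, concentration=1.0, blq_flag=True, missing_flag=False)
        )
        s.observations.append(
            Observation(time=-1.0, concentration=80.0, blq_flag=False, missing_flag=False)
        )
        clean, report = synthesis.apply_preparation_rules(ds)
        assert report["duplicate_time"] >= 1
        assert report["missing"] >= 1
        assert report["blq"] >= 1
        assert report["pre_first_dose"] >= 1
        n_raw = sum(len(x.observations) for x in ds.subjects)
        n_clean = sum(len(x.observations) for x in clean.subjects)
        assert n_clean == n_raw - sum(report.values())
        for x in clean.subjects:
            for o in x.observations:
                assert not o.blq_flag and not o.missing_flag

    def test_impute_covariates_fills_egfr(self, truth):
        design = synthesis.StudyDesign(
            cohort_levels=(6.0,), cohort_sizes=(12,), egfr_missing_fraction=0.25
        )
        ds = synthesis.generate_study_dataset(design, truth, seed=13)
        assert any(s.egfr is None for s in ds.subjects)
        filled = synthesis.impute_covariates(ds)
        assert all(s.egfr is not None and s.egfr > 0 for s in filled.subjects)
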