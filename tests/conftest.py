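"""Shared fixtures: a small synthetic study and a fit of it.

The small study (one 20-subject cohort) keeps the unit suite fast; the
full-design dataset used for acceptance lives in tests/test_acceptance.py.
"""

import pytest

from pospk import estimation, synthesis
from pospk.params import final_model_parameters


@pytest.fixture(scope="session")
def truth():
    return final_model_parameters()


@pytest.fixture(scope="session")
def small_dataset(truth):
    design = synthesis.StudyDesign(cohort_levels=(6.0,), cohort_sizes=(20,))
    raw = synthesis.generate_study_dataset(design, truth, seed=3)
    clean, _ = synthesis.apply_preparation_rules(raw)
    return synthesis.impute_covariates(clean)


@pytest.fixture(scope="session")
def small_fit(small_dataset, truth):
    return estimation.fit_model(small_dataset, truth, compute_se=False)
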