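"""Shared fixtures: a small synthetic survey, classified and scored."""

import dataclasses

import pytest

import nurselabor as nl


@pytest.fixture(scope="session")
def small_params():
    """A reduced 2005-2019 survey: ~36k person-quarter records."""
    return dataclasses.replace(nl.SimulationParams(),
                               n_households_per_quarter=300, seed=20251701)


@pytest.fixture(scope="session")
def small_microdata(small_params):
    return nl.generate_microdata(small_params)


@pytest.fixture(scope="session")
def small_sample(small_microdata):
    """Analytic sample with labor status, period and precarity columns."""
    sample, audit = nl.build_analytic_sample(small_microdata)
    sample = nl.classify_labor_status_frame(sample)
    from nurselabor.cohort import add_period_column

    sample = add_period_column(sample)
    sample = nl.add_precarity_columns(sample)
    return sample, audit


@pytest.fixture(scope="session")
def design():
    return nl.SurveyDesign()
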