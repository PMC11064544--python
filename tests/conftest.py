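import pytest

from dlpk.models import load_model
from dlpk.population import PopulationSpec, draw_covariates, simulate_population


@pytest.fixture(scope="session")
def dtg():
    return load_model("dolutegravir")


@pytest.fixture(scope="session")
def ltc():
    return load_model("lamivudine")


@pytest.fixture(scope="session")
def cohort_covariates():
    """Full-size (n=361) baseline covariate table, fixed seed."""
    return draw_covariates(PopulationSpec(), seed=11)


@pytest.fixture(scope="session")
def dtg_rich_data(dtg):
    """Densely sampled dolutegravir dataset: 60 subjects, all intensive."""
    return simulate_population(dtg, PopulationSpec(n_subjects=60, n_intensive=60), seed=42)


@pytest.fixture(scope="session")
def dtg_rich_fit(dtg, dtg_rich_data):
    """One shared maximum-likelihood fit of the rich dolutegravir dataset."""
    from dlpk.estimation import fit

    return fit(dtg_rich_data, dtg, n_starts=1, seed=1)
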