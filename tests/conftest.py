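import numpy as np
import pytest

import mixrelease as mr
from mixrelease.qccp_terms import generate_term_basis
from mixrelease.qif_fit import ar1_basis, fit_qif
from mixrelease.reference_model import SELECTED_TERMS
from mixrelease.release_objectives import ReleaseModel, build_objectives


@pytest.fixture(scope="session")
def reference():
    return mr.load_reference_dataset()


@pytest.fixture(scope="session")
def basis5():
    return generate_term_basis(5)


@pytest.fixture(scope="session")
def candidates():
    return mr.load_candidate_table()


@pytest.fixture(scope="session")
def refit_model(reference, basis5):
    """QIF refit of the published selected term set on the reference data."""
    fit = fit_qif(reference, basis5, SELECTED_TERMS + ["intercept"],
                  ar1_basis(reference.n_times))
    return ReleaseModel.from_fit(basis5, fit)


@pytest.fixture(scope="session")
def release_objectives(refit_model):
    return build_objectives(refit_model)


@pytest.fixture(scope="session")
def synthetic_small():
    """A small deterministic synthetic study with known sparse truth."""
    cfg = mr.SyntheticConfig(n_formulations=40, seed=1234)
    dataset, truth = mr.simulate_mixture_study(cfg)
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
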