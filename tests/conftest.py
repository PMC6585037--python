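import logging

import numpy as np
import pytest

from coupledesign.fixtures_oracle import toy_network, write_fixture_sbml
from coupledesign.intervention import FormulationParams, LinearFluxSpace

logging.getLogger("cobra").setLevel(logging.ERROR)


@pytest.fixture
def toy_a():
    return toy_network("TOY-A")


@pytest.fixture
def toy_b():
    return toy_network("TOY-B")


@pytest.fixture
def toy_b_maint():
    return toy_network("TOY-B", maintenance_lb=1.0)


@pytest.fixture
def toy_c():
    return toy_network("TOY-C")


@pytest.fixture(scope="session")
def fixture_sbml_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("sbml")
    write_fixture_sbml(str(out))
    return out


def weak_coupling_target(model, min_biomass=1.0, max_product=0.0):
    """Target space blocking {v_p <= max_product, v_bio >= min_biomass}."""
    rows = np.zeros((2, model.n_reactions))
    rows[0, model.index("R_p")] = -1.0
    rows[1, model.index("R_bio")] = 1.0
    return LinearFluxSpace(T=rows, b=np.array([-max_product, min_biomass]), label="weak")


def standard_formulations():
    """One parameter set per target-space formulation, on the shared toy ids."""
    return [
        FormulationParams(formulation="MCSe", product_id="R_p", substrate_id="R_s",
                          atpm_id="R_m", y_min=0.3, s_max=10.0, m_atp=1.0),
        FormulationParams(formulation="MCSf", product_id="R_p", substrate_id="R_s",
                          y_min=0.3, s_max=10.0),
        FormulationParams(formulation="MCSw", product_id="R_p", biomass_id="R_bio",
                          eps=1e-4, F=0.1),
    ]
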