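import numpy as np
import pytest

import peritonsim as ps


@pytest.fixture(scope="session")
def params():
    return ps.default_parameters()


@pytest.fixture(scope="session")
def dd_days3(params):
    """Three dry-day treatment days at the reference prescription (expensive;
    shared by the acceptance-level checks)."""
    return ps.simulate_days(params, ps.Prescription.dd_reference(), 3,
                            n_cells=50)


@pytest.fixture()
def equilibrium_tissue(params):
    return ps.init_grid(params, 50)
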