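import pytest

import radscav as r


@pytest.fixture(scope="session")
def fixtures():
    """Packaged printed-precision reference tables."""
    return r.table_fixtures()


@pytest.fixture()
def gas_refs():
    return r.GAS_REFERENCES


@pytest.fixture()
def sample_set():
    """A synthetic gas-phase species set with known cycle quantities."""
    targets = r.ThermoTargets(bde=79.14, ip=167.82, pa=320.94)
    return r.make_species_set(targets, base_enthalpy=-1200.5, seed=7)
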