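import numpy as np
import pytest

from cbcstim import experiments, morphology, protocols


@pytest.fixture(scope="session")
def on_cell():
    return morphology.build_on_cell()


@pytest.fixture(scope="session")
def off_cell():
    return morphology.build_off_cell()


@pytest.fixture(scope="session")
def field20():
    """Unit-drive sandwich field on a 20 um grid, shared across the session."""
    return experiments.default_field(grid_spacing=20.0)


@pytest.fixture()
def standard_pulse():
    return protocols.monophasic(1.0, 1.0, "cathodic")


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("repro", derandomize=True)
_hyp_settings.load_profile("repro")
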