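import numpy as np
import pytest

from protonselect.phantoms import CaseParams, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(CaseParams(), seed=1)


@pytest.fixture(scope="session")
def dual_phantom():
    return generate_phantom(CaseParams(dual_gradient=True, patient_id="dual"), seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
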