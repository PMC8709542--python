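import numpy as np
import pytest

from fhncircuit import ModelParams, preset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211105)


def random_params(rng, n):
    """Random but physically sensible parameter draws for oracle tests."""
    out = []
    for _ in range(n):
        out.append(
            ModelParams.from_ratios(
                b=float(rng.uniform(0.2, 3.0)),
                epsilon=float(10 ** rng.uniform(-3, 1.5)),
                r=float(10 ** rng.uniform(-1.3, 0.7)),
                tau_m=float(10 ** rng.uniform(-3, -1)),
                R_I=float(10 ** rng.uniform(-1, 0.5)),
                u_1=1.0,
            )
        )
    return out


@pytest.fixture(scope="session")
def model(request):
    return preset(request.param)
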