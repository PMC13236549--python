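import dataclasses

import numpy as np
import pytest

from anatodetect.phantom import decoy_spec, easy_spec, generate_cohort


@pytest.fixture(scope="session")
def easy_cohort():
    """Small easy-regime cohort shared across tests (32^3 keeps tests fast)."""
    spec = dataclasses.replace(easy_spec((32, 32, 32)),
                               lesion_radius_range=(3.0, 5.0))
    return generate_cohort(spec, 6, seed=42)


@pytest.fixture(scope="session")
def decoy_case():
    spec = decoy_spec((48, 48, 48))
    from anatodetect.phantom import generate_phantom
    return generate_phantom(spec, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
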