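import math

import pytest

from plastisize import GeneratorConfig, fit_loglog, generate_taxa

BODY_RANGE = (math.log10(9.00), math.log10(10340.0))


@pytest.fixture
def default_records():
    """65 records from the default generator (seeded)."""
    return generate_taxa(GeneratorConfig(seed=42))


@pytest.fixture
def noiseless_records():
    return generate_taxa(
        GeneratorConfig(seed=7, noise_sd=0.0, target_r2=None, min_plastic_noise_sd=0.0)
    )


@pytest.fixture
def fitted(default_records):
    return fit_loglog(default_records)
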